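"""Binary tissue-mask conditioning in physical (millimetre) units.

Before extracting ROI-mean BOLD signals, the tissue masks are conditioned:
subcortical gray matter (SGM) and normal-appearing white matter (NAWM) are
eroded by 1 mm to limit partial-volume contamination; the lateral ventricles
are dilated anisotropically (5 mm left-right, 4 mm antero-posterior and
supero-inferior) and subtracted from the NAWM and white-matter-hyperintensity
(WMH) masks to exclude the large periventricular vessels; an optional vein
mask is removed from all three.  Masks are then carried to the BOLD grid by
nearest-neighbour resampling through supplied affines.

All morphology uses axis-aligned box structuring elements whose half-widths
are the millimetre extents converted to voxels by round-half-up (minimum one
voxel for a positive extent).  Anatomical directions are resolved through
explicit axis labels, never guessed from array order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "MaskVolume",
    "erode_mask",
    "dilate_mask_anisotropic",
    "subtract_mask",
    "prepare_roi_masks",
    "resample_mask_to_bold",
    "EmptyRoiError",
    "load_mask",
    "save_mask",
]

DIRECTIONS = ("LR", "AP", "SI")


class EmptyRoiError(ValueError):
    """Mask conditioning produced an empty ROI; the tissue is unusable."""


@dataclass(frozen=True)
class MaskVolume:
    """Binary 3-D mask with voxel dimensions and anatomical axis labels.

    Attributes
    ----------
    grid : numpy.ndarray of bool
        The mask.
    voxel_mm : tuple of float
        Voxel edge length along each array axis, millimetres.
    axes : tuple of str
        Anatomical direction of each array axis; a permutation of
        ``("LR", "AP", "SI")``.
    affine : numpy.ndarray, optional
        4x4 voxel-to-world transform; defaults to a scaling by ``voxel_mm``.
    """

    grid: np.ndarray = field(repr=False)
    voxel_mm: tuple[float, float, float]
    axes: tuple[str, str, str] = ("LR", "AP", "SI")
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        g = np.asarray(self.grid)
        if g.ndim != 3:
            raise ValueError("mask grid must be 3-D")
        if g.dtype != bool:
            uniq = np.unique(g)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask values must be binary (0/1)")
            g = g.astype(bool)
        object.__setattr__(self, "grid", g)
        vox = tuple(float(v) for v in self.voxel_mm)
        if len(vox) != 3 or any(v <= 0 for v in vox):
            raise ValueError("voxel_mm must be three positive sizes")
        object.__setattr__(self, "voxel_mm", vox)
        if sorted(self.axes) != sorted(DIRECTIONS):
            raise ValueError(f"axes must be a permutation of {DIRECTIONS}")
        aff = self.affine
        if aff is None:
            aff = np.diag((*vox, 1.0))
        aff = np.asarray(aff, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        object.__setattr__(self, "affine", aff)

    def axis_of(self, direction: str) -> int:
        """Array axis corresponding to an anatomical direction label."""
        return self.axes.index(direction)

    @property
    def n_voxels(self) -> int:
        return int(self.grid.sum())

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_mm)) / 1000.0

    @property
    def volume_ml(self) -> float:
        return self.n_voxels * self.voxel_volume_ml

    def same_space(self, other: "MaskVolume") -> bool:
        return (
            self.grid.shape == other.grid.shape
            and self.voxel_mm == other.voxel_mm
            and self.axes == other.axes
            and np.allclose(self.affine, other.affine)
        )


def _half_width_vox(mm: float, voxel_mm: float) -> int:
    """mm extent -> voxel half-width: round-half-up, at least 1 when mm > 0."""
    if mm < 0:
        raise ValueError("extent must be non-negative")
    if mm == 0:
        return 0
    return max(1, int(np.floor(mm / voxel_mm + 0.5)))


def _box(half_widths: tuple[int, int, int]) -> np.ndarray:
    return np.ones(tuple(2 * h + 1 for h in half_widths), dtype=bool)


def erode_mask(mask: MaskVolume, mm: float) -> MaskVolume:
    """Erode by ``mm`` in all directions with an axis-aligned box.

    A voxel survives iff every voxel of the box centred on it (half-width
    ``round(mm / voxel_mm)`` per axis) is inside the mask; voxels beyond the
    grid border count as background.
    """
    hw = tuple(_half_width_vox(mm, v) for v in mask.voxel_mm)
    if all(h == 0 for h in hw):
        return replace(mask, grid=mask.grid.copy())
    out = ndimage.binary_erosion(mask.grid, structure=_box(hw), border_value=0)
    return replace(mask, grid=out)


def dilate_mask_anisotropic(
    mask: MaskVolume, mm_lr: float, mm_ap: float, mm_si: float
) -> MaskVolume:
    """Dilate with per-direction millimetre extents (box structuring element).

    Extents are given along anatomical directions (left-right,
    anterior-posterior, superior-inferior) and mapped to array axes through
    the mask's axis labels.
    """
    by_direction = {"LR": mm_lr, "AP": mm_ap, "SI": mm_si}
    hw = tuple(
        _half_width_vox(by_direction[d], mask.voxel_mm[mask.axis_of(d)])
        for d in mask.axes
    )
    if all(h == 0 for h in hw):
        return replace(mask, grid=mask.grid.copy())
    out = ndimage.binary_dilation(mask.grid, structure=_box(hw))
    return replace(mask, grid=out)


def subtract_mask(a: MaskVolume, b: MaskVolume) -> MaskVolume:
    """Set difference ``a \\ b``; both masks must live on the same grid."""
    if not a.same_space(b):
        raise ValueError("masks do not share grid shape / voxel size / axes")
    return replace(a, grid=a.grid & ~b.grid)


def prepare_roi_masks(
    sgm: MaskVolume,
    nawm: MaskVolume,
    wmh: MaskVolume,
    ventricles: MaskVolume,
    veins: MaskVolume | None = None,
    *,
    erosion_mm: float = 1.0,
    ventricle_dilation_mm: tuple[float, float, float] = (5.0, 4.0, 4.0),
) -> dict[str, MaskVolume]:
    """Condition the SGM / NAWM / WMH masks for CVR extraction.

    SGM and NAWM are eroded by ``erosion_mm``; the ventricles are dilated by
    ``ventricle_dilation_mm`` (LR, AP, SI) and subtracted from the eroded NAWM
    and from WMH; vein voxels, if a vein mask is supplied, are removed from
    all three.  An empty final mask raises :class:`EmptyRoiError` — that
    tissue cannot contribute a CVR estimate for this subject.
    """
    for name, m in (("nawm", nawm), ("wmh", wmh), ("ventricles", ventricles)):
        if not sgm.same_space(m):
            raise ValueError(f"{name} mask is not in the same space as sgm")
    if veins is not None and not sgm.same_space(veins):
        raise ValueError("veins mask is not in the same space as sgm")

    sgm_out = erode_mask(sgm, erosion_mm)
    nawm_out = erode_mask(nawm, erosion_mm)
    vent_dil = dilate_mask_anisotropic(ventricles, *ventricle_dilation_mm)
    nawm_out = subtract_mask(nawm_out, vent_dil)
    wmh_out = subtract_mask(wmh, vent_dil)
    if veins is not None:
        sgm_out = subtract_mask(sgm_out, veins)
        nawm_out = subtract_mask(nawm_out, veins)
        wmh_out = subtract_mask(wmh_out, veins)

    out = {"sgm": sgm_out, "nawm": nawm_out, "wmh": wmh_out}
    empty = [name for name, m in out.items() if m.n_voxels == 0]
    if empty:
        raise EmptyRoiError(f"conditioning emptied mask(s): {', '.join(empty)}")
    return out


def resample_mask_to_bold(
    mask: MaskVolume,
    affine: np.ndarray | None,
    bold_shape: tuple[int, int, int],
    bold_affine: np.ndarray,
    bold_voxel_mm: tuple[float, float, float],
    bold_axes: tuple[str, str, str] | None = None,
) -> MaskVolume:
    """Nearest-neighbour transfer of a mask onto the BOLD grid.

    ``affine`` maps mask-world to BOLD-world coordinates (identity if None;
    registration estimation is out of scope).  Each BOLD voxel centre is
    mapped back into the source voxel grid and takes the nearest source
    voxel's value; centres falling outside the source grid are background.
    """
    world = np.eye(4) if affine is None else np.asarray(affine, dtype=float)
    if world.shape != (4, 4):
        raise ValueError("affine must be 4x4")
    bold_affine = np.asarray(bold_affine, dtype=float)
    try:
        # BOLD voxel -> BOLD world -> mask world -> mask voxel
        chain = (
            np.linalg.inv(mask.affine) @ np.linalg.inv(world) @ bold_affine
        )
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular affine: {exc}") from exc

    ii, jj, kk = np.meshgrid(
        *(np.arange(s) for s in bold_shape), indexing="ij"
    )
    coords = np.stack(
        [ii.ravel(), jj.ravel(), kk.ravel(), np.ones(ii.size)], axis=0
    )
    src = chain @ coords
    src_idx = np.rint(src[:3]).astype(int)
    inside = np.all(
        (src_idx >= 0) & (src_idx < np.array(mask.grid.shape)[:, None]), axis=0
    )
    out = np.zeros(int(np.prod(bold_shape)), dtype=bool)
    valid = src_idx[:, inside]
    out[inside] = mask.grid[valid[0], valid[1], valid[2]]
    return MaskVolume(
        grid=out.reshape(bold_shape),
        voxel_mm=tuple(float(v) for v in bold_voxel_mm),
        axes=bold_axes if bold_axes is not None else mask.axes,
        affine=bold_affine,
    )


_CODE_TO_DIRECTION = {
    "R": "LR", "L": "LR",
    "A": "AP", "P": "AP",
    "S": "SI", "I": "SI",
}


def load_mask(path) -> MaskVolume:
    """Load a binary NIfTI mask; orientation labels come from the header."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D mask, got {data.ndim}-D")
    rounded = np.rint(data)
    if not np.allclose(data, rounded, atol=1e-6) or rounded.min() < 0 or rounded.max() > 1:
        raise ValueError(f"{path}: mask is not binary 0/1")
    axcodes = nib.aff2axcodes(img.affine)
    axes = tuple(_CODE_TO_DIRECTION[c] for c in axcodes)
    voxel_mm = tuple(float(z) for z in img.header.get_zooms()[:3])
    return MaskVolume(
        grid=rounded.astype(bool), voxel_mm=voxel_mm, axes=axes, affine=img.affine
    )


def save_mask(mask: MaskVolume, path) -> None:
    """Write a mask as uint8 NIfTI using its affine."""
    import nibabel as nib

    img = nib.Nifti1Image(mask.grid.astype(np.uint8), mask.affine)
    img.header.set_zooms(mask.voxel_mm)
    nib.save(img, str(path))
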