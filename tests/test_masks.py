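import numpy as np
import pytest

from svdcvr.masks import (
    EmptyRoiError,
    MaskVolume,
    dilate_mask_anisotropic,
    erode_mask,
    load_mask,
    prepare_roi_masks,
    resample_mask_to_bold,
    save_mask,
    subtract_mask,
)
from svdcvr.simulate import SimulationConfig, simulate_masks


def make_mask(grid, voxel_mm=(1.0, 1.0, 1.0), axes=("LR", "AP", "SI")):
    return MaskVolume(grid=grid.astype(bool), voxel_mm=voxel_mm, axes=axes)


def random_blob(rng, shape=(9, 9, 9), p=0.5):
    return rng.random(shape) < p


def brute_erode(grid, half_widths):
    """Voxel-by-voxel box criterion; outside the grid counts as background."""
    out = np.zeros_like(grid)
    hx, hy, hz = half_widths
    nx, ny, nz = grid.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if (
                    x - hx < 0 or x + hx >= nx
                    or y - hy < 0 or y + hy >= ny
                    or z - hz < 0 or z + hz >= nz
                ):
                    continue
                box = grid[x - hx : x + hx + 1, y - hy : y + hy + 1, z - hz : z + hz + 1]
                out[x, y, z] = box.all()
    return out


def brute_dilate(grid, half_widths):
    out = np.zeros_like(grid)
    hx, hy, hz = half_widths
    nx, ny, nz = grid.shape
    for x, y, z in zip(*np.nonzero(grid)):
        out[
            max(0, x - hx) : x + hx + 1,
            max(0, y - hy) : y + hy + 1,
            max(0, z - hz) : z + hz + 1,
        ] = True
    return out


class TestErode:
    def test_solid_cube_shrinks_by_one_voxel_shell(self):
        mask = make_mask(np.ones((5, 5, 5)))
        out = erode_mask(mask, 1.0)
        assert out.n_voxels == 27
        assert out.grid[1:4, 1:4, 1:4].all()

    def test_zero_mm_is_identity(self, rng):
        mask = make_mask(random_blob(rng))
        out = erode_mask(mask, 0.0)
        np.testing.assert_array_equal(out.grid, mask.grid)

    def test_matches_brute_force_on_anisotropic_voxels(self, rng):
        # 0.9 mm voxels: 1 mm erosion rounds to a 1-voxel half-width
        mask = make_mask(random_blob(rng), voxel_mm=(0.9, 0.9, 0.9))
        out = erode_mask(mask, 1.0)
        np.testing.assert_array_equal(out.grid, brute_erode(mask.grid, (1, 1, 1)))

    def test_anti_extensive_and_monotone_in_mm(self, rng):
        mask = make_mask(random_blob(rng, shape=(12, 12, 12)))
        e1, e2 = erode_mask(mask, 1.0), erode_mask(mask, 2.0)
        assert not (e1.grid & ~mask.grid).any()  # output subset of input
        assert not (e2.grid & ~e1.grid).any()  # more erosion, smaller mask


class TestDilate:
    def test_point_grows_into_extent_box(self):
        grid = np.zeros((15, 15, 15))
        grid[7, 7, 7] = 1
        out = dilate_mask_anisotropic(make_mask(grid), 5.0, 4.0, 4.0)
        assert out.n_voxels == 11 * 9 * 9 == 891
        assert out.grid[2:13, 3:12, 3:12].all()

    def test_zero_extents_identity(self, rng):
        mask = make_mask(random_blob(rng))
        out = dilate_mask_anisotropic(mask, 0.0, 0.0, 0.0)
        np.testing.assert_array_equal(out.grid, mask.grid)

    def test_extents_resolve_through_axis_labels(self):
        # same physical extents, permuted array axes: the 5 mm must follow LR
        grid = np.zeros((11, 11, 11))
        grid[5, 5, 5] = 1
        out = dilate_mask_anisotropic(
            make_mask(grid, axes=("AP", "SI", "LR")), 5.0, 4.0, 4.0
        )
        xs, ys, zs = np.nonzero(out.grid)
        assert np.ptp(xs) == 8 and np.ptp(ys) == 8 and np.ptp(zs) == 10

    def test_matches_brute_force_on_anisotropic_voxels(self, rng):
        mask = make_mask(
            random_blob(rng, p=0.2), voxel_mm=(0.5, 1.0, 3.0)
        )
        out = dilate_mask_anisotropic(mask, 5.0, 4.0, 4.0)
        # half-widths: round(5/0.5)=10 (LR), round(4/1)=4 (AP), round(4/3)=1 (SI)
        np.testing.assert_array_equal(out.grid, brute_dilate(mask.grid, (10, 4, 1)))

    def test_extensive_and_closing_contains_input(self, rng):
        # interior blob: the closing property needs the dilation to stay
        # inside the grid (out-of-grid voxels count as background)
        grid = np.zeros((14, 14, 14), dtype=bool)
        grid[3:11, 3:11, 3:11] = random_blob(rng, shape=(8, 8, 8), p=0.3)
        mask = make_mask(grid)
        dil = dilate_mask_anisotropic(mask, 2.0, 2.0, 2.0)
        assert not (mask.grid & ~dil.grid).any()  # input subset of output
        closed = erode_mask(dil, 2.0)
        assert not (mask.grid & ~closed.grid).any()  # box closing keeps input


class TestSubtract:
    def test_self_subtraction_empty(self, rng):
        mask = make_mask(random_blob(rng))
        assert subtract_mask(mask, mask).n_voxels == 0

    def test_subtract_empty_is_identity(self, rng):
        mask = make_mask(random_blob(rng))
        empty = make_mask(np.zeros((9, 9, 9)))
        np.testing.assert_array_equal(subtract_mask(mask, empty).grid, mask.grid)

    def test_counting_oracle(self, rng):
        a, b = make_mask(random_blob(rng)), make_mask(random_blob(rng))
        out = subtract_mask(a, b)
        assert out.n_voxels == a.n_voxels - int((a.grid & b.grid).sum())

    def test_mismatched_grids_rejected(self, rng):
        a = make_mask(random_blob(rng))
        b = make_mask(random_blob(rng), voxel_mm=(2.0, 1.0, 1.0))
        with pytest.raises(ValueError):
            subtract_mask(a, b)


class TestPrepareRoiMasks:
    def test_reduces_to_erosion_without_ventricles_or_veins(self, rng):
        shape = (16, 16, 16)
        solid = np.zeros(shape)
        solid[4:12, 4:12, 4:12] = 1
        masks = {
            "sgm": make_mask(solid),
            "nawm": make_mask(solid),
            "wmh": make_mask(solid),
            "ventricles": make_mask(np.zeros(shape)),
        }
        out = prepare_roi_masks(**masks)
        np.testing.assert_array_equal(
            out["nawm"].grid, erode_mask(masks["nawm"], 1.0).grid
        )

    def test_each_stage_predicate_holds_on_phantoms(self):
        masks = simulate_masks(SimulationConfig(seed=3))
        out = prepare_roi_masks(
            masks["sgm"], masks["nawm"], masks["wmh"], masks["ventricles"],
            veins=masks["veins"],
        )
        vent_dil = dilate_mask_anisotropic(masks["ventricles"], 5.0, 4.0, 4.0)
        eroded_nawm = erode_mask(masks["nawm"], 1.0)
        # nawm: erosion, ventricle exclusion, vein exclusion all verifiable
        assert not (out["nawm"].grid & ~eroded_nawm.grid).any()
        for roi in ("sgm", "nawm", "wmh"):
            assert not (out[roi].grid & masks["veins"].grid).any()
        for roi in ("nawm", "wmh"):
            assert not (out[roi].grid & vent_dil.grid).any()
        assert not (out["sgm"].grid & ~erode_mask(masks["sgm"], 1.0).grid).any()

    def test_wmh_swallowed_by_ventricle_dilation_raises(self):
        shape = (20, 20, 20)
        vent = np.zeros(shape)
        vent[9:11, 9:11, 9:11] = 1
        wmh = np.zeros(shape)
        wmh[11:13, 9:11, 9:11] = 1  # entirely inside the 5/4/4 mm dilation
        solid = np.zeros(shape)
        solid[2:18, 2:18, 2:18] = 1
        with pytest.raises(EmptyRoiError):
            prepare_roi_masks(
                make_mask(solid), make_mask(solid), make_mask(wmh), make_mask(vent)
            )


class TestResampleToBold:
    def test_identity_transform_identity(self, rng):
        mask = make_mask(random_blob(rng, shape=(10, 10, 10)))
        out = resample_mask_to_bold(
            mask, None, mask.grid.shape, mask.affine, mask.voxel_mm
        )
        np.testing.assert_array_equal(out.grid, mask.grid)

    def test_pure_translation_shifts_exactly(self, rng):
        grid = np.zeros((12, 12, 12))
        grid[4:8, 4:8, 4:8] = 1
        mask = make_mask(grid)
        world = np.eye(4)
        world[0, 3] = 2.0  # mask world shifted +2 mm (= 2 voxels) along axis 0
        out = resample_mask_to_bold(mask, world, grid.shape, mask.affine, mask.voxel_mm)
        np.testing.assert_array_equal(out.grid[6:10, 4:8, 4:8], np.ones((4, 4, 4), bool))
        assert out.n_voxels == mask.n_voxels

    def test_rigid_transform_agrees_with_point_oracle(self, rng):
        shape = (20, 20, 20)
        xs = np.ogrid[:20, :20, :20]
        sphere = sum((g - 10.0) ** 2 for g in xs) <= 36
        mask = make_mask(sphere)
        theta = 0.12
        world = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0, 1.2],
                [np.sin(theta), np.cos(theta), 0, -0.7],
                [0, 0, 1, 0.4],
                [0, 0, 0, 1],
            ]
        )
        out = resample_mask_to_bold(mask, world, shape, mask.affine, mask.voxel_mm)
        # independent per-voxel mapping: solve the chain point by point
        agree = 0
        for idx in np.ndindex(shape):
            bold_world = mask.affine @ np.array([*idx, 1.0])
            src_world = np.linalg.solve(world, bold_world)
            src_vox = np.linalg.solve(mask.affine, src_world)[:3]
            j = np.rint(src_vox).astype(int)
            inside = np.all((j >= 0) & (j < np.array(shape)))
            val = mask.grid[tuple(j)] if inside else False
            agree += val == out.grid[idx]
        assert agree / np.prod(shape) >= 0.95

    def test_singular_affine_rejected(self, rng):
        mask = make_mask(random_blob(rng))
        singular = np.zeros((4, 4))
        with pytest.raises(ValueError):
            resample_mask_to_bold(
                mask, singular, mask.grid.shape, mask.affine, mask.voxel_mm
            )


class TestNiftiIo:
    def test_round_trip_preserves_grid_and_metadata(self, tmp_path, rng):
        mask = make_mask(random_blob(rng), voxel_mm=(1.0, 1.0, 1.0))
        p = tmp_path / "mask.nii"
        save_mask(mask, p)
        back = load_mask(p)
        np.testing.assert_array_equal(back.grid, mask.grid)
        assert back.voxel_mm == mask.voxel_mm

    def test_non_binary_volume_rejected(self, tmp_path):
        import nibabel as nib

        img = nib.Nifti1Image(np.full((4, 4, 4), 2.0), np.eye(4))
        p = tmp_path / "notmask.nii"
        nib.save(img, str(p))
        with pytest.raises(ValueError):
            load_mask(p)
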