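"""End-to-end pipeline: simulate → mask prep → CVR fit → volumetrics →
association models → report, with a reproducibility manifest.

The pipeline is configured by a plain dict (typically loaded from YAML/JSON):

.. code-block:: yaml

    seed: 1
    out_dir: run1
    stages: [simulate, roi_prep, cvr_fit, volumes, associate, report]
    simulate: {cohort_n: 163}       # SimulationConfig overrides
    inputs: {}                      # external files when not simulating

A single top-level seed fans out to fixed per-stage offsets so any stage can
be re-run in isolation with identical results.  Each stage records its status
and the SHA-256 digest of every file it wrote in a :class:`RunManifest`;
deterministic stages reproduce their digests on re-run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .associations import (
    LINEAR_OUTCOMES,
    ORDINAL_OUTCOMES,
    TISSUES,
    CohortTable,
    ModelResult,
    SeparationError,
    fit_binomial_outcome,
    fit_linear_outcome,
    fit_ordinal_outcome,
    standardize_coefficients,
)
from .cvr import CvrModel, mean_roi_timeseries
from .masks import load_mask, prepare_roi_masks, save_mask
from .paradigm import build_paradigm, read_etco2, resample_etco2
from .simulate import (
    SimulationConfig,
    simulate_bold_volume,
    simulate_cohort,
    simulate_etco2,
    simulate_masks,
)
from .volumetrics import change_summary

__all__ = ["RunManifest", "run_pipeline", "STAGES", "PipelineConfigError"]

logger = logging.getLogger("svdcvr")

STAGES = ("simulate", "roi_prep", "cvr_fit", "volumes", "associate", "report")
_STAGE_SEED_OFFSET = {name: 101 * (i + 1) for i, name in enumerate(STAGES)}

#: normalized-volume cohort columns summarised by the volumes stage
VOLUME_COLUMNS = (
    "wmh_pct_icv",
    "brain_pct_icv",
    "pvs_bg_pct_roiv",
    "pvs_cso_pct_roiv",
    "pvs_total_pct_roiv",
)


class PipelineConfigError(ValueError):
    """Pipeline configuration violates the schema; nothing was executed."""


@dataclass
class RunManifest:
    """Record of one pipeline run: config, per-stage status, output digests."""

    config: dict
    seed: int
    version: str = __version__
    stages: dict = field(default_factory=dict)

    def record(
        self, stage: str, status: str, outputs: dict[str, str] | None = None,
        error: str | None = None, started: float | None = None,
    ) -> None:
        self.stages[stage] = {
            "status": status,
            "outputs": outputs or {},
            "error": error,
            "started": started,
            "finished": time.time(),
        }

    @property
    def ok(self) -> bool:
        return all(s["status"] in ("done", "skipped") for s in self.stages.values())

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, default=str)
        if path is not None:
            Path(path).write_text(text)
        return text


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _digest_outputs(paths) -> dict[str, str]:
    return {str(p): _sha256(Path(p)) for p in paths}


def _validate_config(config: dict) -> dict:
    if not isinstance(config, dict):
        raise PipelineConfigError("config must be a mapping")
    known = {"seed", "out_dir", "stages", "simulate", "inputs", "cvr"}
    unknown = set(config) - known
    if unknown:
        raise PipelineConfigError(f"unknown config keys: {sorted(unknown)}")
    stages = config.get("stages", list(STAGES))
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise PipelineConfigError(f"unknown stage name(s): {bad}")
    cfg = dict(config)
    cfg["stages"] = list(stages)
    cfg["seed"] = int(config.get("seed", 0))
    cfg.setdefault("simulate", {})
    cfg.setdefault("inputs", {})
    cfg.setdefault("cvr", {})
    return cfg


def _stage_seed(seed: int, stage: str) -> int:
    return (seed * 1000003 + _STAGE_SEED_OFFSET[stage]) % 2**31


def _write_nifti(data: np.ndarray, voxel_mm, path: Path) -> None:
    import nibabel as nib

    affine = np.diag((*voxel_mm, 1.0))
    img = nib.Nifti1Image(data, affine)
    nib.save(img, str(path))


# ------------------------------------------------------------- stages ------

def _stage_simulate(cfg: dict, out: Path) -> dict[str, str]:
    sim = SimulationConfig(
        seed=_stage_seed(cfg["seed"], "simulate"), **cfg["simulate"]
    )
    out.mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(exist_ok=True)

    schedule = sim.schedule()
    trace = simulate_etco2(sim)
    etco2_path = out / "etco2.tsv"
    np.savetxt(
        etco2_path,
        np.column_stack([trace.times_s, trace.values_mmHg]),
        fmt="%.6f",
        delimiter="\t",
        header="time_s\tetco2_mmHg",
    )

    masks = simulate_masks(sim)
    mask_paths = []
    for name, mask in masks.items():
        p = out / "masks" / f"{name}.nii"
        save_mask(mask, p)
        mask_paths.append(p)

    regressor = resample_etco2(trace, schedule)
    bold = simulate_bold_volume(sim, regressor, masks)
    bold_path = out / "bold.nii"
    _write_nifti(bold, sim.voxel_mm, bold_path)

    cohort = simulate_cohort(sim)
    cohort_path = out / "cohort.csv"
    cohort.to_csv(cohort_path)

    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(sim.truth(), indent=2))
    paradigm_path = out / "paradigm.json"
    paradigm_path.write_text(
        json.dumps({"block_minutes": list(sim.block_minutes), "tr_s": sim.tr_s})
    )
    return _digest_outputs(
        [etco2_path, bold_path, cohort_path, truth_path, paradigm_path, *mask_paths]
    )


def _stage_roi_prep(cfg: dict, out: Path) -> dict[str, str]:
    inputs = cfg["inputs"]
    mask_dir = Path(inputs.get("mask_dir", out / "masks"))
    masks = {
        name: load_mask(mask_dir / f"{name}.nii")
        for name in ("sgm", "nawm", "wmh", "ventricles")
    }
    veins_path = mask_dir / "veins.nii"
    veins = load_mask(veins_path) if veins_path.exists() else None
    prepared = prepare_roi_masks(**masks, veins=veins)
    roi_dir = out / "roi"
    roi_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, mask in prepared.items():
        p = roi_dir / f"{name}.nii"
        save_mask(mask, p)
        paths.append(p)
    return _digest_outputs(paths)


def _stage_cvr_fit(cfg: dict, out: Path) -> dict[str, str]:
    import nibabel as nib

    inputs = cfg["inputs"]
    bold_path = Path(inputs.get("bold", out / "bold.nii"))
    etco2_path = Path(inputs.get("etco2", out / "etco2.tsv"))
    paradigm_path = Path(inputs.get("paradigm", out / "paradigm.json"))
    paradigm = json.loads(paradigm_path.read_text())
    schedule = build_paradigm(paradigm["block_minutes"], paradigm["tr_s"])

    bold = np.asanyarray(nib.load(str(bold_path)).dataobj)
    trace = read_etco2(etco2_path)
    regressor = resample_etco2(trace, schedule)

    roi_dir = Path(inputs.get("roi_dir", out / "roi"))
    rows = []
    for tissue in TISSUES:
        mask = load_mask(roi_dir / f"{tissue}.nii")
        series = mean_roi_timeseries(bold, schedule.tr_s, mask)
        result = CvrModel(series, regressor, schedule).fit()
        rows.append(
            {
                "roi": tissue,
                "cvr_pct_per_mmHg": result.cvr_pct_per_mmHg,
                "delay_s": result.delay_s,
                "beta_au_per_mmHg": result.beta_au_per_mmHg,
                "baseline_bold_au": result.baseline_bold_au,
                "r_squared": result.r_squared,
                "ssr_au2": result.ssr_au2,
                "n_volumes": result.n_volumes,
            }
        )
    cvr_path = out / "cvr.csv"
    pd.DataFrame(rows).to_csv(cvr_path, index=False)
    sidecar = out / "cvr_settings.json"
    grid = CvrModel(series, regressor, schedule).delay_grid_s
    sidecar.write_text(
        json.dumps(
            {
                "delay_grid_s": grid.tolist(),
                "tr_s": schedule.tr_s,
                "block_minutes": paradigm["block_minutes"],
                "baseline_volumes": 30,
            },
            indent=2,
        )
    )
    return _digest_outputs([cvr_path, sidecar])


def _stage_volumes(cfg: dict, out: Path) -> dict[str, str]:
    cohort_path = Path(cfg["inputs"].get("cohort", out / "cohort.csv"))
    df = pd.read_csv(cohort_path)
    rows = []
    for name in VOLUME_COLUMNS:
        pair = df[[f"{name}_baseline", f"{name}_year1"]].dropna()
        s = change_summary(
            pair[f"{name}_baseline"].to_numpy(), pair[f"{name}_year1"].to_numpy()
        )
        rows.append(
            {
                "variable": name,
                "n": s.n,
                "change_median": s.median,
                "change_q1": s.q1,
                "change_q3": s.q3,
            }
        )
    path = out / "volumes_summary.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return _digest_outputs([path])


def fit_all_models(cohort: CohortTable) -> tuple[list[ModelResult], list[dict]]:
    """Fit every outcome × tissue model; collect failures without aborting."""
    results: list[ModelResult] = []
    failures: list[dict] = []
    for tissue in TISSUES:
        for outcome in LINEAR_OUTCOMES:
            try:
                results.append(fit_linear_outcome(cohort, outcome, tissue))
            except (ValueError, SeparationError) as exc:
                failures.append({"outcome": outcome, "tissue": tissue, "error": str(exc)})
        for outcome in ORDINAL_OUTCOMES:
            try:
                results.append(fit_ordinal_outcome(cohort, outcome, tissue))
            except (ValueError, SeparationError) as exc:
                failures.append({"outcome": outcome, "tissue": tissue, "error": str(exc)})
        try:
            results.append(fit_binomial_outcome(cohort, tissue))
        except (ValueError, SeparationError) as exc:
            failures.append({"outcome": "recurrence", "tissue": tissue, "error": str(exc)})
    return results, failures


def _stage_associate(cfg: dict, out: Path) -> dict[str, str]:
    cohort_path = Path(cfg["inputs"].get("cohort", out / "cohort.csv"))
    cohort = CohortTable.from_csv(cohort_path)
    results, failures = fit_all_models(cohort)
    if not results:
        raise RuntimeError(f"all association fits failed: {failures}")
    tidy = pd.concat([r.to_frame() for r in results], ignore_index=True)
    assoc_path = out / "associations.csv"
    tidy.to_csv(assoc_path, index=False)

    std_rows = []
    for r in results:
        try:
            std_rows.append(standardize_coefficients(r).to_frame())
        except (ValueError, SeparationError):
            continue
    std_path = out / "associations_standardized.csv"
    pd.concat(std_rows, ignore_index=True).to_csv(std_path, index=False)

    fail_path = out / "association_failures.json"
    fail_path.write_text(json.dumps(failures, indent=2))
    return _digest_outputs([assoc_path, std_path, fail_path])


def _stage_report(cfg: dict, out: Path) -> dict[str, str]:
    from .report import report_tables

    std = pd.read_csv(out / "associations_standardized.csv")
    tidy = pd.read_csv(out / "associations.csv")
    paths = report_tables(tidy, std, out / "report")
    return _digest_outputs(paths)


_STAGE_FN = {
    "simulate": _stage_simulate,
    "roi_prep": _stage_roi_prep,
    "cvr_fit": _stage_cvr_fit,
    "volumes": _stage_volumes,
    "associate": _stage_associate,
    "report": _stage_report,
}

# stages whose inputs come from an earlier stage (when no external input given)
_DEPENDS = {
    "roi_prep": ("simulate",),
    "cvr_fit": ("roi_prep",),
    "volumes": (),
    "associate": (),
    "report": ("associate",),
}


def run_pipeline(config: dict, out_dir=None) -> RunManifest:
    """Execute the configured stages; return the run manifest.

    Stage failures are recorded without aborting independent stages; stages
    whose upstream dependency failed are marked skipped.  ``manifest.ok`` is
    False if anything failed.
    """
    cfg = _validate_config(config)
    out = Path(out_dir if out_dir is not None else cfg.get("out_dir", "svdcvr_run"))
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg, seed=cfg["seed"])

    failed: set[str] = set()
    for stage in STAGES:
        if stage not in cfg["stages"]:
            continue
        deps = [
            d
            for d in _DEPENDS.get(stage, ())
            if d in cfg["stages"] and d in failed
        ]
        if deps:
            manifest.record(stage, "skipped", error=f"upstream failed: {deps}")
            logger.warning("stage %s skipped (upstream failure)", stage)
            continue
        started = time.time()
        logger.info("stage %s: started", stage)
        try:
            outputs = _STAGE_FN[stage](cfg, out)
        except Exception as exc:  # recorded, independent stages continue
            failed.add(stage)
            manifest.record(stage, "failed", error=str(exc), started=started)
            logger.error("stage %s: failed: %s", stage, exc)
        else:
            manifest.record(stage, "done", outputs=outputs, started=started)
            logger.info("stage %s: done (%d outputs)", stage, len(outputs))

    manifest.to_json(out / "manifest.json")
    return manifest
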