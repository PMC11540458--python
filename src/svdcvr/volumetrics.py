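"""Lesion / brain / perivascular-space volumetrics.

White-matter-hyperintensity (WMH) and whole-brain volumes are expressed as a
percentage of intracranial volume (%ICV); perivascular-space (PVS) volumes as
a percentage of the segmentation region volume (%ROIV).  Normalized volumes
are log10-transformed before regression to stabilise residuals, and 1-year
change is summarised per variable as the median and quartiles of the paired
follow-up − baseline differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "VOLUME_KINDS",
    "VolumeRecord",
    "ChangeSummary",
    "normalize_volume",
    "log10_volume",
    "change_summary",
    "summarize_change_table",
    "LOG10_FLOOR_PCT",
]

VOLUME_KINDS = ("wmh", "brain", "pvs_bg", "pvs_cso", "pvs_total")

#: Floor applied before log10 so that zero-volume lesions stay in the sample
#: instead of silently shrinking n.
LOG10_FLOOR_PCT = 1e-4


@dataclass(frozen=True)
class VolumeRecord:
    """One measured volume with its normalizing reference.

    ``normalized_pct == 100 * raw_ml / reference_ml`` holds exactly.
    """

    raw_ml: float
    reference_ml: float
    kind: str
    normalized_pct: float = None

    def __post_init__(self) -> None:
        if self.kind not in VOLUME_KINDS:
            raise ValueError(f"kind must be one of {VOLUME_KINDS}")
        pct = normalize_volume(self.raw_ml, self.reference_ml)
        if self.normalized_pct is None:
            object.__setattr__(self, "normalized_pct", pct)
        elif self.normalized_pct != pct:
            raise ValueError("normalized_pct inconsistent with raw/reference")


def normalize_volume(raw_ml: float, reference_ml: float) -> float:
    """Volume as a percentage of its reference (ICV or ROI volume)."""
    if reference_ml <= 0:
        raise ValueError("reference volume must be positive")
    if raw_ml < 0:
        raise ValueError("raw volume must be non-negative")
    return 100.0 * raw_ml / reference_ml


def log10_volume(normalized_pct, floor_pct: float = LOG10_FLOOR_PCT):
    """log10 of a normalized volume, floored at ``floor_pct`` to keep zeros.

    Accepts scalars or arrays.
    """
    x = np.asarray(normalized_pct, dtype=float)
    if np.any(x < 0):
        raise ValueError("normalized volume must be non-negative")
    out = np.log10(np.maximum(x, floor_pct))
    return float(out) if np.isscalar(normalized_pct) else out


@dataclass(frozen=True)
class ChangeSummary:
    """Median and quartiles of per-patient 1-year differences."""

    median: float
    q1: float
    q3: float
    n: int

    def __str__(self) -> str:
        return f"{self.median:.3g} ({self.q1:.3g}, {self.q3:.3g}) [n={self.n}]"


def change_summary(baseline, followup) -> ChangeSummary:
    """Median (Q1, Q3) of paired ``followup − baseline`` differences.

    Quantiles use linear interpolation between order statistics.
    """
    b = np.asarray(baseline, dtype=float)
    f = np.asarray(followup, dtype=float)
    if b.shape != f.shape or b.ndim != 1:
        raise ValueError("baseline and follow-up must be paired 1-D vectors")
    if b.size < 1:
        raise ValueError("at least one pair is required")
    diff = f - b
    q1, med, q3 = np.quantile(diff, [0.25, 0.5, 0.75], method="linear")
    return ChangeSummary(median=float(med), q1=float(q1), q3=float(q3), n=int(b.size))


def summarize_change_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per-kind 1-year change summary from a long-format volume table.

    ``records`` needs columns (patient_id, visit, kind, raw_ml, reference_ml)
    with visit in {baseline, year1}.  Returns one row per kind with the
    median / Q1 / Q3 of the change in normalized (%) volume across patients
    measured at both visits.
    """
    required = {"patient_id", "visit", "kind", "raw_ml", "reference_ml"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    bad_visits = set(records["visit"]) - {"baseline", "year1"}
    if bad_visits:
        raise ValueError(f"unknown visit labels: {sorted(bad_visits)}")

    df = records.copy()
    df["normalized_pct"] = [
        normalize_volume(r, ref) for r, ref in zip(df["raw_ml"], df["reference_ml"])
    ]
    wide = df.pivot_table(
        index=["patient_id", "kind"], columns="visit", values="normalized_pct"
    ).dropna(subset=["baseline", "year1"])

    rows = []
    for kind, grp in wide.groupby(level="kind"):
        s = change_summary(grp["baseline"].to_numpy(), grp["year1"].to_numpy())
        rows.append(
            {
                "kind": kind,
                "n": s.n,
                "change_median_pct": s.median,
                "change_q1_pct": s.q1,
                "change_q3_pct": s.q3,
            }
        )
    return pd.DataFrame(rows).set_index("kind")
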