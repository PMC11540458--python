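"""Delay-optimized CVR estimation from ROI-mean BOLD signals.

Model
-----
For each region of interest the mean BOLD signal ``y(v)`` over volumes ``v``
is regressed on an intercept, the EtCO2 regressor shifted by a candidate
delay, and a linear drift term (the volume index):

    y(v) = b0 + beta * EtCO2(v - delay/TR) + b_drift * v + e(v)

The delay is chosen on a grid of integer TR multiples as the shift with the
lowest residual sum of squares; because shifted regressors hold their edge
values, every candidate delay is fit on the identical sample count and the
residual sums are directly comparable.  Cerebrovascular reactivity is the
EtCO2 coefficient expressed as a relative signal change,

    CVR = 100 * beta / baseline BOLD   (%/mm Hg),

with the baseline taken as the mean signal across the first 30 volumes of
the opening medical-air block.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .masks import MaskVolume
from .paradigm import (
    AIR,
    ParadigmSchedule,
    RegressorSeries,
    default_delay_grid,
    shift_regressor,
)

__all__ = [
    "BoldSeries",
    "CvrModel",
    "CvrResult",
    "mean_roi_timeseries",
    "baseline_bold",
    "fit_at_delay",
    "estimate_cvr",
    "RankDeficientError",
]

MIN_VOLUMES = 60
BASELINE_VOLUMES = 30


class RankDeficientError(ValueError):
    """Design matrix is rank deficient (e.g. constant EtCO2 regressor)."""


@dataclass(frozen=True)
class BoldSeries:
    """ROI-mean BOLD time series (arbitrary units) with its TR."""

    values_au: np.ndarray
    tr_s: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values_au, dtype=float)
        object.__setattr__(self, "values_au", v)
        if v.ndim != 1:
            raise ValueError("BOLD series must be 1-D")
        if v.size < MIN_VOLUMES:
            raise ValueError(f"BOLD series needs >= {MIN_VOLUMES} volumes, got {v.size}")
        if not np.all(np.isfinite(v)):
            raise ValueError("BOLD series must be finite")
        if not np.all(v > 0):
            raise ValueError("BOLD series values must be positive")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")

    def __len__(self) -> int:
        return int(self.values_au.size)


@dataclass(frozen=True)
class CvrResult:
    """Fitted CVR for one ROI, with the delay search diagnostics.

    ``cvr_pct_per_mmHg == 100 * beta_au_per_mmHg / baseline_bold_au`` holds
    exactly by construction.
    """

    cvr_pct_per_mmHg: float
    delay_s: float
    beta_au_per_mmHg: float
    baseline_bold_au: float
    r_squared: float
    ssr_au2: float
    n_volumes: int
    delay_grid_s: np.ndarray = field(repr=False, default=None)
    ssr_by_delay: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.baseline_bold_au <= 0:
            raise ValueError("baseline BOLD must be positive")
        if not (0.0 <= self.r_squared <= 1.0):
            raise ValueError("r_squared must lie in [0, 1]")

    def summary(self) -> str:
        lines = [
            "CVR fit (delay-optimized BOLD ~ EtCO2 + drift)",
            "=" * 46,
            f"n volumes        : {self.n_volumes}",
            f"baseline BOLD    : {self.baseline_bold_au:.4g} au",
            f"optimal delay    : {self.delay_s:+.2f} s",
            f"beta (EtCO2)     : {self.beta_au_per_mmHg:.6g} au / mm Hg",
            f"CVR              : {self.cvr_pct_per_mmHg:.6g} %/mm Hg",
            f"R^2              : {self.r_squared:.4f}",
            f"SSR at optimum   : {self.ssr_au2:.6g} au^2",
        ]
        return "\n".join(lines)


def mean_roi_timeseries(bold4d: np.ndarray, tr_s: float, mask: MaskVolume) -> BoldSeries:
    """Per-volume arithmetic mean of the BOLD signal over the mask voxels."""
    bold4d = np.asarray(bold4d)
    if bold4d.ndim != 4:
        raise ValueError("BOLD data must be 4-D (x, y, z, t)")
    if bold4d.shape[:3] != mask.grid.shape:
        raise ValueError(
            f"mask shape {mask.grid.shape} does not match BOLD grid {bold4d.shape[:3]}"
        )
    if mask.n_voxels == 0:
        raise ValueError("ROI mask is empty")
    series = bold4d[mask.grid].mean(axis=0).astype(float)
    return BoldSeries(values_au=series, tr_s=float(tr_s))


def baseline_bold(series: BoldSeries, schedule: ParadigmSchedule) -> float:
    """Mean signal of the first 30 volumes of the opening medical-air block."""
    gas0, dur0 = schedule.blocks[0]
    if gas0 != AIR:
        raise ValueError("first block must be medical air")
    n_air = int(np.floor(dur0 / schedule.tr_s))
    if n_air < BASELINE_VOLUMES:
        raise ValueError(
            f"first air block holds only {n_air} volumes; "
            f"{BASELINE_VOLUMES} are required for the baseline"
        )
    return float(series.values_au[:BASELINE_VOLUMES].mean())


def _design(regressor: np.ndarray) -> np.ndarray:
    n = regressor.size
    return np.column_stack([np.ones(n), regressor, np.arange(n, dtype=float)])


def fit_at_delay(
    series: BoldSeries, regressor: RegressorSeries, delay_s: float
) -> tuple[float, float, float]:
    """OLS of BOLD on {intercept, EtCO2 shifted by ``delay_s``, volume index}.

    Returns ``(beta, ssr, r_squared)`` where ``beta`` is the EtCO2
    coefficient.  A regressor that is constant after shifting makes the
    design rank deficient and raises :class:`RankDeficientError`.
    """
    if len(series) != len(regressor):
        raise ValueError("BOLD series and regressor lengths differ")
    shifted = shift_regressor(regressor, delay_s)
    x = shifted.values_mmHg
    if np.ptp(x) <= 1e-12 * max(1.0, abs(float(x[0]))):
        raise RankDeficientError(
            "EtCO2 regressor is constant after shifting; CVR is not identifiable"
        )
    X = _design(x)
    y = series.values_au
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 3:
        raise RankDeficientError("rank-deficient design matrix")
    resid = y - X @ coef
    ssr = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if sst <= 0 else max(0.0, min(1.0, 1.0 - ssr / sst))
    return float(coef[1]), ssr, r2


class CvrModel:
    """Delay-optimized CVR model for one ROI-mean BOLD series.

    Parameters
    ----------
    series : BoldSeries
        ROI-mean BOLD signal.
    regressor : RegressorSeries
        Unshifted EtCO2 regressor on the same volume grid.
    schedule : ParadigmSchedule
        Gas-block schedule (provides the baseline window definition).
    delay_grid_s : sequence of float, optional
        Candidate delays in seconds, each an integer multiple of TR;
        defaults to −10·TR … +40·TR.

    Examples
    --------
    >>> result = CvrModel(series, regressor, schedule).fit()
    >>> print(result.summary())
    """

    def __init__(
        self,
        series: BoldSeries,
        regressor: RegressorSeries,
        schedule: ParadigmSchedule,
        delay_grid_s=None,
    ) -> None:
        if len(series) != len(regressor):
            raise ValueError("BOLD series and regressor lengths differ")
        if delay_grid_s is None:
            delay_grid_s = default_delay_grid(series.tr_s)
        grid = np.asarray(delay_grid_s, dtype=float)
        if grid.size == 0:
            raise ValueError("delay grid must not be empty")
        ratios = grid / series.tr_s
        if np.any(np.abs(ratios - np.rint(ratios)) > 1e-6):
            raise ValueError("all grid delays must be integer multiples of TR")
        self.series = series
        self.regressor = regressor
        self.schedule = schedule
        self.delay_grid_s = np.sort(grid)

    @classmethod
    def from_roi(
        cls,
        bold4d: np.ndarray,
        mask: MaskVolume,
        regressor: RegressorSeries,
        schedule: ParadigmSchedule,
        delay_grid_s=None,
    ) -> "CvrModel":
        series = mean_roi_timeseries(bold4d, schedule.tr_s, mask)
        return cls(series, regressor, schedule, delay_grid_s)

    def fit(self) -> CvrResult:
        """Grid-search the delay, fit OLS at each, return the optimum.

        Ties in the residual sum of squares resolve to the smallest delay.
        A zero-variance BOLD series yields CVR = 0 and R^2 = 0 with a warning
        rather than NaN.
        """
        y = self.series.values_au
        baseline = baseline_bold(self.series, self.schedule)
        degenerate = np.ptp(y) == 0.0
        if degenerate:
            warnings.warn(
                "BOLD series has zero variance; reporting CVR = 0", stacklevel=2
            )

        ssr_by_delay = np.empty(self.delay_grid_s.size)
        best = None  # (ssr, delay, beta, r2)
        for i, d in enumerate(self.delay_grid_s):
            beta, ssr, r2 = fit_at_delay(self.series, self.regressor, d)
            ssr_by_delay[i] = ssr
            if best is None or ssr < best[0]:  # strict: ties keep earliest delay
                best = (ssr, d, beta, r2)

        ssr, delay, beta, r2 = best
        if degenerate:
            # zero-variance BOLD: every delay fits identically, so the search
            # is meaningless; report the smallest grid delay deterministically
            beta, r2 = 0.0, 0.0
            delay = float(self.delay_grid_s[0])
            ssr = float(ssr_by_delay[0])
        cvr = 100.0 * beta / baseline
        return CvrResult(
            cvr_pct_per_mmHg=cvr,
            delay_s=float(delay),
            beta_au_per_mmHg=float(beta),
            baseline_bold_au=baseline,
            r_squared=float(r2),
            ssr_au2=float(ssr),
            n_volumes=len(self.series),
            delay_grid_s=self.delay_grid_s.copy(),
            ssr_by_delay=ssr_by_delay,
        )


def estimate_cvr(
    series: BoldSeries,
    etco2: RegressorSeries,
    schedule: ParadigmSchedule,
    delay_grid_s=None,
) -> CvrResult:
    """Functional wrapper over :class:`CvrModel`: fit and return the result."""
    return CvrModel(series, etco2, schedule, delay_grid_s).fit()
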