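"""Synthetic data with known ground truth for the full CVR pipeline.

Generates every input the pipeline consumes:

* block-structured EtCO2 traces (exponential transitions into and out of the
  hypercapnic blocks),
* ROI-mean BOLD series (and optional 4-D volumes over mask phantoms) whose
  generating CVR, delay, drift and noise are configured,
* nested-ellipsoid tissue-mask phantoms (brain, NAWM, WMH, SGM, ventricles,
  veins) coherent with the mask-conditioning pipeline,
* longitudinal cohorts whose covariate marginals are matched to the study
  population (median age 68, 32% female, median NAWM CVR 0.042 %/mm Hg, 29%
  recurrence, ...) and whose outcome-vs-CVR effects are set to configurable
  generating coefficients.

The BOLD generator is the exact inverse of the estimation model: on a
noiseless series with the generating delay on the search grid, the estimator
returns the generating CVR and delay exactly.  Both the EtCO2 term and the
drift term are centred on the first 30 air volumes so the baseline BOLD of
the noiseless series equals B0 by construction.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .associations import CohortTable
from .cvr import BASELINE_VOLUMES, BoldSeries
from .masks import MaskVolume
from .paradigm import (
    CO2,
    Etco2Trace,
    ParadigmSchedule,
    RegressorSeries,
    build_paradigm,
    shift_regressor,
)

__all__ = [
    "SimulationConfig",
    "simulate_etco2",
    "simulate_bold",
    "simulate_bold_volume",
    "simulate_masks",
    "simulate_cohort",
    "etco2_block_value",
]

# Lognormal CVR marginals (median, sigma of the natural log) matched to the
# study cohort's per-tissue median (Q1, Q3).
DEFAULT_CVR_LOGNORM = {
    "sgm": (0.171, 0.3168),
    "nawm": (0.042, 0.3652),
    "wmh": (0.040, 0.7083),
}

# Baseline outcome marginals: ("lognormal", median, log-sigma) or
# ("normal", mean, sd) or ("poisson", rate).
DEFAULT_BASELINES = {
    "wmh_pct_icv": ("lognormal", 0.506, 1.1490),
    "brain_pct_icv": ("normal", 67.6, 4.89),
    "pvs_bg_pct_roiv": ("lognormal", 4.89, 0.4452),
    "pvs_cso_pct_roiv": ("lognormal", 3.31, 0.6472),
    "pvs_total_pct_roiv": ("lognormal", 3.66, 0.5812),
    "n_lacunes": ("poisson", 1.5),
    "n_microbleeds": ("poisson", 0.2),
}

# Generating CVR coefficients for the 1-year continuous outcomes, applied via
# the designated effect tissue (NAWM by default).  WMH and PVS effects act on
# the log10 scale, brain volume on the %ICV scale.
DEFAULT_LINEAR_EFFECTS = {
    "wmh_pct_icv": -1.14,
    "brain_pct_icv": 0.0,
    "pvs_bg_pct_roiv": -2.12,
    "pvs_cso_pct_roiv": -1.93,
    "pvs_total_pct_roiv": -1.90,
}

# Median 1-year drift of each continuous outcome (log10 scale for the
# log-transformed ones), matched to the cohort's observed median changes.
DEFAULT_OUTCOME_DRIFT = {
    "wmh_pct_icv": 0.0158,
    "brain_pct_icv": -0.97,
    "pvs_bg_pct_roiv": 0.0209,
    "pvs_cso_pct_roiv": 0.0415,
    "pvs_total_pct_roiv": 0.0421,
}

DEFAULT_OUTCOME_NOISE = {
    "wmh_pct_icv": 0.10,
    "brain_pct_icv": 0.90,
    "pvs_bg_pct_roiv": 0.10,
    "pvs_cso_pct_roiv": 0.10,
    "pvs_total_pct_roiv": 0.10,
}

# Tissue-specific truths for 4-D phantom BOLD volumes (CVR %/mm Hg, delay in
# TR units).  CVR values are the cohort medians; delays are artifact choices.
DEFAULT_TISSUE_CVR = {"sgm": 0.171, "nawm": 0.042, "wmh": 0.040}
DEFAULT_TISSUE_DELAY_TR = {"sgm": 3, "nawm": 4, "wmh": 5}


@dataclass
class SimulationConfig:
    """All generator knobs; a fixed seed makes every output reproducible."""

    seed: int = 0
    # paradigm
    block_minutes: tuple = (2, 3, 2, 3, 2)
    tr_s: float = 1.55
    # EtCO2 dynamics (tau/delta are plausible for a 6% CO2 challenge; they are
    # artifact defaults, not cohort-reported values)
    etco2_baseline_mmHg: float = 40.0
    etco2_delta_mmHg: float = 8.0
    transition_tau_s: float = 15.0
    breath_interval_s: float = 4.0
    etco2_jitter_sd_mmHg: float = 0.0
    # single-series BOLD truth
    bold_b0_au: float = 1000.0
    cvr_true_pct_per_mmHg: float = 0.042
    delay_true_s: float = 4 * 1.55
    drift_au_per_vol: float = 0.05
    noise_sd_au: float = 5.0  # 0.5% of B0
    # mask phantoms
    grid_shape: tuple = (32, 32, 32)
    voxel_mm: tuple = (1.0, 1.0, 1.0)
    # 4-D volume truths
    tissue_cvr: dict = field(default_factory=lambda: dict(DEFAULT_TISSUE_CVR))
    tissue_delay_tr: dict = field(default_factory=lambda: dict(DEFAULT_TISSUE_DELAY_TR))
    # cohort
    cohort_n: int = 163
    age_mean: float = 65.8
    age_sd: float = 11.2
    age_bounds: tuple = (35.0, 95.0)
    female_frac: float = 0.32
    map_mean_mmHg: float = 105.0
    map_sd_mmHg: float = 12.6
    smoking_probs: tuple = (0.45, 0.39, 0.16)  # never, ever, current
    prev_hypertension: float = 0.72
    prev_diabetes: float = 0.20
    prev_hypercholesterolemia: float = 0.72
    cvr_lognorm: dict = field(default_factory=lambda: dict(DEFAULT_CVR_LOGNORM))
    age_cvr_rho: float = -0.3
    baselines: dict = field(default_factory=lambda: dict(DEFAULT_BASELINES))
    effect_tissue: str = "nawm"
    linear_effects: dict = field(default_factory=lambda: dict(DEFAULT_LINEAR_EFFECTS))
    outcome_drift: dict = field(default_factory=lambda: dict(DEFAULT_OUTCOME_DRIFT))
    outcome_noise_sd: dict = field(default_factory=lambda: dict(DEFAULT_OUTCOME_NOISE))
    age_effect_log10: float = 0.003  # per year, on log10-scale outcomes
    ordinal_log_or: float = 0.0
    ordinal_baseline_beta: float = 0.8
    binomial_log_or: float = 0.0
    recurrence_prevalence: float = 0.29
    new_lacune_rate: float = 0.083
    new_microbleed_rate: float = 0.105

    def __post_init__(self) -> None:
        if self.cohort_n < 1:
            raise ValueError("cohort_n must be >= 1")
        for name in ("etco2_jitter_sd_mmHg", "noise_sd_au"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def schedule(self) -> ParadigmSchedule:
        return build_paradigm(self.block_minutes, self.tr_s)

    def rng(self, offset: int = 0) -> np.random.Generator:
        return np.random.default_rng((int(self.seed) + 997 * offset) % 2**31)

    def to_dict(self) -> dict:
        return asdict(self)

    def truth(self) -> dict:
        """Ground-truth parameters a recovery test should reproduce."""
        return {
            "cvr_true_pct_per_mmHg": self.cvr_true_pct_per_mmHg,
            "delay_true_s": self.delay_true_s,
            "tissue_cvr": dict(self.tissue_cvr),
            "tissue_delay_s": {
                t: k * self.tr_s for t, k in self.tissue_delay_tr.items()
            },
            "linear_effects": dict(self.linear_effects),
            "effect_tissue": self.effect_tissue,
            "ordinal_log_or": self.ordinal_log_or,
            "binomial_log_or": self.binomial_log_or,
            "recurrence_prevalence": self.recurrence_prevalence,
        }


# ---------------------------------------------------------------- EtCO2 ----

def etco2_block_value(times_s, schedule: ParadigmSchedule, baseline, delta, tau):
    """Noise-free EtCO2 value at arbitrary times under exponential transitions.

    Within each block the level approaches the block target (baseline for
    air, baseline + delta for CO2) exponentially with time constant ``tau``
    from the level reached at the block boundary; ``tau = 0`` gives an ideal
    square wave.
    """
    times = np.asarray(times_s, dtype=float)
    starts, value_at_start = [], []
    t0, v = 0.0, float(baseline)
    for gas, dur in schedule.blocks:
        starts.append((t0, v, baseline + delta if gas == CO2 else baseline))
        if tau > 0:
            v = starts[-1][2] + (v - starts[-1][2]) * np.exp(-dur / tau)
        else:
            v = starts[-1][2]
        t0 += dur
    ends = np.cumsum([d for _, d in schedule.blocks])
    idx = np.minimum(np.searchsorted(ends, times, side="right"), len(ends) - 1)
    out = np.empty_like(times)
    for i, (t_start, v_start, target) in enumerate(starts):
        sel = idx == i
        if not np.any(sel):
            continue
        if tau > 0:
            out[sel] = target + (v_start - target) * np.exp(
                -(times[sel] - t_start) / tau
            )
        else:
            out[sel] = target
    return out


def simulate_etco2(config: SimulationConfig) -> Etco2Trace:
    """Breath-sampled EtCO2 trace for the configured gas challenge."""
    schedule = config.schedule()
    total = schedule.total_duration_s
    times = np.arange(0.0, total + config.breath_interval_s / 2, config.breath_interval_s)
    values = etco2_block_value(
        times,
        schedule,
        config.etco2_baseline_mmHg,
        config.etco2_delta_mmHg,
        config.transition_tau_s,
    )
    if config.etco2_jitter_sd_mmHg > 0:
        rng = config.rng(offset=1)
        values = values + rng.normal(0.0, config.etco2_jitter_sd_mmHg, values.size)
    values = np.clip(values, 0.0, 150.0)
    return Etco2Trace(times_s=times, values_mmHg=values)


# ----------------------------------------------------------------- BOLD ----

def _noiseless_bold(
    regressor: RegressorSeries,
    b0: float,
    cvr: float,
    delay_s: float,
    drift: float,
) -> np.ndarray:
    k = delay_s / regressor.tr_s
    if abs(k - round(k)) <= 1e-6:
        shifted = shift_regressor(regressor, regressor.tr_s * round(k)).values_mmHg
    else:
        # fractional delay (noisy simulations only): interpolate with edge hold
        n = len(regressor)
        shifted = np.interp(
            np.arange(n) - k, np.arange(n), regressor.values_mmHg
        )
    t = np.arange(shifted.size, dtype=float)
    # centring both terms on the baseline window keeps baseline BOLD == B0
    e_c = shifted - shifted[:BASELINE_VOLUMES].mean()
    t_c = t - t[:BASELINE_VOLUMES].mean()
    return b0 * (1.0 + (cvr / 100.0) * e_c) + drift * t_c


def simulate_bold(
    config: SimulationConfig,
    etco2: RegressorSeries,
    rng: np.random.Generator | None = None,
) -> BoldSeries:
    """ROI-mean BOLD series with configured CVR, delay, drift and noise.

    With ``noise_sd_au = 0`` the generating delay must lie on the volume grid
    (an off-grid delay would silently break the exact-recovery contract).
    """
    k = config.delay_true_s / config.tr_s
    if config.noise_sd_au == 0 and abs(k - round(k)) > 1e-6:
        raise ValueError(
            "noiseless simulation requires delay_true_s on the volume grid"
        )
    values = _noiseless_bold(
        etco2,
        config.bold_b0_au,
        config.cvr_true_pct_per_mmHg,
        config.delay_true_s,
        config.drift_au_per_vol,
    )
    if config.noise_sd_au > 0:
        rng = config.rng(offset=2) if rng is None else rng
        values = values + rng.normal(0.0, config.noise_sd_au, values.size)
    return BoldSeries(values_au=np.maximum(values, 1e-6), tr_s=config.tr_s)


def simulate_bold_volume(
    config: SimulationConfig,
    etco2: RegressorSeries,
    masks: dict[str, MaskVolume],
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """4-D BOLD volume (float32) over the mask phantoms.

    Voxels of each tissue share that tissue's noiseless response (its own CVR
    and delay from the config); all voxels get independent Gaussian noise.
    Non-tissue brain voxels respond with zero CVR; background is near-zero.
    """
    rng = config.rng(offset=3) if rng is None else rng
    shape = masks["brain"].grid.shape
    n_vol = len(etco2)
    vol = np.zeros((*shape, n_vol), dtype=np.float32)

    brain = masks["brain"].grid
    t = np.arange(n_vol, dtype=float)
    base = config.bold_b0_au + config.drift_au_per_vol * (
        t - t[:BASELINE_VOLUMES].mean()
    )
    vol[brain] = base.astype(np.float32)
    for tissue in ("sgm", "nawm", "wmh"):
        series = _noiseless_bold(
            etco2,
            config.bold_b0_au,
            config.tissue_cvr[tissue],
            config.tissue_delay_tr[tissue] * config.tr_s,
            config.drift_au_per_vol,
        )
        vol[masks[tissue].grid] = series.astype(np.float32)
    if config.noise_sd_au > 0:
        vol[brain] += rng.normal(0.0, config.noise_sd_au, (int(brain.sum()), n_vol)).astype(
            np.float32
        )
    vol[~brain] = np.abs(
        rng.normal(5.0, 1.0, (int((~brain).sum()), n_vol))
    ).astype(np.float32)
    return vol


# ---------------------------------------------------------------- masks ----

def _ellipsoid(shape, centre, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, centre, radii))
    return acc <= 1.0


def simulate_masks(config: SimulationConfig) -> dict[str, MaskVolume]:
    """Nested-ellipsoid tissue phantoms emulating a deep-brain slab.

    brain ⊃ {nawm shell, sgm blobs, wmh blobs}; central ventricles disjoint
    from SGM; WMH blobs sit against the ventricle tips so the periventricular
    exclusion bites; a vein line crosses one SGM blob.
    """
    shape = tuple(int(s) for s in config.grid_shape)
    if min(shape) < 16:
        raise ValueError("phantom grid must be at least 16 voxels per axis")
    s = min(shape) / 32.0
    c = tuple(n // 2 for n in shape)

    def r(x: float) -> float:
        return max(1.0, x * s)

    brain = _ellipsoid(shape, c, (r(14),) * 3)
    ventricles = _ellipsoid(shape, c, (r(2), r(4), r(2)))
    shell = _ellipsoid(shape, c, (r(11),) * 3) & ~_ellipsoid(
        shape, c, (r(5), r(7), r(5))
    )
    sgm = np.zeros(shape, dtype=bool)
    for sign in (-1, 1):
        sgm |= _ellipsoid(
            shape, (c[0] + sign * round(r(8)), c[1], c[2]), (r(3),) * 3
        )
    wmh = np.zeros(shape, dtype=bool)
    for sign in (-1, 1):
        wmh |= _ellipsoid(
            shape, (c[0], c[1] + sign * round(r(8)), c[2]), (r(2),) * 3
        )
    wmh &= brain
    nawm = shell & ~sgm & ~wmh & ~ventricles
    veins = np.zeros(shape, dtype=bool)
    x = c[0] + round(r(8))
    z0, z1 = c[2] - round(r(6)), c[2] + round(r(6)) + 1
    veins[x, c[1], z0:z1] = True

    out = {}
    for name, grid in (
        ("brain", brain),
        ("nawm", nawm),
        ("wmh", wmh),
        ("sgm", sgm),
        ("ventricles", ventricles),
        ("veins", veins),
    ):
        out[name] = MaskVolume(
            grid=grid, voxel_mm=tuple(config.voxel_mm), axes=("LR", "AP", "SI")
        )
    return out


# --------------------------------------------------------------- cohort ----

def _lognormal_from_median(rng, median, sigma, n, z=None):
    z = rng.standard_normal(n) if z is None else z
    return np.exp(np.log(median) + sigma * z)


def _ordinal_from_marginal(rng, marginal_levels, marginal_probs, eta):
    """Proportional-odds draw: P(y <= k) = expit(c_k − eta)."""
    cum = np.cumsum(marginal_probs)[:-1]
    cum = np.clip(cum, 1e-9, 1 - 1e-9)
    cut = logit(cum)
    u = rng.logistic(size=eta.shape)
    y_idx = np.sum(u[:, None] > (cut[None, :] - eta[:, None]), axis=1)
    return np.asarray(marginal_levels)[y_idx]


def _solve_intercept(lp: np.ndarray, target: float) -> float:
    f = lambda c: expit(c + lp).mean() - target
    return brentq(f, -40.0, 40.0)


def simulate_cohort(config: SimulationConfig) -> CohortTable:
    """Longitudinal cohort with configured marginals and generating effects.

    Continuous 1-year outcomes follow the same linear model the analysis
    fits (baseline term with unit coefficient, CVR effect through the
    designated tissue, a small age effect, Gaussian noise), so estimates are
    unbiased and their CIs have nominal coverage under the generator.
    """
    rng = config.rng(offset=4)
    n = config.cohort_n

    # age and per-tissue CVR share a Gaussian copula: corr(age, log CVR_t) = rho
    z_age = rng.standard_normal(n)
    lo = (config.age_bounds[0] - config.age_mean) / config.age_sd
    hi = (config.age_bounds[1] - config.age_mean) / config.age_sd
    for _ in range(100):
        bad = (z_age < lo) | (z_age > hi)
        if not bad.any():
            break
        z_age[bad] = rng.standard_normal(int(bad.sum()))
    age = config.age_mean + config.age_sd * z_age

    rho = config.age_cvr_rho
    lam = 0.6  # shared-factor loading: cross-tissue CVR correlation
    e_common = rng.standard_normal(n)
    cvr = {}
    for tissue in ("sgm", "nawm", "wmh"):
        e_t = rng.standard_normal(n)
        z_t = rho * z_age + np.sqrt(1 - rho**2) * (
            lam * e_common + np.sqrt(1 - lam**2) * e_t
        )
        median, sigma = config.cvr_lognorm[tissue]
        cvr[tissue] = _lognormal_from_median(rng, median, sigma, n, z=z_t)

    sex = np.where(rng.random(n) < config.female_frac, "female", "male")
    smoking = rng.choice(SMOKING := ("never", "ever", "current"), size=n,
                         p=config.smoking_probs)
    htn = (rng.random(n) < config.prev_hypertension).astype(int)
    dm = (rng.random(n) < config.prev_diabetes).astype(int)
    chol = (rng.random(n) < config.prev_hypercholesterolemia).astype(int)
    map_mmHg = rng.normal(config.map_mean_mmHg, config.map_sd_mmHg, n).clip(60, 160)
    resting_etco2 = rng.normal(40.0, 3.0, n).clip(25, 60)

    df = pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(n)],
            "age_years": age,
            "sex": sex,
            "map_mmHg": map_mmHg,
            "smoking": smoking,
            "hypertension": htn,
            "diabetes": dm,
            "hypercholesterolemia": chol,
            "resting_etco2_mmHg": resting_etco2,
            "cvr_sgm": cvr["sgm"],
            "cvr_nawm": cvr["nawm"],
            "cvr_wmh": cvr["wmh"],
        }
    )

    cvr_eff = cvr[config.effect_tissue]
    age_c = age - config.age_mean

    # continuous outcomes
    for name, spec in config.baselines.items():
        kind = spec[0]
        if kind == "lognormal":
            base = _lognormal_from_median(rng, spec[1], spec[2], n)
        elif kind == "normal":
            base = rng.normal(spec[1], spec[2], n)
        elif kind == "poisson":
            base = rng.poisson(spec[1], n).astype(float)
        else:  # pragma: no cover
            raise ValueError(f"unknown baseline kind {kind!r}")
        df[f"{name}_baseline"] = base

        if name in ("n_lacunes", "n_microbleeds"):
            rate = (
                config.new_lacune_rate
                if name == "n_lacunes"
                else config.new_microbleed_rate
            )
            df[f"{name}_year1"] = base + rng.poisson(rate, n)
            continue

        B = config.linear_effects.get(name, 0.0)
        drift = config.outcome_drift.get(name, 0.0)
        noise_sd = config.outcome_noise_sd.get(name, 0.1)
        median_cvr, sigma_cvr = config.cvr_lognorm[config.effect_tissue]
        mean_cvr = median_cvr * np.exp(sigma_cvr**2 / 2)
        eps = rng.normal(0.0, noise_sd, n)
        if name == "brain_pct_icv":
            intercept = drift - B * mean_cvr
            df[f"{name}_year1"] = (
                base + intercept + B * cvr_eff + 10 * config.age_effect_log10 * age_c + eps
            )
        else:  # log10-scale generative model
            log_base = np.log10(np.maximum(base, 1e-4))
            intercept = drift - B * mean_cvr
            log_y1 = (
                log_base
                + intercept
                + B * cvr_eff
                + config.age_effect_log10 * age_c
                + eps
            )
            df[f"{name}_year1"] = 10.0 ** log_y1

    # ordinal scores: baseline marginals, then proportional-odds year-1 draw
    nihss0 = np.minimum(rng.poisson(1.2, n), 8)
    mrs0 = rng.choice([0, 1, 2], size=n, p=[0.2, 0.6, 0.2])
    moca0 = np.clip(np.rint(rng.normal(25.0, 3.0, n)), 0, 30).astype(int)
    for name, base in (("nihss", nihss0), ("mrs", mrs0), ("moca", moca0)):
        df[f"{name}_baseline"] = base
        levels, counts = np.unique(base, return_counts=True)
        probs = counts / counts.sum()
        eta = config.ordinal_baseline_beta * (base - base.mean()) + (
            config.ordinal_log_or * (cvr_eff - cvr_eff.mean())
        )
        df[f"{name}_year1"] = _ordinal_from_marginal(rng, levels, probs, eta)

    # recurrence: logistic with the configured marginal prevalence
    lp = config.binomial_log_or * (cvr_eff - cvr_eff.mean()) + 0.02 * age_c
    intercept = _solve_intercept(lp, config.recurrence_prevalence)
    df["recurrence"] = (rng.random(n) < expit(intercept + lp)).astype(int)

    return CohortTable(df)
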