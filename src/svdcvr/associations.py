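"""Covariate-adjusted models linking baseline CVR to 1-year outcomes.

Three model families mirror the outcome types of a longitudinal
small-vessel-disease cohort:

* **linear** (OLS) for quantitative imaging outcomes — the 1-year value
  (log10-transformed for WMH and PVS volumes) regressed on baseline CVR,
  the same variable at baseline, age, sex, mean arterial pressure, smoking
  history (current / ever vs never), and hypertension, diabetes and
  hypercholesterolemia diagnoses;
* **ordinal** (proportional-odds logistic) for NIHSS, mRS and MoCA scores,
  additionally adjusted for baseline WMH volume (log10 %ICV);
* **binomial** (logistic) for recurrent stroke/TIA or new infarct, with a
  reduced covariate set — baseline WMH volume, age, sex, MAP and an
  equal-weight vascular-risk-factor score — to avoid overfitting.

Every term is reported with a Wald 95% CI (t-based for OLS, normal for the
logistic families) and p-value; logistic coefficients are reported as odds
ratios.  Missing data are handled complete-case per model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.stats.diagnostic import het_breuschpagan
from statsmodels.stats.stattools import jarque_bera
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .volumetrics import log10_volume

__all__ = [
    "SMOKING_LEVELS",
    "SEX_LEVELS",
    "TISSUES",
    "LINEAR_OUTCOMES",
    "ORDINAL_OUTCOMES",
    "CohortTable",
    "TermResult",
    "ModelResult",
    "LinearOutcomeModel",
    "OrdinalOutcomeModel",
    "BinomialOutcomeModel",
    "vrf_score",
    "fit_linear_outcome",
    "fit_ordinal_outcome",
    "fit_binomial_outcome",
    "standardize_coefficients",
    "SeparationError",
]

SMOKING_LEVELS = ("never", "ever", "current")
SEX_LEVELS = ("female", "male")
TISSUES = ("sgm", "nawm", "wmh")

#: Quantitative outcomes and whether they are log10-transformed before OLS.
LINEAR_OUTCOMES = {
    "wmh_pct_icv": True,
    "brain_pct_icv": False,
    "pvs_bg_pct_roiv": True,
    "pvs_cso_pct_roiv": True,
    "pvs_total_pct_roiv": True,
    "n_lacunes": False,
    "n_microbleeds": False,
}
ORDINAL_OUTCOMES = ("nihss", "mrs", "moca")
ORDINAL_RANGES = {"nihss": (0, 42), "mrs": (0, 6), "moca": (0, 30)}

MIN_N = 20  # guard against silently meaningless fits on toy inputs

_BASE_COLUMNS = (
    "patient_id",
    "age_years",
    "sex",
    "map_mmHg",
    "smoking",
    "hypertension",
    "diabetes",
    "hypercholesterolemia",
    "cvr_sgm",
    "cvr_nawm",
    "cvr_wmh",
    "recurrence",
)


class SeparationError(RuntimeError):
    """Logistic fit shows (quasi-)separation; estimates are not reportable."""


def vrf_score(hypertension, diabetes, hypercholesterolemia, smoking) -> int:
    """Equal-weight vascular-risk-factor score (0-4).

    One point each for hypertension, diabetes, hypercholesterolemia, and any
    smoking history (ever or current vs never).
    """
    for name, v in (
        ("hypertension", hypertension),
        ("diabetes", diabetes),
        ("hypercholesterolemia", hypercholesterolemia),
    ):
        if v not in (0, 1, True, False):
            raise ValueError(f"{name} must be 0/1, got {v!r}")
    if smoking not in SMOKING_LEVELS:
        raise ValueError(f"smoking must be one of {SMOKING_LEVELS}, got {smoking!r}")
    return int(hypertension) + int(diabetes) + int(hypercholesterolemia) + int(
        smoking != "never"
    )


class CohortTable:
    """Validated per-patient longitudinal cohort table.

    One row per patient with demographics, vascular risk factors, per-tissue
    baseline CVR, and baseline / year-1 outcome values (columns suffixed
    ``_baseline`` and ``_year1``).
    """

    def __init__(self, frame: pd.DataFrame) -> None:
        missing = [c for c in _BASE_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"cohort table lacks columns: {missing}")
        df = frame.reset_index(drop=True).copy()

        bad_sex = set(df["sex"].dropna()) - set(SEX_LEVELS)
        if bad_sex:
            raise ValueError(f"unknown sex levels: {sorted(bad_sex)}")
        bad_smoke = set(df["smoking"].dropna()) - set(SMOKING_LEVELS)
        if bad_smoke:
            raise ValueError(f"unknown smoking levels: {sorted(bad_smoke)}")
        for col in ("hypertension", "diabetes", "hypercholesterolemia", "recurrence"):
            vals = df[col].dropna()
            if not vals.isin([0, 1]).all():
                raise ValueError(f"{col} must be binary 0/1")
        for col in ("cvr_sgm", "cvr_nawm", "cvr_wmh"):
            if not np.all(np.isfinite(df[col].dropna())):
                raise ValueError(f"{col} contains non-finite values")
        for score, (lo, hi) in ORDINAL_RANGES.items():
            for suffix in ("baseline", "year1"):
                col = f"{score}_{suffix}"
                if col in df.columns:
                    vals = df[col].dropna()
                    if len(vals) and (vals.min() < lo or vals.max() > hi):
                        raise ValueError(f"{col} outside its range [{lo}, {hi}]")
        self.frame = df

    @classmethod
    def from_csv(cls, path) -> "CohortTable":
        return cls(pd.read_csv(Path(path)))

    def to_csv(self, path) -> None:
        self.frame.to_csv(Path(path), index=False)

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class TermResult:
    """One model term: point estimate, Wald 95% CI and p-value."""

    name: str
    estimate: float
    ci_low: float
    ci_high: float
    p: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError(f"CI does not bracket estimate for term {self.name!r}")
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"p-value out of (0, 1] for term {self.name!r}")


@dataclass(frozen=True)
class ModelResult:
    """Fitted association model: terms, sample size, diagnostics.

    ``terms`` reports regression coefficients (linear family) or odds ratios
    (ordinal and binomial families).  ``diagnostics`` carries residual and
    collinearity checks; they are reported, never auto-acted-on.
    """

    family: str
    outcome_name: str
    cvr_tissue: str
    terms: tuple[TermResult, ...]
    n_used: int
    transform_applied: str | None
    diagnostics: dict = field(default_factory=dict)
    standardized: bool = False
    _endog: pd.Series = field(default=None, repr=False, compare=False)
    _design: pd.DataFrame = field(default=None, repr=False, compare=False)

    def term(self, name: str) -> TermResult:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    @property
    def cvr_term(self) -> TermResult:
        return self.term("cvr")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "model": self.family,
                "outcome": self.outcome_name,
                "tissue": self.cvr_tissue,
                "term": t.name,
                "estimate": t.estimate,
                "ci_low": t.ci_low,
                "ci_high": t.ci_high,
                "p": t.p,
                "n_used": self.n_used,
            }
            for t in self.terms
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        kind = "B" if self.family == "linear" else "OR"
        head = (
            f"{self.family} model: {self.outcome_name} (1 y) ~ CVR[{self.cvr_tissue}]"
            f" + covariates   (n = {self.n_used}"
            f"{', standardized' if self.standardized else ''})"
        )
        lines = [head, "-" * len(head)]
        if self.transform_applied:
            lines.append(f"outcome transform: {self.transform_applied}")
        lines.append(f"{'term':<22}{kind:>12}{'95% CI':>26}{'p':>10}")
        for t in self.terms:
            ci = f"({t.ci_low:.4g}, {t.ci_high:.4g})"
            lines.append(f"{t.name:<22}{t.estimate:>12.4g}{ci:>26}{t.p:>10.3g}")
        for key, val in self.diagnostics.items():
            lines.append(f"[diag] {key}: {val:.4g}" if np.isscalar(val) else f"[diag] {key}: {val}")
        return "\n".join(lines)


def _as_frame(cohort) -> pd.DataFrame:
    if isinstance(cohort, CohortTable):
        return cohort.frame
    return CohortTable(cohort).frame


def _full_covariates(df: pd.DataFrame, cvr_col: str) -> pd.DataFrame:
    """Shared adjusted covariate block: CVR + demographics + risk factors."""
    X = pd.DataFrame(index=df.index)
    X["cvr"] = df[cvr_col].astype(float)
    X["age_years"] = df["age_years"].astype(float)
    X["sex_male"] = (df["sex"] == "male").astype(float)
    X["map_mmHg"] = df["map_mmHg"].astype(float)
    X["smoking_current"] = (df["smoking"] == "current").astype(float)
    X["smoking_ever"] = (df["smoking"] == "ever").astype(float)
    for col in ("hypertension", "diabetes", "hypercholesterolemia"):
        X[col] = df[col].astype(float)
    # NaN category indicators must not mask missing source data
    for col in ("sex", "smoking"):
        X.loc[df[col].isna(), [c for c in X.columns if c.startswith(col)]] = np.nan
    return X

def _clip_p(p: float) -> float:
    return float(min(max(p, 5e-324), 1.0))


def _terms_from_arrays(names, est, lo, hi, p) -> tuple[TermResult, ...]:
    return tuple(
        TermResult(n, float(e), float(l), float(h), _clip_p(pv))
        for n, e, l, h, pv in zip(names, est, lo, hi, p)
    )


def _check_rank(X: pd.DataFrame) -> None:
    arr = np.column_stack([np.ones(len(X)), X.to_numpy(float)])
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        raise ValueError("rank-deficient design matrix")


class LinearOutcomeModel:
    """OLS of a 1-year quantitative outcome on baseline CVR + covariates."""

    family = "linear"

    def __init__(
        self,
        cohort,
        outcome: str,
        cvr_tissue: str = "nawm",
        log_transform: bool | None = None,
        extra_covariates: tuple[str, ...] = (),
    ) -> None:
        if outcome not in LINEAR_OUTCOMES:
            raise ValueError(f"unknown linear outcome {outcome!r}")
        if cvr_tissue not in TISSUES:
            raise ValueError(f"unknown tissue {cvr_tissue!r}")
        self.df = _as_frame(cohort)
        self.outcome = outcome
        self.cvr_tissue = cvr_tissue
        self.log_transform = (
            LINEAR_OUTCOMES[outcome] if log_transform is None else bool(log_transform)
        )
        self.extra_covariates = tuple(extra_covariates)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "LinearOutcomeModel":
        return cls(CohortTable(frame), **kwargs)

    def _data(self) -> tuple[pd.Series, pd.DataFrame]:
        df = self.df
        y_col, b_col = f"{self.outcome}_year1", f"{self.outcome}_baseline"
        for col in (y_col, b_col):
            if col not in df.columns:
                raise ValueError(f"cohort table lacks column {col!r}")
        X = _full_covariates(df, f"cvr_{self.cvr_tissue}")
        if self.log_transform:
            y = pd.Series(log10_volume(df[y_col].to_numpy(float)), index=df.index)
            X.insert(1, "baseline", log10_volume(df[b_col].to_numpy(float)))
        else:
            y = df[y_col].astype(float)
            X.insert(1, "baseline", df[b_col].astype(float))
        for col in self.extra_covariates:
            X[col] = df[col].astype(float)
        keep = y.notna() & X.notna().all(axis=1)
        return y[keep], X[keep]

    def fit(self) -> ModelResult:
        y, X = self._data()
        if len(y) < MIN_N:
            raise ValueError(f"only {len(y)} complete cases; at least {MIN_N} required")
        _check_rank(X)
        res = sm.OLS(y.to_numpy(), sm.add_constant(X.to_numpy(float))).fit()
        names = ["const", *X.columns]
        ci = res.conf_int(alpha=0.05)  # t-based Wald interval
        terms = _terms_from_arrays(names, res.params, ci[:, 0], ci[:, 1], res.pvalues)

        resid = res.resid
        _, jb_p, _, _ = jarque_bera(resid)
        diagnostics = {"resid_jarque_bera_p": float(jb_p)}
        try:
            _, bp_p, _, _ = het_breuschpagan(resid, sm.add_constant(X.to_numpy(float)))
            diagnostics["het_breusch_pagan_p"] = float(bp_p)
        except (ValueError, np.linalg.LinAlgError):
            pass
        Xs = X.to_numpy(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            scaled = (Xs - Xs.mean(0)) / np.where(Xs.std(0) > 0, Xs.std(0), 1.0)
        diagnostics["design_condition_number"] = float(
            np.linalg.cond(np.column_stack([np.ones(len(X)), scaled]))
        )
        return ModelResult(
            family=self.family,
            outcome_name=self.outcome,
            cvr_tissue=self.cvr_tissue,
            terms=terms,
            n_used=int(len(y)),
            transform_applied="log10" if self.log_transform else None,
            diagnostics=diagnostics,
            _endog=y,
            _design=X,
        )


def _logistic_terms(names, params, bse, pvalues) -> tuple[TermResult, ...]:
    """Odds-ratio terms from log-odds estimates via normal Wald intervals."""
    if np.any(~np.isfinite(bse)) or np.any(~np.isfinite(params)):
        raise SeparationError("non-finite coefficient or standard error")
    z = 1.959963984540054
    lo = np.exp(params - z * bse)
    hi = np.exp(params + z * bse)
    return _terms_from_arrays(names, np.exp(params), lo, hi, pvalues)


class OrdinalOutcomeModel:
    """Proportional-odds model of a 1-year ordinal score on CVR + covariates.

    Adjusted for the baseline score, the full covariate block, and baseline
    WMH volume (log10 %ICV); coefficients are reported as odds ratios for a
    higher category.
    """

    family = "ordinal"

    def __init__(
        self,
        cohort,
        outcome: str,
        cvr_tissue: str = "nawm",
        extra_covariates: tuple[str, ...] = (),
    ) -> None:
        if outcome not in ORDINAL_OUTCOMES:
            raise ValueError(f"outcome must be one of {ORDINAL_OUTCOMES}")
        if cvr_tissue not in TISSUES:
            raise ValueError(f"unknown tissue {cvr_tissue!r}")
        self.df = _as_frame(cohort)
        self.outcome = outcome
        self.cvr_tissue = cvr_tissue
        self.extra_covariates = tuple(extra_covariates)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "OrdinalOutcomeModel":
        return cls(CohortTable(frame), **kwargs)

    def _data(self) -> tuple[pd.Series, pd.DataFrame]:
        df = self.df
        y = df[f"{self.outcome}_year1"].astype(float)
        X = _full_covariates(df, f"cvr_{self.cvr_tissue}")
        X.insert(1, "baseline", df[f"{self.outcome}_baseline"].astype(float))
        X["wmh_baseline_log10"] = log10_volume(
            df["wmh_pct_icv_baseline"].to_numpy(float)
        )
        for col in self.extra_covariates:
            X[col] = df[col].astype(float)
        keep = y.notna() & X.notna().all(axis=1)
        return y[keep], X[keep]

    def fit(self) -> ModelResult:
        y, X = self._data()
        if len(y) < MIN_N:
            raise ValueError(f"only {len(y)} complete cases; at least {MIN_N} required")
        levels = np.unique(y)
        if levels.size < 3:
            raise ValueError(
                f"ordinal outcome {self.outcome!r} has {levels.size} observed levels; >= 3 required"
            )
        _check_rank(X)
        # fit on z-scored columns for conditioning; report on the original scale
        Xa = X.to_numpy(float)
        mu, sd = Xa.mean(axis=0), Xa.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        model = OrderedModel(y.to_numpy(), (Xa - mu) / sd, distr="logit")
        try:
            res = model.fit(method="lbfgs", maxiter=2000, disp=False)
        except (np.linalg.LinAlgError, PerfectSeparationError) as exc:
            raise SeparationError(str(exc)) from exc
        k = X.shape[1]
        params, bse, pvals = res.params[:k] / sd, res.bse[:k] / sd, res.pvalues[:k]
        if not res.mle_retvals.get("converged", True) or np.any(np.abs(params) > 1e3):
            raise SeparationError(
                "proportional-odds fit did not converge cleanly (possible separation)"
            )
        terms = _logistic_terms(list(X.columns), params, bse, pvals)
        return ModelResult(
            family=self.family,
            outcome_name=self.outcome,
            cvr_tissue=self.cvr_tissue,
            terms=terms,
            n_used=int(len(y)),
            transform_applied=None,
            diagnostics={"n_levels": int(levels.size)},
            _endog=y,
            _design=X,
        )


class BinomialOutcomeModel:
    """Logistic model of recurrent stroke/TIA or new infarct on CVR.

    Uses the reduced covariate set — baseline WMH volume (log10 %ICV), age,
    sex, MAP and the equal-weight VRF score — to limit overfitting with only
    ~30% events.
    """

    family = "binomial"
    outcome = "recurrence"

    def __init__(
        self, cohort, cvr_tissue: str = "nawm", extra_covariates: tuple[str, ...] = ()
    ) -> None:
        if cvr_tissue not in TISSUES:
            raise ValueError(f"unknown tissue {cvr_tissue!r}")
        self.df = _as_frame(cohort)
        self.cvr_tissue = cvr_tissue
        self.extra_covariates = tuple(extra_covariates)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "BinomialOutcomeModel":
        return cls(CohortTable(frame), **kwargs)

    def _data(self) -> tuple[pd.Series, pd.DataFrame]:
        df = self.df
        y = df["recurrence"].astype(float)
        X = pd.DataFrame(index=df.index)
        X["cvr"] = df[f"cvr_{self.cvr_tissue}"].astype(float)
        X["wmh_baseline_log10"] = log10_volume(
            df["wmh_pct_icv_baseline"].to_numpy(float)
        )
        X["age_years"] = df["age_years"].astype(float)
        X["sex_male"] = (df["sex"] == "male").astype(float)
        X.loc[df["sex"].isna(), "sex_male"] = np.nan
        X["map_mmHg"] = df["map_mmHg"].astype(float)
        score = [
            vrf_score(h, d, c, s)
            if not (pd.isna(h) or pd.isna(d) or pd.isna(c) or pd.isna(s))
            else np.nan
            for h, d, c, s in zip(
                df["hypertension"], df["diabetes"], df["hypercholesterolemia"], df["smoking"]
            )
        ]
        X["vrf_score"] = score
        for col in self.extra_covariates:
            X[col] = df[col].astype(float)
        keep = y.notna() & X.notna().all(axis=1)
        return y[keep], X[keep]

    def fit(self) -> ModelResult:
        y, X = self._data()
        if len(y) < MIN_N:
            raise ValueError(f"only {len(y)} complete cases; at least {MIN_N} required")
        if y.nunique() < 2:
            raise ValueError("recurrence outcome has a single class; cannot fit")
        _check_rank(X)
        model = sm.Logit(y.to_numpy(), sm.add_constant(X.to_numpy(float)))
        try:
            res = model.fit(disp=0, maxiter=200)
        except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
            raise SeparationError(str(exc)) from exc
        if not res.mle_retvals.get("converged", True):
            raise SeparationError("logistic fit did not converge (possible separation)")
        names = ["const", *X.columns]
        terms = _logistic_terms(names, res.params, res.bse, res.pvalues)
        return ModelResult(
            family=self.family,
            outcome_name=self.outcome,
            cvr_tissue=self.cvr_tissue,
            terms=terms,
            n_used=int(len(y)),
            transform_applied=None,
            diagnostics={"event_rate": float(y.mean())},
            _endog=y,
            _design=X,
        )


def fit_linear_outcome(
    cohort, outcome: str, cvr_tissue: str = "nawm", log_transform: bool | None = None,
    extra_covariates: tuple[str, ...] = (),
) -> ModelResult:
    """Fit the adjusted linear model; see :class:`LinearOutcomeModel`."""
    return LinearOutcomeModel(
        cohort, outcome, cvr_tissue, log_transform, extra_covariates
    ).fit()


def fit_ordinal_outcome(
    cohort, outcome: str, cvr_tissue: str = "nawm",
    extra_covariates: tuple[str, ...] = (),
) -> ModelResult:
    """Fit the proportional-odds model; see :class:`OrdinalOutcomeModel`."""
    return OrdinalOutcomeModel(cohort, outcome, cvr_tissue, extra_covariates).fit()


def fit_binomial_outcome(
    cohort, cvr_tissue: str = "nawm", extra_covariates: tuple[str, ...] = ()
) -> ModelResult:
    """Fit the logistic recurrence model; see :class:`BinomialOutcomeModel`."""
    return BinomialOutcomeModel(cohort, cvr_tissue, extra_covariates).fit()


_BINARY_OK = {0.0, 1.0}


def standardize_coefficients(result: ModelResult, cohort=None) -> ModelResult:
    """Refit with continuous predictors z-scored; binary predictors untouched.

    The outcome is left on its own scale.  Standardized coefficients are
    comparable across predictors measured in different units (forest-plot
    form).  ``cohort`` is accepted for API symmetry; the cached design of the
    fitted model is what gets standardized.
    """
    if result._design is None or result._endog is None:
        raise ValueError("result carries no design to standardize")
    X = result._design.copy()
    for col in X.columns:
        vals = X[col].to_numpy(float)
        uniq = set(np.unique(vals))
        if uniq <= _BINARY_OK:
            continue  # binary dummy: leave on its natural scale
        sd = vals.std(ddof=0)
        if sd == 0:
            raise ValueError(f"zero-variance predictor {col!r}")
        X[col] = (vals - vals.mean()) / sd

    y = result._endog
    if result.family == "linear":
        res = sm.OLS(y.to_numpy(), sm.add_constant(X.to_numpy(float))).fit()
        names = ["const", *X.columns]
        ci = res.conf_int(alpha=0.05)
        terms = _terms_from_arrays(names, res.params, ci[:, 0], ci[:, 1], res.pvalues)
    elif result.family == "binomial":
        res = sm.Logit(y.to_numpy(), sm.add_constant(X.to_numpy(float))).fit(
            disp=0, maxiter=200
        )
        terms = _logistic_terms(["const", *X.columns], res.params, res.bse, res.pvalues)
    elif result.family == "ordinal":
        model = OrderedModel(y.to_numpy(), X.to_numpy(float), distr="logit")
        res = model.fit(method="lbfgs", maxiter=500, disp=False)
        k = X.shape[1]
        terms = _logistic_terms(
            list(X.columns), res.params[:k], res.bse[:k], res.pvalues[:k]
        )
    else:  # pragma: no cover - families are closed
        raise ValueError(f"unknown family {result.family!r}")

    return ModelResult(
        family=result.family,
        outcome_name=result.outcome_name,
        cvr_tissue=result.cvr_tissue,
        terms=terms,
        n_used=result.n_used,
        transform_applied=result.transform_applied,
        diagnostics=dict(result.diagnostics),
        standardized=True,
        _endog=y,
        _design=X,
    )
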