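# Methods

## CVR estimation

A block-design hypercapnic challenge alternates medical air and 6% CO₂
(default blocks 2-3-2-3-2 minutes) while gradient-echo EPI volumes are
acquired every TR = 1.55 s; `build_paradigm` labels each volume by the gas
block containing its centre time (v + 0.5)·TR. The breath-sampled EtCO₂
trace is linearly interpolated at volume centres (`resample_etco2`);
recordings spanning less than half the scan are rejected as unusable.
Breath-level structure is below the TR, so linear interpolation loses
nothing the model could use.

The ROI-mean BOLD series is regressed on an intercept, the delay-shifted
EtCO₂ regressor and a linear drift (the volume index). The delay grid runs
over integer TR multiples from −10 TR to +40 TR (−15.5 s … +62 s): the BOLD
response lags the gas stimulus, so the grid is generous on the positive
side while keeping a short negative margin as a sanity check; 0 is always
included. Shifted samples pushed past the series edges hold the edge value,
so all delays are fit on identical sample counts and their residual sums of
squares are directly comparable; the optimum is the minimal-SSR delay, with
exact floating-point comparison and ties resolved to the smallest delay.
CVR = 100·β/BOLD₀ in %/mm Hg, with BOLD₀ the mean of the first 30 volumes
of the opening air block (the first air block by definition, for
determinism). A zero-variance BOLD series yields CVR = 0 and R² = 0 with a
warning, and the (meaningless) delay is reported as the smallest grid value
rather than NaN. An explicit intercept is used rather than demeaned
regressors; β is identical either way.

### Estimator precision at single-series scale

With noise at 0.5% of baseline on one series (no spatial averaging), the
OLS standard error of CVR at NAWM-like reactivity (0.042 %/mm Hg, EtCO₂
excursion 8 mm Hg) is ≈ 0.006 %/mm Hg — a median absolute error of ≈ 10% of
the true value even when the delay is known. The delay itself is weakly
identified: with exponential EtCO₂ transitions (τ = 15 s) the regressor
shifted by one TR (1.55 s) is almost collinear with the unshifted one, so
single-series delay estimates scatter widely. Practical CVR maps rely on
ROI averaging: pooling a few hundred voxels divides the series noise by
√n_voxels, after which both CVR and delay are recovered tightly (the
end-to-end pipeline test recovers all three tissue CVRs within a few
percent and the delays exactly). The acceptance script reports both the
single-series Monte-Carlo error and the ROI-level recoveries so this
distinction stays visible.

## Mask conditioning

All morphology uses axis-aligned box structuring elements: the stated
millimetre extents are per-direction, which a box realises exactly (a
point dilated by 5/4/4 mm on a 1 mm grid becomes an 11×9×9 box).
Millimetre extents convert to voxel half-widths by round-half-up of
mm/voxel_mm per axis, minimum one voxel for a positive extent. Anatomical
directions (left–right, anterior–posterior, superior–inferior) are resolved
through explicit axis labels taken from the NIfTI header orientation, never
guessed from array order — the 5 vs 4 mm anisotropy of the ventricle
dilation is meaningless otherwise. Voxels beyond the grid border count as
background, so erosion is anti-extensive even at the edge of the field of
view.

The conditioning chain: SGM and NAWM eroded 1 mm (partial-volume
protection); ventricles dilated 5 mm LR / 4 mm AP / 4 mm SI and subtracted
from the eroded NAWM and from WMH (periventricular large-vessel exclusion);
an optional vein mask subtracted from all three. An empty final mask raises
an error — that subject contributes no CVR for that tissue. Registration
estimation is out of scope: an affine may be supplied (identity by default)
and masks are carried to the BOLD grid by nearest-neighbour sampling of
each BOLD voxel centre mapped through the affines.

## Volumetrics

WMH and brain volumes are normalized to intracranial volume (%ICV), PVS
volumes to their segmentation region (%ROIV); the identity
normalized = 100·raw/reference is exact. Volumes are log₁₀-transformed
before regression; zero volumes are floored at 1e-4% rather than excluded,
so patients without lesions stay in the sample (exclusion would silently
change n). One-year change is summarised as the median and quartiles of
paired follow-up − baseline differences, with linear interpolation between
order statistics as the quantile rule (conventions differ, so it is pinned
here).

## Association models

All families share the adjusted covariate block: baseline CVR of one
tissue, age, sex (female reference), MAP, smoking as two dummies
(current, ever vs never), hypertension, diabetes, hypercholesterolemia.
Linear models add the outcome's baseline value; ordinal models add the
baseline score and baseline WMH volume (log₁₀ %ICV); the binomial
recurrence model uses the reduced set {CVR, baseline WMH, age, sex, MAP,
equal-weight VRF score} since only ~30% of patients have events. In the
VRF score smoking is binarized (ever/current vs never); in the adjusted
models it keeps all three levels.

Intervals are Wald throughout: t-based for OLS, normal-approximation for
the logistic families, with odds ratios exp(coefficient). Missing data are
handled complete-case per model; no imputation. A minimum of 20 complete
cases is required, preventing silently meaningless fits on toy inputs.
Rank-deficient designs are rejected; logistic fits that fail to converge or
produce non-finite standard errors raise a separation error instead of
reporting penalized or runaway estimates. Linear-model diagnostics
(Jarque–Bera residual normality, Breusch–Pagan heteroscedasticity,
standardized-design condition number) are attached to every result but
never auto-acted-on.

The proportional-odds model is optimized on internally z-scored columns and
the coefficients are mapped back to the original scale (a pure
reparametrization: estimates, SEs and p-values are unchanged, but the
optimizer sees a well-conditioned problem — CVR near 0.04 next to MAP near
105 otherwise stalls quasi-Newton steps).

`standardize_coefficients` refits with continuous predictors z-scored and
binary dummies untouched; the outcome keeps its own scale, so standardized
linear coefficients equal raw B × SD(predictor). This is the forest-plot
form for comparing effects across tissues.

## Synthetic data generator

The generator is the exact inverse of the estimation model, so it doubles
as a correctness oracle:

* **EtCO₂**: baseline 40 mm Hg rising by Δ = 8 mm Hg inside CO₂ blocks via
  exponential approach with τ = 15 s, sampled every 4 s (a breath).
  Plausible values for a 6% CO₂ challenge — artifact defaults, not measured
  cohort values. τ → 0 gives an ideal square wave.
* **BOLD**: B₀·(1 + (CVR/100)·(EtCO₂(t−δ) − its first-30-volume mean)) +
  drift·(t − its first-30-volume mean) + Gaussian noise. Centring both
  terms on the baseline window makes the noiseless baseline exactly B₀, so
  the estimator returns the generating CVR and delay exactly whenever δ is
  on the grid and noise is zero. Noiseless generation with an off-grid δ is
  rejected rather than silently breaking that contract.
* **Mask phantoms**: nested ellipsoids on a 32³ grid of 1 mm isotropic
  voxels — brain shell ⊃ NAWM shell, lateral SGM blobs, WMH blobs abutting
  central ventricles, a vein line crossing one SGM blob. The geometry is a
  deep-brain cartoon, chosen so the fixed 5/4/4 mm ventricle dilation
  genuinely bites into periventricular WMH yet every conditioned ROI stays
  non-empty. 1 mm voxels keep the millimetre→voxel conversions exact; the
  grid is far coarser than real acquisitions and carries no partial-volume,
  motion, or susceptibility structure.
* **Cohorts**: covariate marginals matched to the study population (age
  normal 65.8 ± 11.2 truncated 35–95, 32% female, MAP ≈ 105 ± 12.6, smoking
  45/39/16% never/ever/current, hypertension 72%, diabetes 20%,
  hypercholesterolemia 72%); per-tissue CVR lognormal matched to the
  reported medians and IQRs (e.g. NAWM median 0.042, SGM 0.171, WMH
  0.040 %/mm Hg), sharing a Gaussian copula with age (corr −0.3 by default)
  so covariate adjustment actually matters. Continuous 1-year outcomes
  follow the same linear model the analysis fits (unit baseline
  coefficient, configurable CVR effect through one designated tissue —
  default NAWM with −1.14 on log₁₀ WMH, −2.12/−1.93/−1.90 on PVS volumes —
  plus a small age effect and Gaussian noise), so estimates are unbiased
  and CI coverage is nominal under the generator. Ordinal scores are drawn
  by proportional-odds inversion around their baseline marginals; the CVR
  effect on ordinal and recurrence outcomes defaults to zero, matching the
  null findings for those outcomes; recurrence prevalence is calibrated to
  29% by solving for the logistic intercept. Counts (lacunes, microbleeds)
  gain Poisson increments with ~8–10% of patients affected.

What passing tests show — and don't: the generator proves the chain of
estimators recovers its own generating process (identifiability,
calibration, type-I error control as wired). It does not emulate scanner
physics, motion, segmentation error, non-random dropout, or model
misspecification; performance on real data depends on those.

A single seed drives everything; pipeline stages derive per-stage seeds by
fixed offsets so any stage re-runs in isolation reproducibly.

## Numerical choices

* Delay ties: smallest delay, exact float comparison (identical sample
  counts make SSRs directly comparable, so no epsilon is needed).
* mm→voxel: round-half-up, minimum 1 voxel for positive extents.
* log₁₀ floor: 1e-4% before transforming normalized volumes.
* Quantiles: linear interpolation between order statistics.
* p-values are clipped into (0, 1] so that exact fits (zero residual)
  report the smallest positive float rather than 0.
* OLS via `numpy.linalg.lstsq` inside the delay search (speed), statsmodels
  for the association families (inference machinery).

## Known limitations

* Single-series delay estimates are unreliable at low SNR (see above); CVR
  itself is more robust because β at neighbouring delays is similar.
* Only two visits are modelled; no trajectories, no mixed effects.
* No multiple-testing correction across the outcome × tissue grid, by
  design — estimates and CIs are reported per model.
* Separation in logistic models aborts the fit; no penalized fallback.
* Nearest-neighbour mask resampling is faithful to binary masks but
  aliases at large voxel-size ratios.
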