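# Methods

## Pharmacokinetic model

Organ activity after injection is modeled as the difference of two
exponentials, each carrying the physical decay of ¹⁷⁷Lu:

    A(t) = A₁·exp(−(λ₁+λ_phys)t) − A₂·exp(−(λ₂+λ_phys)t)

* `t` — hours post-injection. Hours are the time unit everywhere; the
  6.65 d physical half-life is converted once to 159.6 h and stored
  (`PhysicalDecay.lu177()`), never re-derived ad hoc.
* `A₁` (MBq), `λ₁` (1/h) — washout amplitude and biological rate. The
  effective half-life is `T_eff = ln2/(λ₁+λ_phys)`.
* `A₂` (MBq), `λ₂` (1/h) — uptake amplitude and rate, fixed to per-organ
  population values during fitting (2 free parameters per curve).

The model is signed: during uptake (`A₂ > A₁` at small `t`) it can be
negative. The evaluator returns the signed value; only the synthetic
generator clamps observed activities at zero. This keeps the mathematics
faithful and isolates physical plausibility in data generation.

TIA has the closed form `Ã = A₁·T_eff/ln2 − A₂/(λ₂+λ_phys)`; an adaptive
quadrature route (`numeric_tia`, scipy `quad` on [0, ∞)) serves as an
independent numerical oracle and must agree to 1e-6 relative (in practice
~1e-14).

## MTP fitting

Curves need ≥3 samples. The fit is bounded least squares (scipy
`least_squares`, trf) over `(A₁, λ₁)`; `(A₂, λ₂)` come from a required
prior file. Choices where no convention existed:

* **Objective** — unweighted residuals by default; optional relative
  (1/activity) weighting.
* **Initialization** — log-linear regression on the last ≤3
  positive-activity samples (where the fast uptake term has died away),
  plus a small fixed multiplicative grid on λ₁ (×0.25, ×4) and one
  conservative start; a deterministic list, so fits are reproducible.
* **Bounds** — λ₁ ∈ [0, 10 h⁻¹]. The A₁ bound is 10× the *larger* of the
  maximum observed activity and the log-linear back-extrapolated
  amplitude. Bounding by observed activity alone fails for late-only
  schedules of fast-clearing organs (e.g. spleen sampled only at ≥69 h,
  where every sample sits two orders of magnitude below A₁); the
  extrapolated bound fixes that while staying generous.
* Whether clinical fits constrained `A₁ > A₂` is unknown; the fit is
  unconstrained in that respect and diagnostics carry the fitted values.

With noiseless in-model data, parameters recover to machine precision for
every organ and ≥3-point schedule; at 5% multiplicative noise the median
T_eff error is ~3–4%.

## Single-time-point estimators

* **Hänscheid**: `Ã = (1/ln2)·A(t_sc)·2·t_sc`. For mono-exponential truth
  the error ratio is `x·2^(1−x)` with `x = t_sc/T_eff`: exact at `x = 1`,
  +6.1% at `x = 1/ln2`, −11.6% at `x = 2.5`. The validity window
  [0.75, 2.5]×T_eff is treated as a closed interval; out-of-window
  estimates (notably 2 h) are computed but flagged `out_of_method`.
* **iSTP**: the initial activity is reconstructed by mono-exponential
  back-extrapolation `A₀ = A(t_sc)·2^(t_sc/T_eff)` with the predicted
  T_eff, then integrated analytically: `Ã = A₀·T_eff/ln2`. The integrand
  contains a single exponential, so the uptake term is deliberately
  omitted from the reconstruction; an optional variant adds the population
  uptake term back before extrapolation and subtracts its integral
  (`uptake_prior=` argument). With a perfectly predicted T_eff and
  mono-exponential truth, the estimate is exact at every scan time.

## Effective-half-life predictor

One model per organ: median imputation → zero-variance guard →
standardization → RBF-kernel SVR, all inside one scikit-learn pipeline so
every statistic is fitted on training rows only. Predictions are floored
at 1 h (a physically meaningless sub-hour half-life would otherwise
explode the back-extrapolation).

* Features: age (y), weight (kg), PSA (ng/mL), LDH, creatinine,
  hemoglobin, SUV_mean of left/right kidney, liver, spleen and urinary
  bladder, cycle index, optional injected PET activity, and a one-hot
  organ-condition class with an explicit category list (unknown categories
  rejected).
* Hyperparameters: C ∈ {1, 10, 100}, ε ∈ {0.1, 0.5, 2} h,
  γ ∈ {scale, 0.01, 0.1}, selected by inner 3-fold CV minimizing mean
  absolute percentage error; ties break toward smaller C then larger ε
  (stronger regularization), then γ, for full determinism.
* Validation: 10-fold CV. "ME" is the mean absolute percentage error per
  fold, summarized as mean ± SD across folds; the signed bias is reported
  alongside. The default split is plain row-level shuffling; a
  `by_patient` grouping is available because one patient's cycles are
  correlated and row-level splitting lets them straddle folds.
* Prediction modes: `per_cycle` uses each cycle's own pretherapy features;
  `first_cycle_only` substitutes the patient's cycle-1 features for all
  cycles (single pretherapy PET for the whole treatment). Only the cycle
  index keeps its true value — it is known without imaging. Patients
  lacking a cycle-1 row are excluded from that mode with a logged reason.

## Dosimetry

`D(target) = Σ_source Ã_source·S(target←source)` with S-values in
Gy/(MBq·h), so the product with TIA in MBq·h yields Gy directly. The
S-value file declares its units and the reader validates the declaration —
"dose per decay" shorthands invite silent 3.6×10⁶ unit errors. Cross-organ
terms are included by default; absent cross-terms can be treated as zero
only by explicit opt-in. The shipped 4-organ matrix is synthetic, scaled
so doses land in the few-Gy (kidneys), sub-Gy (spleen), centi-Gy (liver)
ranges expected for this therapy.

## Evaluation

`RAD = |θ_STP/θ_MTP − 1|·100%` (the signed version is kept for bias
analysis; references ≤0 are excluded with a logged count). Aggregations:
per organ × method × early scan time {2, 20, 43, 69} h, and per cycle
group {1, 2, 3, ≥4}. Paired comparisons use the Wilcoxon signed-rank test
(zeros dropped by default, Pratt optional), unpaired ones Mann–Whitney U;
below 14 (non-zero / combined) observations the p-value is exact —
full-enumeration permutation, valid under ties; singleton groups fall back
to the exact U distribution — and the tie-corrected normal approximation
is used above. Significance is two-sided at P < 0.05, uncorrected.

## Synthetic cohort generator

The generator emulates the statistical structure the method assumes, not
any patient:

* **Kinetics** — per-organ T_eff truncated-normal: left kidney 35 ± 16 h
  on [7, 65], right kidney 34 ± 16 on [7, 65], liver 11 ± 4 on [6, 25],
  spleen 9 ± 4 on [5, 25]. Truncated normal is the simplest distribution
  honoring a "mean ± SD (min–max)" summary. λ₁ is back-solved from T_eff;
  A₁ scales the injected activity (7.3 ± 0.3 GBq) by an organ uptake
  fraction (kidneys 2%, liver 1.5%, spleen 0.5% — sized for
  kidney-dominant PSMA uptake) with 20% lognormal inter-subject spread;
  (A₂, λ₂) come from the synthetic prior, calibrated so uptake peaks
  before 2 h.
* **Sampling** — 3–5 distinct times from {2, 20, 43, 69, 144, 168} h
  (the clinical ">165 h" point represented as 168 h), early times
  weighted higher; multiplicative lognormal noise with CV 5% by default,
  calibrated to unit mean.
* **Cohort shape** — 22 patients; cycle counts drawn so the expected
  per-cycle-group patient counts follow the published 20/12/6/4 attrition.
* **Covariates** — age 69 ± 9 y, weight 82.3 ± 10.6 kg, PSA on
  [0.1, 2936] ng/mL, LDH on [161, 664], creatinine on [0.5, 2.0],
  hemoglobin on [8.7, 15.2], all truncated normal.
* **Feature link** — organ SUV_mean = a + b·ln(T_eff) + noise, with
  per-organ noise SD ≈ 8% of the slope so every organ carries the same
  strong, learnable signal; the bladder SUV is anti-correlated with mean
  kidney T_eff as a renal-clearance proxy. A global `link_noise_scale`
  degrades the signal for ablations. **This link is an invention required
  for testability** — the true correlation structure between pretherapy
  features and organ kinetics is unknown, so passing predictor tests shows
  the pipeline learns a planted signal without leakage, not that clinical
  features predict clinical T_eff.

What the generator does *not* emulate: image-level effects
(reconstruction, partial volume, segmentation error), inter-organ kinetic
correlation beyond the shared injected activity, disease progression
across cycles (labs are redrawn i.i.d.), and any real feature–kinetics
physiology.

## Determinism and provenance

All randomness flows from one integer seed through numpy `SeedSequence`.
Scenario bundles are byte-identical across reruns with the same
configuration; every output file carries the package version, seed and a
hash of the scientific configuration (output paths excluded from the
hash).

## Problem sizes

Default analysis sizes, chosen to make the statistical checks stable at
interactive cost: 100 random parameter sets for the TIA oracle agreement;
~200 curves (50 cycles × 4 organs) for noisy fit recovery; ~200
patient-cycles for predictor cross-validation; a 22-patient-shaped cohort
for the scenario runs; 20 seeds × 3 noise scales (120-cycle cohorts, fixed
SVR hyperparameters) for the noise-monotonicity check — the full inner
grid search is reserved for the headline CV estimate, where selection
matters.

## Known limitations

* The population prior and S-values are synthetic fixtures; absolute dose
  values have fixture-dependent scale (relative comparisons, RAD, and all
  recovery properties are scale-free).
* The iSTP A₀ reconstruction assumes pure mono-exponential washout at the
  scan time; at 2 h, residual uptake biases A₀ low for organs with slow
  uptake (the optional uptake-corrected variant addresses this at the
  cost of trusting the population prior).
* The iSTP error grows exponentially with
  `t_sc·(1/T_eff_pred − 1/T_eff_true)`: a badly underpredicted half-life
  in the lower tail of the kidney distribution can turn a 69 h scan into a
  many-orders-of-magnitude TIA overestimate. The per-organ/per-t_sc tables
  expose this; the scenario headline summaries therefore aggregate the
  2 and 20 h scans and report a median over all four times rather than an
  all-time-point mean, which a single tail case can dominate.
* Plain 10-fold CV lets one patient's cycles appear in different folds;
  the `by_patient` mode exists precisely because this can flatter the
  reported ME.
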