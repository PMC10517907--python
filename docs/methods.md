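# Methods

## Signal models

Let S(b) be the DWI signal at diffusion weighting b (s/mm²) and S0 the
signal at b = 0. Three decay models are fitted per voxel over the
protocol b-values {0, 50, 100, 150, 200, 500, 800} s/mm²:

* **Mono-exponential:** `S(b) = S0·exp(−b·ADC)`. Fitted by log-linear
  least squares over all b-values; any non-positive sample marks the
  voxel unfit (NaN) rather than raising.
* **IVIM biexponential:** `S(b) = S0[(1−f)·e^{−b·D} + f·e^{−b·(D+D*)}]`,
  with f the vascular volume fraction, D the tissue diffusivity, and D*
  the decay-rate excess of the vascular pool (so the fast pool decays at
  D + D*, always ≥ D).
* **Stretched exponential:** implemented as `S(b) = S0·exp(−(b·DDC)^α)`,
  the standard Kohlrausch form with the exponent applied to the product
  b·DDC. The algebraically different placement `S0·exp(−b·DDC)^α`
  collapses to a mono-exponential with rate α·DDC, making α
  unidentifiable, so it is not a usable model; this implementation choice
  is deliberate and load-bearing.

**Virtual MR elastography.** The surrogate stiffness is
`μ_diff = α_scale·ln(S_low/S_high) + β_shift` with α_scale = −9.8 kPa,
β_shift = 14 kPa and S_low, S_high the signals at b = 200 and
800 s/mm² (multiple acquisitions at a key b are averaged). Equal
signals give exactly the 14 kPa shift; because α_scale < 0, stronger
attenuation (freer diffusion) maps to lower stiffness. Non-positive key
signals yield NaN voxels.

## Fitting algorithms

The IVIM inverse problem is ill-conditioned in D*, so the default is a
**segmented** fit: (1) log-linear fit on b ≥ 200 s/mm² — the same
low/high split as the stiffness computation — gives D and the tissue
intercept; (2) f = 1 − intercept/S(b_min), where the S0 reference is
the mean of all volumes at the minimum b; (3) D* by bounded scalar
least squares on the full curve with f, D fixed. A **full** fit refines
(S0, f, D, D*) jointly by bounded trust-region least squares,
initialised from the segmented fit. The stretched fit optimises
(S0, DDC, α) with DDC initialised at the fitted ADC and α at 0.8.

Bounds (chosen to bracket physiological placental values): f ∈ [0, 1],
D ∈ [10⁻⁵, 5·10⁻³], D* ∈ [5·10⁻³, 0.5], DDC ∈ [10⁻⁵, 10⁻²] mm²/s,
α ∈ [0.01, 1]. If step 2 yields f ≤ 0 (noise can push the tissue
intercept above S0) the voxel is declared perfusion-free (f = 0, D*
undefined) rather than erroring. All fits are deterministic — no
randomness, fixed initialisation — and invariant to overall signal
scaling and to permutation of (volume, b) pairs. On noise-free forward
signals at the protocol b-values all parameters are recovered to ≪ 0.1 %
(D* ≪ 1 %), which the test suite asserts.

Internally diffusivities are in mm²/s; the reporting layer multiplies
by 10³ (and expresses f in %) to match the conventional
10⁻³ mm²/s scales.

## ROI summaries and reader agreement

A subject's value for each parameter is the mean over the masked,
successfully fitted voxels (NaN excluded; failures counted). The
default workflow fits voxelwise and then averages; fitting the
ROI-averaged signal instead is available through the same fitters by
passing the mean signal, but voxelwise-then-average is the documented
default since the stiffness maps are defined voxelwise.

Agreement between readers is ICC from the two-way ANOVA decomposition
(via pingouin): ICC(2,1), two-way random effects / absolute agreement /
single measurement, for two interchangeable readers; ICC(3,1), two-way
mixed / consistency, for repeated reads by one reader. Grades: ≥ 0.75
remarkable, 0.40–0.75 medium, < 0.40 poor (lower boundary of
"remarkable" inclusive). Zero between-subject variance leaves the ICC
undefined and flagged; missing cells are an error, never imputed.

## Cohort statistics

* **Group comparison.** Continuous variables pass a per-group
  Shapiro–Wilk test at α = 0.05; if both groups look normal a Welch
  t-test is used, otherwise a two-sided Mann–Whitney U. Categorical
  variables use Pearson chi-square, Yates-corrected for 2×2 tables.
  The Yates default reproduces the published preterm (p ≈ .003) and
  delivery-route (p ≈ .074) worked examples, while the published
  neonatal-sex p (.445) matches the *uncorrected* statistic — an
  internal inconsistency of the source analysis; we keep the corrected
  default and surface the discrepancy here rather than resolving it
  silently. No multiple-testing correction is applied (none was in the
  source analysis).
* **Logistic risk model.** Maximum-likelihood logistic regression of
  adverse outcome on ROI-mean parameters, with Wald CIs and p-values;
  odds ratio = exp(coefficient) per unit on the reporting scale.
  Separation is detected (fitted probabilities pinned to 0/1, or
  exploding coefficients) and flagged, with coefficients from the last
  stable iterate. Covariate selection mirrors the described procedure:
  all parameters significant univariately enter, then backward
  elimination on Wald p < 0.05.
* **ROC.** Empirical (trapezoidal) AUC — identical to the Mann–Whitney
  identity U/(n₁n₂) — with orientation chosen so AUC ≥ 0.5 unless fixed;
  95 % CI by DeLong's placement-value variance; cutoff maximising
  Youden's J, ties broken toward higher specificity. A closed-form
  binormal AUC `Φ(|Δμ|/√(σ₁²+σ₂²))` serves as the oracle for simulated
  normal cohorts. Constant scores are degenerate: AUC 0.5, no cutoff.
* **Gestational-age correlation.** Pearson and Spearman both supported;
  the pipeline defaults to Spearman (the procedural description names
  it) and the drivers can emit both, since the source is internally
  ambiguous about which was used.

## Synthetic data

The generator defines the study conditions:

* **Parameter-level cohorts.** Per-subject parameter vectors are drawn
  from each group's multivariate normal on the reporting scales, with
  the published group means ± SDs (adverse n = 20: μ_diff 5.47 ± 0.68
  kPa, f 23.56 ± 3.94 %, …; non-adverse n = 40: 4.89 ± 0.59, 28.44 ±
  5.98, …) and a configurable between-parameter correlation. The
  default correlation is the identity because the source reports no
  covariance — a consequence is that the combined μ_diff + f model's
  published AUC (0.895) is not reachable from published summaries alone;
  the combined-model *procedure* is exercised instead, and a positive
  correlation can be supplied to explore that regime. Draws are
  truncated to physical ranges (f ∈ (0,100) %, α ∈ (0,1], positive
  diffusivities and stiffness) by rejection sampling, preserving the
  distribution shape near a bound instead of piling mass on it.
  Clinical covariates follow the published group summaries (normals for
  age/GA/birth weight, published proportions for delivery route,
  preterm, sex).
* **μ_diff is its own axis.** Applying the stiffness formula to
  biexponential signals built from the published group-mean diffusion
  parameters gives ≈ 4.89 / 4.47 kPa — not the published 5.47 / 4.89 —
  so measured stiffness carries contrast beyond the fitted
  diffusivities. The cohort generator therefore draws μ_diff from its
  own published distribution rather than deriving it from the signal
  model; signal-level phantoms are used for fit-recovery checks,
  parameter-level cohorts for the statistics.
* **Signal-level phantoms.** Homogeneous regions generated from any of
  the forward models at the protocol b-values, with Gaussian
  (N(0, σ·S0), clipped at zero) or Rician (|S + n₁ + i·n₂|) noise; the
  Rician floor σ√(π/2) at vanishing signal is reproduced and tested.
  The default noise level is σ = 2 % of S0, a typical placental DWI SNR
  regime. Phantom geometry is abstract (boxes/half-volumes), not
  anatomical.
* **Reader replicates.** Rater k reads subject i as
  truth_i + bias_k + N(0, σ_reader²), giving the textbook
  variance-component limit ICC → σ_subject²/(σ_subject² + σ_reader²)
  that the tests verify.

What passing tests show — and don't. Synthetic cohorts are exactly
(truncated-)normal with known correlation; real parameter distributions
may be skewed, heteroscedastic and correlated in unknown ways, and real
DWI carries motion, registration error and spatially varying noise that
the phantoms deliberately omit. The tests therefore validate the
estimators and the statistical machinery, not the clinical effect sizes.

## Problem sizes and numerical choices

The cohort-scale AUC experiment uses 2,000 simulated 20-vs-40 cohorts
(Monte-Carlo SE ≈ 0.0015, comfortably below the published-CI widths);
generator calibration uses 10⁵ draws (SE of the mean ≈ 0.002 kPa);
phantom grids are small (tens of voxels) since each voxel is an
independent fit. Optimiser tolerances are set to 10⁻¹⁴ (xtol/ftol/gtol)
so noise-free recovery is limited by conditioning, not stopping rules.
Seeds are explicit everywhere; identical seeds reproduce every output
bit-for-bit, and the pipeline writes a manifest (seed, config hash,
package versions) sufficient to reproduce a run.

## Known limitations

No DICOM ingestion, motion/eddy correction, registration or
auto-segmentation: masks must share the DWI grid exactly. No
tri-exponential, kurtosis or Bayesian IVIM variants, and no spatial
regularisation. The ICC form used for the published agreement table is
not stated in the source; ICC(2,1)/ICC(3,1) are conventional defaults
for the described two-reader design, and other choices would shift
agreement values. Sample-specific published quantities (odds ratios
23.446 / 0.590, combined AUC 0.895, cutoffs 5.29 kPa / 25.03 %, exact
ICC magnitudes) depend on the unpublished subject-level data and are
out of reach by design; the procedures that produce them are fully
implemented and exercised on synthetic data.
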