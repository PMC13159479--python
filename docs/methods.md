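# Methods

This note records the models the package implements, the assumptions behind
them, the parameters that matter, and the choices made where the design was
genuinely open.  Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## 1. Exposure model

Application records are point events (field centroids) on a flat planar
square; geodesy is deliberately absent because the 500 m buffer logic is
scale-local.  For participant *i*, chemical *c*, year *t*:

    E_ict = Σ over applications of c in year t with
            ||(x,y)_app − (x,y)_address|| ≤ r, address active in t
            of pounds/acres

with r = 500 m, boundary inclusive, residential and workplace buffers
summed.  The window average divides Σ_t E_ict by (blood-draw year − 1974 + 1)
— years with no application count in the denominator.  Per chemical, the
threshold is the control median of window averages (numpy midpoint
convention); the indicator is **strictly greater than** the threshold, so
ties — common when most controls are unexposed and the median is 0 — score
zero.  The copper/OP counts are sums of indicators over the configured
chemical lists.

A field note on the count range: the study population this design mirrors
reports a copper score ranging 0–17 while listing 15 copper chemicals; the
mapping is not documented anywhere we could verify, so the package counts
over the configured chemical list (0–15 with defaults) and leaves the
discrepancy visible rather than inventing extra indicators.

## 2. Synthetic cohort (the stated world)

Defaults mirror the population the method was developed for: 569 cases and
237 controls; cases ≈ 3.1 years older (70.5 vs 67.4); 59.8% male; 86.2%
European ancestry; smoking 49.3/45.4/5.3% never/former/current; two
recruitment waves; six blood-cell fractions drawn Dirichlet around
whole-blood proportions.  Every categorical level is guaranteed to occur
within each disease stratum (deterministic assignment of the first few
participants per stratum) so stratified adjustment designs stay full rank
even at test-scale cohorts.

Copper and OP applications share spatial hotspots, with OP intensity a noisy
log-linear function of copper intensity; participants live near hotspots
with probability 0.6.  This induces a copper–OP count correlation of ≈ 0.8
— the central confounding structure the OP adjustment exists to address
(field reports put it near 0.76; the generator treats that as a qualitative
target, and the acceptance suite only requires > 0.4).

Methylation is generated on the logit (M-value) scale where covariate and
exposure effects are additive, then mapped through the inverse logit, so
beta values are strictly inside (0,1).  Baselines are a three-component
mixture (unmethylated/methylated/intermediate); per-probe covariate slopes
are Gaussian with per-covariate SDs (cell composition largest, 0.3 on the
logit scale); residual noise is N(0, noise_sd²) with noise_sd = 0.5 on the
logit scale.  `noise_sd` is defined on the logit scale because that is the
scale on which effects are additive.

**Effect calibration.**  The planted slope for target partial correlation r
is

    b = r′/√(1−r′²) · noise_sd / sd(c⊥),   r′ = r / 0.87

where c⊥ is the copper count residualized against the full adjustment design
(computed exactly inside the generator) and 0.87 is a fixed attenuation
constant measured once: the inverse-logit curvature plus 5/95 winsorization
shrink the realized beta-scale correlation by ~13% relative to the
logit-scale planting.  The constant was calibrated at the design condition
(r = 0.3, n = 300) and is not revisited per run.  DMR specs either give an
explicit per-unit-exposure logit shift or inherit the calibrated b with a
random sign.

**What the generator does not emulate:** probe-type (Infinium I/II)
distributional differences, spatial correlation of *noise* along the genome,
batch/plate artifacts beyond a wave covariate, detection p-values, and
missingness.  A green recovery test therefore establishes that the chain is
correct and calibrated under independent logit-normal noise with additive
effects — not that it is robust to array-specific artifacts.

## 3. Preprocessing

QC filtering removes any probe flagged cross-reactive, SNP-overlapping,
sex-chromosomal or non-CpG (defaults plant flags on ~28% of probes,
matching the attrition a real 450k filtering step produces).  Winsorization
clamps each feature to its 5th/95th percentile with **linear interpolation
of order statistics** (the k-th order statistic sits at quantile
(k−1)/(n−1)).  One consequence worth documenting: with interpolated
quantiles, winsorization is *exactly* idempotent only when 0.05·(n−1) is an
integer (the quantile then is an order statistic that clipping leaves in
place); otherwise a second pass can clip further, by at most one
inter-order-statistic gap.  The tests assert exact idempotence at the
integer case and the bounded version generally.

Residualization removes X = [1, age, sex, ancestry, smoking dummies, wave,
5 of 6 cell fractions, OP count] from every probe.  One cell fraction (the
granulocyte fraction by default, configurable) must be dropped because the
six sum to one.  Disease status is intentionally excluded from X —
methylation may be both a mediator and a consequence of disease, and
conditioning on it would open a collider path; instead the pipeline runs the
total sample and strata separately.  Two estimators are available:

- `ols` (default): per-feature least squares; residuals exactly orthogonal
  to X.
- `eb`: per-feature coefficients shrunk toward the across-feature mean with
  per-covariate prior variance τ̂²ⱼ = across-feature coefficient variance
  minus mean sampling variance (floored at 10⁻⁸), ridge-toward-prior form,
  intercept never shrunk, residuals re-centered.  The exact estimator behind
  the technique's usual software is not published, so `eb` is
  property-tested (shrinkage direction) and `ols` anchors the calibration
  tests.

## 4. EWAS statistics

**Frisch–Waugh exposure adjustment.** The exposure is residualized against
the same X before the per-probe regressions.  This is not cosmetic: the
copper and OP counts are strongly correlated and OP count is in X, so
regressing X-orthogonal residuals on the *raw* copper count would deflate
every t-statistic by ≈ (1 − R²_{copper|X}) and wreck null calibration
(λ ≈ 0.5 rather than 1).  With the adjusted exposure the per-probe simple
regression equals the full multiple-regression copper coefficient.

**Residual degrees of freedom.** For the same reason the per-probe variance
uses d = n − k − 1 (k = columns of X) rather than n − 2: the adjustment
already spent k degrees of freedom, and ignoring that biases s_g² low by
(n−k−1)/(n−2) and makes null tests measurably anticonservative (+0.004 on
the p < 0.05 rate at n = 300).

**Moderation.** (d₀, s₀²) solve the moment equations of the scaled-F model
for s_g²: with e_g = log s_g² − ψ(d/2) + log(d/2),

    ψ′(d₀/2) = var(e) − ψ′(d/2),    s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2))

(ψ, ψ′ di/trigamma; trigamma inverted by Newton).  When the observed spread
of log-variances is no larger than sampling alone implies, d₀ is capped at
a documented ceiling of 10⁶ (statistically "infinite": full pooling).
Moderated t has d + d₀ degrees of freedom; p-values are floored at the
smallest positive double.

**Inflation and empirical null.** λ = median(z²)/0.4549364 (median of χ²₁),
z from two-sided p with the slope's sign.  The empirical-null correction
fits a three-component Gaussian mixture by EM: a dominant null component and
two signal components constrained to opposite sides of the null mean *and at
least 2 null-SDs away from it*.  The separation constraint is what keeps the
mixture identifiable when there is little or no signal — without it the
signal components absorb central mass and bias the null SD low by ~5%.  It
does not bind when genuine signal sits ≳3 null-SDs out.  EM is initialized
from a 1-D k-means pass (centers at the median and extreme quantiles),
seeded, tolerance 10⁻⁸ on the log-likelihood, max 500 iterations;
non-convergence returns the last iterate with a flag.  Corrected statistics
are z′ = (z − μ̂₀)/σ̂₀.  Note that λ computed over *all* corrected statistics
stays above 1 whenever real signal is present (the signal mass shifts the
median χ²); calibration claims in the tests are therefore evaluated on
ground-truth null statistics, which only a simulation can identify.

**Significance rule.** The headline label follows the operational rule of
the motivating analysis: unadjusted p < 10⁻⁷, with BH-adjusted p emitted
alongside.  Whether reported p-values should come from the moderated
regression or from a bicor test is ambiguous in the source material; this
package reports moderated-t p-values with bicor as the effect scale.

## 5. DMR detection

Clusters are maximal runs of probes with inter-probe gaps ≤ 1 kb on one
chromosome.  Default smoothing is a truncated centered running mean (window
3); a tricube local-linear smoother is available.  The cutoff is the 0.99
quantile of genome-wide |smoothed slopes|; candidates are maximal
same-direction exceedance runs with ≥ 5 probes (the one region parameter the
motivating analysis pins).  The permutation null permutes the exposure
vector B times (default 250 in the API, 100 in the pipeline/demo — scaled
for test budgets) and pools **all** above-cutoff run areas, without the
min-probes filter; that makes the null pool larger and the p-values
conservative, which we prefer to the alternative (length-filtered nulls are
scarcer, and their scarcity would manufacture significance).  The pooled
p is (1 + #{null areas ≥ area}) / (1 + #null areas), never exactly zero.
Slopes for bump hunting are the unmoderated per-probe regression slopes on
the adjusted exposure — the same quantities the EWAS fits, before variance
shrinkage (shrinkage rescales t, not slopes, and areas live on the slope
scale).

## 6. Enrichment

The probability-weighting function bins genes into (up to) 10 quantile bins
of surviving-CpG count, takes per-bin selection proportions, smooths them
with weighted isotonic regression on the bin mean count (bias from probe
density is monotone in every data set we are aware of), floors weights at
ε = 10⁻³ and normalizes to mean 1.  A set's odds are mean weight inside vs
outside; the p-value is the exact Wallenius noncentral hypergeometric upper
tail computed by the sequential biased-urn recursion (O(N·n₁), exact to
float rounding; the distribution *is* the law of that urn process).  With
all weights equal the recursion reduces to the central hypergeometric, i.e.
Fisher's exact test.  BH runs within each category label (BP/CC/MF/pathway),
matching how set collections are usually reported.  Gene sets arrive as GMT
files; the description column carries the category label.  No ontology
graph or term-ancestry propagation — enrichment here is strictly set-level.

## 7. Pipeline and reproducibility

`RunConfig` (constructible from YAML) drives simulate → exposure →
preprocess → ewas (total + per-stratum) → dmr → enrich.  All randomness
derives from one root seed through fixed per-stage keys
(`default_rng([seed, stage_key])`), so stages are independently
reproducible and identical (config, seed) runs produce byte-identical
outputs — report files deliberately contain no wall-clock times or absolute
paths (timers go to the stderr log), and floats are written with a fixed
`%.8g` format.  Stratified tables re-residualize within the stratum before
fitting.  Stage failures raise `StageError` carrying the stage name.

## 8. Known limitations

- Point-in-circle exposure (no field polygons, no land-use weighting); a
  raw-pounds mode exists but the lbs/acre rate is the default and the only
  tested unit.
- The EB residualization estimator is a reasonable reconstruction, not a
  reimplementation of any specific package's internals.
- The empirical-null EM is a maximum-likelihood stand-in for the Bayesian
  Gibbs formulation it emulates; agreement is at the level of the recovered
  null parameters, not posterior draws.
- Permutation p-value resolution is bounded by the pooled null count; at
  B = 100 the smallest attainable p is ~10⁻⁴ on a 20k-probe study.
- Beta-scale heteroscedasticity near 0/1 is handled only implicitly (logit
  generation, winsorization); no explicit variance-stabilizing transform is
  applied at analysis time.
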