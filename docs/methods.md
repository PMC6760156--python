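# Methods

This note documents the models, conventions and design choices behind
`toothrqa`, in the spirit of a statistical software appendix. It states
no empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## 1. The synthetic cohort generator

### Signal model

Tooth elemental profiles are quasi-periodic, strictly positive metal:Ca
ratio series sampled along growth increments. No generative model for
them is established in the literature, so the generator uses the
simplest process whose one interpretable knob maps monotonically onto
the downstream recurrence measures:

    v(t) = b·s + A·sin(2π t / T + φ(t)) + η(t),    clipped at 0,

where

- `b` (`base_level`) is the element's characteristic ratio scale and `s`
  a subject-level factor (mean 1, SD 0.3, truncated ≥ 0.2);
- φ is a Brownian phase walk with per-step SD
  `phase_jitter_sd · (1 − regularity) · √Δt` (units: radians/√day);
- η is AR(1) noise with autoregression `ar_coeff` and innovation SD
  `noise_sd · (2 − regularity)`, initialized at its stationary variance.

`regularity ∈ [0, 1]` is the single dysregulation knob: at 1 the phase
walk vanishes and the cycle is exact; lowering it simultaneously
diffuses the phase and inflates the noise. A `marginal="lognormal"`
option exponentiates the cyclic + noise term instead, for users who
prefer a multiplicative ratio scale; the additive form is the default
because nothing in the source data constrains the choice and the
additive form keeps amplitude parameters in ratio units.

Sampling density: the number of locations per tooth is Poisson with mean
`n_points_mean = 152` (floored at 20), matching the reported average
sampling density of LA-ICP-MS transects; days are uniformly spaced over
`[day_min, day_max] = [−120, +200]`, bracketing the published example
traces (−106…+110 and −125…+187 days). RQA operates on sample index, so
the uniform grid is the honest default for increment-regular tooth data.

Default scales: `amplitude = 0.35·b`, `noise_sd = 0.05·b`,
`phase_jitter_sd = 1.0`, `period = 30` days, `ar_coeff = 0.3`,
`regularity = 0.8`. These were fixed once, by the design requirement
that the regularity knob span a scientifically meaningful determinism
range: visibly rhythmic control-like traces near the top of the DET
scale, noise-floor behaviour near the bottom, and a monotone mean-DET
response across the grid {0.2, 0.5, 0.8, 1.0} (asserted by the test
suite). Element base levels are plausible metal:Ca orders of magnitude
(e.g. Zn 5·10⁻⁴, Co 5·10⁻⁷); because the recurrence radius is calibrated
per matrix, only relative dynamics matter downstream.

### Cohort structure

The default cohort reproduces the motivating twin design: 30 complete
pairs, 1 triplet group (MZ), 11 singletons = 74 subjects, with diagnosis
counts TD 41 / ADHD 13 / ASD 8 / comorbid 12 permuted randomly across
subjects. Pairs alternate MZ/DZ deterministically so zygosity counts are
stable. Within a birth group, gestational length is shared and MZ
members are same-sex. Covariates: gestational days ~ N(246, 24) truncated
to [180, 300]; birth weight ~ N(2.4, 0.7) kg truncated ≥ 0.3 (truncation
bounds are plausibility choices); IQ drawn per diagnosis group from the
published group means/SDs.

Twin resemblance: co-twins mix a shared and an individual draw of both
the subject factor and a latent regularity deviation (SD 0.08) with
weight `twin_correlation` (MZ) or `twin_correlation/2` (DZ), default
0.5. This yields MZ within-pair correlations ≥ DZ ones (a population
property the tests check over 200 pairs) without committing to a full
ACE decomposition, which the pipeline does not need.

Effect injection: `pathway_effects[(diagnosis, key)]` shifts the
regularity of one element (`key = "Co"`) or of a zinc pair's partner
(`key = "Zn-Sn"` shifts Sn) for subjects with that diagnosis, before
clipping regularity to [0, 1]. Injecting on the generative knob — never
on the features — keeps parameter-recovery tests non-circular. Recovery
simulations use a shift of −0.4, chosen once as a clearly detectable
deficit at the simulated scale.

## 2. Recurrence quantification

Embedding defaults m = 3, τ = 1 follow common practice for short
biomarker series; the literature motivating this pipeline names its
toolbox but not its parameters, so these are declared choices, exposed
in `EmbeddingParams`. The radius is calibrated per matrix to a target
recurrence rate (default 0.10) — a fixed ε would be meaningless across
elements whose ratio scales differ by orders of magnitude. The radius is
the `target_rr` quantile of the off-diagonal pairwise distances;
the full (duplicated) off-diagonal multiset is used for both auto- and
cross-calibration, and aligned i = j pairs are excluded from
equal-length cross calibration, so a series crossed with itself
reproduces its auto-recurrence matrix exactly. Threshold comparisons
carry a 10⁻¹² relative tolerance so quantiles that land exactly on a
tied distance are not decided by last-bit noise.

Conventions (all configurable):

- Norm: Euclidean (max / Manhattan available).
- Theiler window: `w` masks diagonals with |i − j| < w; default w = 1 for
  auto-recurrence (excludes exactly the line of identity), 0 for
  cross-recurrence.
- `l_min = 2`; entropy in natural log.
- DET's denominator counts all recurrence points (every recurrent point
  lies on exactly one maximal diagonal run, possibly of length 1) — the
  standard convention; verbal definitions that contrast diagonal with
  vertical structures are ambiguous on this point.
- Recurrence time is type 2: the count-weighted mean length of maximal
  vertical white runs. Theiler-masked cells are neither recurrence nor
  whitespace; they break white runs.
- Features with an empty supporting histogram are explicitly missing
  (`None`/NaN), never 0.
- Series yielding fewer than 50 embedded points produce missing features
  in the cohort pipeline rather than unstable estimates.

Cross-recurrence alignment: both series are restricted to their
overlapping day interval, linearly interpolated onto a uniform grid of
length min of the two overlap point-counts, and z-normalized
independently — the minimal treatment that makes unequal-length,
unequal-scale series comparable. The radius is calibrated on the pooled
cross-distances.

The diagonal histogram is computed by a skew-scatter (all diagonals
become columns of one padded array, counted in a single run-length
pass); an independent cell-by-cell brute-force enumerator in the test
suite verifies exact equality on hundreds of random matrices.

## 3. Per-feature inference

Model: `y = β₀ + β_ADHD·1[ADHD or comorbid] + β_sex·male +
β_g·gest + β_bw·bw + β_ASD·1[ASD or comorbid] + u_pair + ε`, REML via
`statsmodels.MixedLM`, with singletons as their own clusters. ADHD and
ASD are non-exclusive indicators (comorbid subjects score 1 on both), so
β_ADHD is the ADHD main effect adjusted for ASD. Female is the reference
sex level. Zygosity and IQ are excluded from the default model (they are
recorded on `SubjectRecord` for users who want them). The ADHD test is a
Wald z test; small-sample degrees-of-freedom corrections
(Kenward–Roger/Satterthwaite) are out of scope and the calibration tests
quantify the consequence: type-I error ≈ 0.06 at 30 pairs, inside the
accepted [0.03, 0.07] band.

Outlier rule: values beyond ±2 sample SDs (single pass, mean/SD from the
unscreened column) are set missing. Which columns get screened is
governed by `outlier_mode`: the default `auto` screens columns failing a
Shapiro–Wilk normality check at α = 0.05; `all`/`none` force either
extreme. Screening precedes modeling and FDR.

FDR: Benjamini–Hochberg step-up applied independently within each
pathway stratum (one pathway's four measures per stratum), via
`statsmodels.multipletests`; hand-computed step-up values in the tests
are the independent oracle. Failed fits become flagged rows (error
string, `converged = False`) and are excluded from the adjustment — the
scan never aborts on a bad column.

## 4. Dimensionality reduction

PCA operates on centered/scaled complete-case rows (constant columns
dropped with a warning), i.e. correlation-matrix PCA, so eigenvalues sum
to the number of features. Retention combines the Kaiser rule with a
cumulative-variance cap: the retained set is the first
`min(#{λ > 1}, smallest k with cumulative share > 0.80)` components.
Per-component group tests are *ordinary* linear models of score on
diagnosis (TD reference) — deliberately not mixed models, mirroring the
original analysis's contrast between its feature-level and
component-level procedures; the discrepancy is noted here rather than
silently "fixed".

LDA solves the generalized eigenproblem `S_b w = λ S_w w` with
`scipy.linalg.eigh`, producing 3 axes for 4 classes, normalized in the
within-class metric (wᵀS_w w = 1) so axis scores are uncorrelated under
that metric. If S_w is singular or ill-conditioned (condition number >
10¹⁰ — plausible with ~60 features and barely more subjects) it is
shrunk toward its diagonal with coefficient 10⁻⁴ and a logged warning.
Complete-case exclusion applies (excluded subjects listed on the
result); an emptied class raises an error naming the class. Class priors
are proportional to observed sizes. Standardized loadings are Pearson
correlations between raw features and axis scores; zero-variance
features get missing loadings. Sign convention for every PC/LD axis:
oriented so its largest-|loading| feature loads positively, making
outputs reproducible across linear-algebra backends. `reclassify` (a
Gaussian nearest-class-mean rule in LD space with log-priors) is a
descriptive separation check only; no cross-validated classification is
offered, by design.

## 5. Problem sizes in the test battery

The simulation-based checks use sizes chosen to make each property
sharply decidable: 1,000 simulated teeth for the sampling-density check;
500 null replicates at 30 pairs and 200 recovery replicates at 200 pairs
for mixed-model calibration; 20 replicates of a 200-pair cohort for
end-to-end recovery of injected Co/Pb/V deficits; 200 random matrices
(N ≤ 40) for brute-force exactness; 50 seeds for each Monte-Carlo
ordering property. The full suite runs in under ten minutes on one CPU.

## 6. What passing tests do and do not show

The generator emulates the *format and statistical structure* of tooth
elemental series — sampling density, time span, positivity, twin
correlation, quasi-periodicity with a controllable regularity deficit.
It does not emulate LA-ICP-MS instrument physics, enamel/dentine
geometry, measurement artifacts near the neonatal line, element-specific
temporal trends (e.g. postnatal zinc decline), or realistic cross-element
correlation beyond the zinc-pair coupling used for effect injection.
Passing tests therefore demonstrate that the pipeline is *correct and
well-calibrated as software* — it recovers what was injected, at the
nominal error rates, with exact feature arithmetic — not that any
particular biological effect exists or would be detectable in real
cohorts. Published cohort-level coefficients depend on undeposited data
and are not reproduced here.

Other known limitations: Wald z inference is mildly liberal at small
cluster counts (quantified above); the auto-τ delay selection documented
in `EmbeddingParams` discussions of the literature is *not* implemented
— the delay is explicit; and the per-component group tests ignore twin
clustering, as discussed in §4.
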