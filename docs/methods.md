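# Methods

This note documents the models, numerical conventions and design
decisions behind `ctgml`, and what the synthetic cohort does and does
not establish about real cardiotocography (CTG) data.

## Complexity indices

**Coarse-graining.** Scale *s* replaces *s* consecutive samples by their
average; a trailing remainder shorter than *s* is dropped, so scale *s*
of an N-sample trace has ⌊N/s⌋ points. Scale 1 is the identity.

**Sample entropy.** SampEn(m, r) = −ln(A/B) with B the number of
ordered pairs of distinct m-point templates within Chebyshev (max-norm)
distance ≤ r, and A the same for (m+1)-point templates. Both counts use
the N−m templates whose (m+1)-point extension exists, and self-matches
are excluded. Defaults m = 2 and r = 0.15 × SD. Two conventions are
worth making explicit:

* r is computed once from the *original* (scale-1) trace and reused
  unchanged at every scale — the common multiscale-entropy convention,
  which makes entropies comparable across scales.
* When A or B is zero the entropy is undefined; the function returns
  `inf` as a flag rather than raising, and the screening stage treats
  non-finite index values as missing. This arises only for traces with
  essentially no repeating structure at the given tolerance.

The implementation counts template pairs with chunked vectorised
max-norm comparisons (exact, no approximation); the unit tests verify
it digit-for-digit (1e−12) against an independent brute-force
template-counting oracle built on `scipy.spatial.distance.cdist`.

**Byte encoding and compression.** Compressed size is only meaningful
relative to a fixed serialisation, so traces are encoded
deterministically before compression: each sample is rounded to the
nearest 0.25 bpm and stored as an unsigned 16-bit little-endian
integer, so an N-sample series is exactly 2N bytes on every platform.
Compression is stdlib bzip2 at level 9. The compression ratio per scale
is CR(s) = 100 · compressed bytes / raw bytes, with the denominator the
encoded byte length (no container or header overhead). Absolute
compressed sizes (SC indices) depend on this encoding choice and on
trace length; the CR indices are ratios and therefore far more portable
across acquisition pipelines — one reason CR2 is the headline index.

**Curve summaries.** Each five-scale curve is summarised by its sum,
the ordinary-least-squares slope against the scale index 1…5, and the
product sum × slope. MSCsum is divided by 10,000 to bring it to order
unity; its product term uses the rescaled sum. The CR-based summaries
are not rescaled.

## Synthetic cohort generator

The generator exists so every pipeline stage can be exercised, end to
end and deterministically, without the (non-public) hospital data. It
reproduces the *statistical structure* the analysis depends on, not the
physiology of labour.

**Cohort table.** Exactly 15 asphyxia and 502 non-asphyxia subjects by
default. Continuous clinical variables are truncated normals with mean
set to the published group median and SD = IQR/1.349; counts are
rounded normals clipped at zero; binary and categorical variables are
Bernoulli/categorical at the published proportions. Variables with no
published group difference share one distribution across groups.
Red-alert counts are drawn conditionally on the prolonged-deceleration
flag to reproduce the moderate correlation between those two CTG flags.
Only BMI is made missing (47 records by default), completely at random,
since no missingness mechanism is reported.

**Signal model.** A trace is
baseline + slow sinusoid + white noise + deceleration dips, clipped to
[30, 240] bpm: baseline 135 bpm; sinusoid period 60 s; Gaussian-shaped
decelerations arriving as a Poisson process (non-asphyxia 1.5/h, depth
25 bpm; asphyxia 4/h, depth 30 bpm; width 20 s jittered ±30%). Three
per-subject latents create realistic between-subject spread and keep
the fifteen indices from collapsing onto a single axis:

* the white-noise SD, lognormal around the group median (dispersion 0.8
  / 1.2 log-units) — the main driver of the compression indices;
* the oscillation amplitude, lognormal (dispersion 0.4) — feeds the
  entropy family through the SD-relative tolerance r while barely
  moving the compression ratios;
* a sample-to-sample alternation component (median 0.30 bpm
  non-asphyxia, 0.05 asphyxia, dispersion 0.6), emulating a
  sensor/acquisition artifact whose prevalence differs between monitor
  types. Alternation cancels exactly under pairwise averaging, so it
  shapes scale-1 indices while leaving CR2 untouched.

**Calibration.** The sampling rate is not part of the study conditions
we emulate (4 Hz, the standard CTG rate, 60-minute traces). The
group-median noise SDs are the calibrated quantities: with all other
parameters frozen, a bisection over the noise SD (400 full-length
signals per step) was run until the group median CR2 hit the published
4.32 (non-asphyxia) and 8.78 (asphyxia); the resulting medians —
0.0106 and 0.03725 bpm — are frozen as defaults and verified on
held-out seeds (medians within ±0.2 of target at n = 500). These noise
scales are small in bpm terms because, under a 0.25-bpm quantised
encoding, compressed size responds to sub-quantisation noise long
before it reaches physiological short-term-variability magnitudes: the
calibrated values are encoding-relative quantities, not estimates of
real fHR variability.

**What passing tests do and do not show.** The generator reproduces
group sizes, published summary statistics, BMI missingness, the CR2
separation, and enough independent variation for the screening stage to
behave as it would on real tables. It does not model gaps or signal
loss, uterine activity, ST events, autocorrelated (coloured) noise,
device differences beyond the alternation artifact, or any causal link
between the clinical table and the trace (a subject's decelerations on
the trace and their SisPorto deceleration counts are drawn
independently). Results on this cohort therefore validate the
*machinery* — indices, screen, resampling, evaluation — not clinical
effect sizes.

## Screening

Univariable binary logistic regressions (maximum likelihood, Newton,
tolerance 1e−12) give the odds ratio, Wald 95% CI and Wald p-value per
candidate; for a binary predictor the ML odds ratio coincides with the
2×2 cross-product ratio, which the tests check to six significant
figures. Perfect separation is flagged (`separated=True`, non-finite
CI) rather than raised, and flagged results never enter candidate
selection. Categorical cohort variables are dummy-coded against fixed
reference levels (O, Rh-negative, spontaneous pregnancy, cephalic,
vaginal delivery, female); newborn outcome descriptors (birth weight,
Apgar, artery pH) are never screening candidates.

Redundancy pruning computes pairwise Spearman correlations and clusters
variables by the transitive closure of |ρ| > 0.6 — a deterministic
generalisation of resolving correlated pairs one at a time — keeping
the smallest-p member per cluster, ties broken lexicographically for
reproducibility. BMI imputation uses the median BMI of mothers of the
same integer year of age (ages are recorded in years), falling back to
the overall median; the estimator form learns its donor table from the
training data only.

One consequence of clean fixed-length traces is worth stating plainly:
at a fixed trace length some compression indices are exact monotone
transforms of each other (SC2 is CR2 times a constant), so "which named
variable represents the compression cluster after pruning" is decided
by floating-point-level p-value differences among near-duplicates. The
tests therefore assert the stable property — CR2 is univariably
significant and the representative of its cluster survives the screen —
rather than the literal name of the survivor. On real data, varying
record lengths and devices break these ties.

## Class imbalance and evaluation

**Resampling.** Oversampling duplicates minority rows with replacement
up to a target prevalence (default 0.3), perturbing duplicated
*continuous* features with Gaussian noise of SD = 0.1 × the feature SD
(a smoothed bootstrap; jitter 0 reproduces plain duplication). Integer-
coded features — dummies and counts — are duplicated untouched.
Undersampling drops majority rows at random; hybrid does both at a
fixed total. The majority class is never altered under pure
oversampling, and the achieved prevalence is within ±0.01 of target
whenever integer rounding allows.

**Classifiers.** The logistic model is a maximum-likelihood GLM
(binomial, logit); diverging fits are flagged via `separated_` but
still score monotonically. The Naive-Bayes model uses Gaussian
class-conditionals for continuous features and add-one-smoothed
frequency tables for categorical ones (float columns whose values are
all 0/1 count as categorical); within-class zero variances are floored
with a warning. A discretise-everything NB variant was considered and
rejected: with 15 positives, discretisation adds binning choices
without adding information, and the Gaussian default matches common
naive-Bayes implementations. Scores at or above the classification cut
(default 0.5) are positive calls — the boundary is inclusive.

**Repeated evaluation.** Each repetition draws a fresh stratified
train/test split (55/45 by default), resamples the training half only,
fits, and scores the untouched test half; stratification guarantees
positives in every test set, which unstratified 45% draws of 15
positives would not. Both the split and the resampling are redrawn
every repetition. The summary is the mean AUC over repetitions with a
normal-approximation 95% CI of the mean (mean ± 1.96·SD/√R) — the CI of
the *mean*, matching the narrow intervals such protocols report, not
the sampling CI of a single AUC. The leave-one-out mode fits n models
on n−1 subjects without resampling, pools the held-out scores into one
AUC, and bootstraps records (2,000 resamples) for its CI.

**Calibration.** The Hosmer–Lemeshow statistic bins records by score
deciles and computes Σ(O−E)²/(E(1−E/n_g)) against χ² with g−2 degrees
of freedom. The g−2 correction presumes the scores come from a model
fitted to the same data; the type-I simulation in the tests therefore
fits a logistic model per replicate (empirical rejection ≈ 5% at
nominal 5%). Handing the test externally specified true probabilities
would make the statistic ≈ χ²(g) and the df = g−2 reference
anticonservative (≈ 11%).

## Numerical conventions and degenerate inputs

* All randomness flows through `numpy.random.Generator`; pipeline
  stages derive their seeds from one global seed via SHA-256, so every
  artifact is reproducible bit-identically from the manifest.
* SD and variance use the population convention (ddof = 0) throughout.
* IQR-to-SD conversion uses the normal factor 1.349.
* Quantisation: nearest-0.25 bpm rounding; encodable range
  [0, 16383.75] bpm, violated values raise.
* Constant predictors, single-class outcomes, empty series, and
  out-of-range configurations raise `ValueError` with context; flagged
  non-finite statistics (degenerate SampEn, separated fits) propagate
  as missing instead of crashing.

## Problem sizes used in validation

The validation suite runs the statistical property checks at full size
(50-series SampEn oracle at n ≤ 600, 200-replicate CI coverage at
n = 5,000, 500-seed Hosmer–Lemeshow type-I rate, 1,000-repetition
null-feature evaluation, 500 signals per group for the CR2
calibration). End-to-end pipeline checks use reduced cohorts (tens to
~165 subjects) and traces of 2–10 minutes: sample entropy on a full
60-minute trace costs seconds per subject, and the group separation
that drives screening and classification is preserved at shorter
lengths, so small sizes exercise identical code paths. The acceptance
script regenerates all of its inputs at study scale (517 subjects,
full-length signals for the CR2 medians).

## Known limitations

* The cohort emulates marginal distributions (plus one deliberate
  correlation); joint clinical structure — age–BMI dependence, parity
  effects — is absent.
* The alternation artifact is a stylised stand-in for device
  differences; real inter-device effects on compression are richer.
* Wald intervals are first-order; with 15 events, profile-likelihood
  or exact intervals would differ. The package reports Wald throughout
  for consistency with standard GLM output.
* Repeated random splits of 517 subjects reuse the same 15 positives in
  every repetition; the CI of the mean AUC reflects split-to-split
  variation, not cohort-level uncertainty. The leave-one-out mode and
  its bootstrap CI give the more honest cohort-level spread.
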