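# Methods

This note documents the models, the synthetic-data generator, numerical
choices, and the design decisions taken where more than one reasonable
implementation existed. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Behavioural model

Judged time-to-collision is modelled per participant × threat condition
by the Stevens power law `jTTC = α · aTTC^β`, against a linear baseline
`jTTC = α + β·aTTC`. Both are fitted by least squares in original jTTC
space (not log space; a log-space fit is available as an option). For
the power law, α is profiled out in closed form — for fixed β the
optimal scale is `α*(β) = Σ y·x^β / Σ x^{2β}` — reducing the problem to
one-dimensional minimization of SSE(β), run with bounded scalar search
over the segments between starts β ∈ {0.3, 0.5, 1.0, 1.5} (tolerance
1e-10, bounds [1e-3, 5]). This dominates a two-parameter multi-start:
the profiled optimum is exact in α, and tests verify the solution never
loses to a dense grid-search oracle. Fits use at least 10 trials;
smaller cells are excluded from downstream models.

Model comparison uses the Gaussian profiled-likelihood convention
`AIC = n·ln(SSE/n) + 2k`, `BIC = n·ln(SSE/n) + k·ln(n)` with k = 2 for
*both* models (σ² profiled out identically), so the comparison reduces
to SSE; ties go to the linear model. Note the honest caveat, verified
in tests: over the narrow 3–5 s aTTC range the √-curvature is subtle,
so with realistic noise the power law wins a majority of conditions,
not all of them.

Treatment/sex/threat effects on the fitted parameters are tested with a
linear mixed model (statsmodels MixedLM, REML): fixed effects Treatment,
Sex, IsThreaten and their two-way interactions; random intercept per
participant; treatment coding against the placebo arm.

## Pupil preprocessing

* **Conversion.** Recorded pixel area maps to diameter as
  `d = α_scale · L · φ(area)` with φ taken proportional to √area (the
  pupil's visual angle scales with the linear size of its image); any
  residual proportionality constant is folded into `α_scale · L`.
  Diameter input passes through unchanged.
* **Cleaning.** Invalid/zero runs are padded by 100 ms on each side
  (blink on/offsets are contaminated beyond the detected gap) and
  linearly interpolated; samples outside a plausibility band (default
  1.5–9 mm, applied only when units are mm) and beyond ±5 SD of the
  trial mean are invalidated and interpolated. Cleaning never changes
  the sample count. Trials with more than 30% of samples interpolated
  are excluded — a package convention standing in for study-specific
  quality criteria, configurable.
* **Downsampling** averages valid samples into 10 ms bins (timestamp =
  bin start; empty bins stay invalid). **Baseline correction** subtracts
  the mean over [0, 300) ms and is idempotent.
* **Behavioural filtering** is two-stage: technical failures first, then
  the ±5 SD per-subject rule on the remaining trials. A degenerate case
  worth knowing: among otherwise near-constant responses, a single
  deviant always sits ~√n SDs out, so the rule is effectively an
  any-deviant filter there.
* **Phase windows** (absolute trial time, half-open): stimulus
  [300, 1300), early imagination [1300, 1800), late imagination
  [keypress−500, keypress) with keypress = 300 + 1000·jTTC ms; trials
  shorter than 2,300 ms cannot cover all three and are excluded.

## Stimulus dynamics

Velocity = (screen width − initial width)/aTTC; the five-level PSV
factor is the equal-width partition of the observed velocity range,
left-closed/right-open with the last interval right-closed, so a shared
boundary belongs to the upper bin. The exact interior edges for the
standard design are 211.6267, 244.0533, 276.48, 308.9067 px/s; the
conventional one-decimal printed form truncates these. Note that the
design's 10 cells yield only 9 distinct velocities: (1280−256)/4 =
(1280−384)/3.5 = 256 px/s.

## Time normalization and smoothing

The two-piece linear warp maps [300, 1300] ms → [0, 0.5] and
[1300, keypress] → [0.5, 1]; it is strictly increasing, bijective and
exactly invertible, and equal-duration trials share one warp. Warped
samples are smoothed by penalized cubic B-splines (P-splines): 20 basis
functions on equally spaced interior knots, second-difference coefficient
penalty, penalty weight selected from a log grid (1e-6…1e2, 17 points)
by GCV with the trace-of-hat-matrix degrees of freedom. The common
output grid is 101 points on [0, 1] (configurable). Samples before
300 ms belong to the baseline only and never enter trajectories.

## FPCA

The trials × grid matrix is centred and the sample covariance surface
eigendecomposed under trapezoid quadrature: with weights w, the
symmetric matrix `W^{1/2} C W^{1/2}` is decomposed and eigenvectors are
rescaled to quadrature-orthonormal eigenfunctions. No smoothing is
applied to the covariance surface — trajectories are pre-smoothed.
Scores are quadrature inner products of centred trajectories with
eigenfunctions; Parseval (Σλ equals total weighted variance) and score
uncorrelatedness hold to numerical precision. Sign convention: each
eigenfunction is flipped so its integral over the stimulus half
[0, 0.5] is non-negative. Retention: the smallest prefix with
cumulative share > 0.85, then members with individual share ≤ 0.05 are
dropped — in that order, which yields three components for a
62/18/7-type spectrum. FPCA is fitted pooled across arms (needed for
cross-arm score comparisons); per-arm fitting is an option.

## Profiles

Level 1: k-means (k = 2, 50 restarts, seeded) on 1-D log jTTC; the
cluster with the smaller centroid is labelled E, making labels invariant
to input order. Level 2: k-means on within-subgroup standardized
retained scores, k ∈ 2…6, chosen by the maximal rank-sum of the
Calinski–Harabasz index and silhouette coefficient (ties → smaller k);
cluster labels are ordered by descending size. On score clouds without
genuine cluster structure the selected k is data-driven and need not be
4 per subgroup; silhouette values near zero flag that situation.

Stability: bootstrap ARI (refit on a resample, compare assignments of
resampled points to the reference labels; n = 1,000 default) and k-fold
held-out accuracy (nearest training centroid, exact Hungarian label
matching). Two calibration facts the tests document: separated clusters
give both indices ≈ 1, and k-means partitions of pure noise retain
*geometric* stability (bootstrap ARI well above the random-labelling
floor of 0), so low-but-nonzero values must be read against that
baseline, not against zero.

Subject-level proportions of early/late trials are correlated
(Pearson) with the subject's mean fitted α and β, BH-corrected within
the family of four tests; E- and L-proportions are complementary, so
the two rows are exact mirror images.

## State dynamics

Per-subject profile sequences in presentation order are pooled within
group; transitions never span subjects or blocks. P is the
row-normalized count matrix (zero-count rows flagged, not imputed); the
stationary distribution is the normalized left eigenvector at
eigenvalue 1, with an error when that eigenvalue is not simple.
Occupancy and transition contrasts use Pearson chi-squared with
*adjusted* standardized residuals `(O−E)/√(E(1−rowshare)(1−colshare))`
(the raw (O−E)/√E form is available), |z| > 1.96 flagged, BH-FDR within
the 64-cell transition family or the 8-cell occupancy family.

Sequence entropy is the Shannon entropy (bits) of the empirical
distribution of overlapping length-3 blocks pooled within group. The
choice of trigrams: for 8 states the single-symbol maximum is 3 bits
while the trigram maximum is 9 bits, which is the only block length
whose range accommodates flexibility values near 8 bits; block length
is configurable. The plug-in estimator is downward-biased by roughly
(m−1)/(2N ln 2) bits for m observed blocks and N samples — group
contrasts at equal N are far less affected than absolute values.

Uncertainty is by subject-level bootstrap (resampling whole sequences
with replacement, percentile 2.5/97.5 bounds; per-subject count
matrices are precomputed so transition-matrix replicates are sums, not
re-scans). Group comparisons bootstrap each group independently and
flag cells whose difference CI excludes zero, with optional BH
correction of bootstrap two-sided p-values. Attractors are states with
self-transition probability above 0.45; a separate 0.10 threshold
applies only to graph visibility.

## Shared statistics

`bh_fdr` wraps the standard Benjamini–Hochberg step-up (statsmodels).
`rm_anova` implements mixed-design repeated-measures ANOVA by the
univariate contrast method: cell means per subject × within-cell,
orthonormal (Helmert) contrast columns per within effect, Type-III sums
of squares of each contrast block against the sum-coded between-subject
factorial, pooled over columns; the Greenhouse–Geisser ε comes from the
contrast-score covariance (Box's formula, floored at 1/d) and corrects
both F degrees of freedom. This in-package implementation exists
because no installed Python package covers > 1 within × > 1 between
factors; it is cross-checked against pingouin's mixed ANOVA on
one-within/one-between designs in the test suite.

`pointwise_functional_contrast` is a deliberate simplification of a
full functional linear mixed model: at each grid point a linear mixed
model with a subject random intercept, BH-FDR across grid points within
each term, and optional global likelihood-ratio pruning of higher-order
interactions on the grid-averaged response. Limitations, stated rather
than worked around: coefficient functions are not smoothed across the
grid, and random slopes (including one on normalized time itself)
cannot be represented pointwise.

## Synthetic-data generator

The generator is the package's test bed and defines its study
conditions; defaults are fixed once and mirror the design being
emulated:

* **Design**: 37 subjects per arm (LT = losartan, PLC = placebo,
  AVP = vasopressin), 5 aTTC levels (3–5 s) × 4 categories
  (snake/spider threat, butterfly/rabbit non-threat) × 2 initial sizes
  (20%/30% of a 1,280 px screen), 4 repetitions → 160 trials in 2
  blocks, order shuffled per subject. Sex is assigned at random
  (balanced in expectation), so between-cells are unbalanced exactly as
  real cohorts are.
* **Behaviour**: `jTTC = α_eff · aTTC^{β_eff} · e^ε`,
  ε ~ N(0, 0.1) on the log scale (multiplicative noise keeps jTTC
  positive and matches the log-scale clustering). Baselines α = 1.5,
  β = 0.55; additive shifts: AVP α +0.3; LT β −0.15, threat β −0.09,
  female β −0.167. The α/β baselines sit at the centre of the
  parameter ranges such experiments report.
* **Pupil**: tonic level 4.0 mm (+0.2 mm for AVP — an elevated-baseline
  pharmacological signature); task-evoked mean 0.35·(1−e^{−4u}) mm on
  warped time; three eigenfunctions built by Gram–Schmidt from fixed
  templates — early-rise-then-plateau, early-inhibition-late-activation,
  peak–trough–recovery — orthonormal under trapezoid quadrature (the
  analytic forms are a repository convention); Gaussian scores with SDs
  (0.315, 0.170, 0.106), i.e. integrated variance ratio 62:18:7, plus
  AR(1) noise (ρ = 0.3, stationary SD 0.144 ⇒ ≈13% noise share);
  condition shifts on score means (AVP and threat load on component 2);
  blinks as Poisson gaps (rate 0.5/trial, 100–300 ms, zeroed and
  flagged). The trace at real time t is the functional signal evaluated
  at the warped time of t, so the analysis warp exactly inverts the
  generative one.
* **States**: per-arm 8×8 chains chosen analytically (exact trigram
  entropy H₃ = H(π) + 2·H_rate) before any test was run: PLC self 0.50
  with 0.09 pulled toward E1 (H₃ ≈ 7.68 bits, E1-centric and rigid);
  AVP self 0.48 with 0.05 toward each of E3/L3 (≈ 7.82); LT self 0.46,
  rest uniform (≈ 8.02). Self-transitions lie in the 0.45–0.63 band
  characteristic of such data. First states draw from the stationary
  distribution.

What the generator does **not** emulate — and therefore what passing
tests do not establish about real data: genuine cluster structure in
pupil scores (scores are Gaussian, so the "true" number of level-2
clusters is 1 and the selected k is data-driven); pupil-behaviour
coupling beyond shared design factors; non-stationary drift, gaze
artifacts or calibration error; heavy-tailed jTTC lapses; any feedback
from states to behaviour. Parameter-recovery results show the
estimators are consistent and correctly calibrated under the assumed
model, not that the model is true of any particular dataset.

## Reproducibility and problem sizes

All randomness flows from one integer seed; per-stage seeds are derived
from it with named SeedSequence spawn keys so stages re-run in
isolation reproducibly. The acceptance script and tests use the sizes
the analyses are designed around — 160 trials/subject for behavioural
recovery (200 replicates), 2,000 trials for FPCA recovery, 37 subjects
× 140 included trials per arm for Markov recovery and coverage (200
replicates of 1,000-fold bootstraps, made cheap by precomputed
per-subject count matrices), 50 end-to-end replicates for effect
directions — chosen as the smallest sizes at which the Monte-Carlo
error of each check is comfortably below its acceptance margin.
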