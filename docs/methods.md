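# Methods

## Estimation model

All three designs estimate the density of *individuals* from counts of
*clusters* (druses): a cluster is one detection unit at one location
with an integer size, and `D̂ = n·Ê(s)/(2w·P̂·L)` multiplies the
detection-corrected cluster density by the mean cluster size.  The
variance uses the standard first-order decomposition into three
relative-variance components (counts, cluster size, detection); the
components reported by `variance_components` are each term divided by
their sum, so they add to one whenever the total is positive.

Assumptions worth keeping in mind:

* clusters are uniform in perpendicular distance within the strip
  (guaranteed by design when transects are placed without reference to
  the animals);
* the two observers detect independently (full independence) with a
  shared detection function — observers alternate roles, so the fitted
  `p` / `(p0, σ)` are pooled averages;
* cluster size does not affect detectability (the simulator has a
  `size_detection_exponent` switch, default 0, for probing the bias
  this would cause);
* quadrat counts are error-free (a `quadrat_miscount_sd` switch exists
  for sensitivity runs).

### Detection likelihoods

Both fits condition on detection by at least one observer.  For the
removal model, an event is first-observer with probability `p/P` and
second-observer-only with probability `(1−p)p/P`, `P = 1−(1−p)²`; the
MLE is `p̂ = 1 − n₂/n₁` (the test suite verifies this against an
exhaustive grid search), with `Var(p̂)` from the observed information
and `se(P̂)` by the delta method.  `n₂ ≥ n₁` puts the MLE at `p ≤ 0`
and raises a boundary error; `n₂ = 0` puts it at `p = 1`, where the
estimate is exact (`P̂ = 1`) and its standard error is reported as 0
with a flag.

For the distance-removal model the per-event contribution at distance
`y` is `g(y)/w` (first observer) or `(1−g(y))g(y)/w` (second only),
normalised by `P̄ = (1/w)∫₀ʷ[1−(1−g)²]dy`.  Events lacking a recorded
distance (legal in the schema) contribute the distance-marginalised
history probability, so all information is used without inventing
data.  Optimisation works on `(logit p0, log σ)`: Nelder-Mead from a
moment-based start and a fixed fallback `(0.5, w/2)`, then BFGS
refinement; the internal scale is clipped at ±40 so the simplex cannot
overflow.  `se(P̂)` uses the inverse observed information
(central-difference Hessian, step 1e-5 on the internal scale) and the
gradient of `P̄`.  Two degenerate regimes are handled explicitly:

* **p0 → 0 collapse.**  When second-observer-only events are roughly
  as frequent as first-observer events (likely at very small n), the
  conditional likelihood is maximised as `p0 → 0`, where `P̄ → 0` and
  density diverges — the distance-design analogue of the removal
  boundary.  The fit raises a boundary error; replicated experiments
  record the replicate as failed rather than aborting.  At ~35 events
  per survey this affects a few replicates per thousand; at ~17 events
  it reaches several percent.
* **p0 → 1 boundary / rank-deficient information.**  With few or no
  second-observer-only events near the line the information matrix in
  the `p0` direction vanishes; the fit still reports `P̂` but flags
  the fit and reports `se(P̂)` as unavailable (NaN) rather than 0.

`average_detection` evaluates `P̄` by adaptive quadrature (absolute
tolerance 1e-10); the likelihood uses the equivalent closed form in
`erf` for speed, and a unit test keeps the two routes consistent.

### Goodness of fit

`gof_chisq` bins `[0, w]` into `k` equal-width bins with expected
counts proportional to `∫bin [1−(1−g)²]`.  The default degrees of
freedom are `k − 1 − 2`; because the parameters are estimated from the
*unbinned* likelihood, the statistic is classically distributed between
`χ²(k−3)` and `χ²(k−1)` rather than exactly at either reference
(verified by simulation in the test suite: rejection at nominal 5% is
~10% under `df = k−3` and ~3% under `df = k−1`).  The `df` argument is
therefore exposed as a caller-set override, and reported p-values near
the threshold deserve caution.  Published GOF reports sometimes use
other df conventions; the bundled checks reproduce one such report
(χ² = 2.82, p = 0.42) only at df = 3.  One published report
(χ² = 40.54, k = 7, p = 0.16) is internally inconsistent under any
standard convention and is treated as a typographical error.

### Effort rule

The default rule is linear in T (`T_est = CV·T_completed/cv_target`),
matching the published equation; the conventional design-based scaling
(`CV ∝ 1/√T`) is provided as `sqrt_scaling` because the two differ by
a factor `CV/cv_target` and users should see both.  Rounding is to the
nearest integer with ties away from zero; raw values are snapped to
nine decimals first so binary-float noise cannot flip an exact half
(0.41·15/0.1 evaluates to 61.499…99 in IEEE-754), and exact halves are
flagged.  Three published counts (61, 14, "Seven") correspond to raw
values 61.5, 15 and 7.5 from the rounded CV table and were evidently
computed from unrounded CVs; they are documented, not reproduced.

## Synthetic lakes

`simulate_population` scatters druses in a rectangular shoreline strip
(x alongshore, y offshore; transects run in y at fixed spacing) either
homogeneously (Poisson) or as a Thomas cluster process whose parents
represent patches of hard substrate — the biological driver of
aggregation.  Parents are generated in a 5-dispersal-SD buffer so the
pattern is homogeneous inside the strip.  Cluster sizes are iid from a
law with support ≥ 1: all singletons, zero-truncated Poisson, or
zero-truncated negative binomial; true density is
`(druse intensity) × (truncated mean)` in closed form.  The three
virtual protocols survey the *same* realised population: two 30-m-long
parallel lines 1 m apart with a 0.5 × 0.5 m quadrat every 2 m starting
at 0 m (30 counts per full transect, endpoint excluded), a 1-m-wide
removal strip, and a 2-m-wide distance strip with per-event
perpendicular distances.  Reproducibility: every stream is
`default_rng([seed, replicate, stream])`, so any replicate regenerates
in isolation.

### Scenario presets and their calibration

The presets follow the full 15-site field protocol and were calibrated
to the published per-lake anchors — surveyed areas (hence per-design
transect lengths, including the high-density lake's shorter distance
transects, 15.5 m vs 21 m, from surveys truncated at the thermocline
on different days), detection totals, mean cluster sizes, and
detection-probability ranges (removal `p` > 0.9; distance `P̄` between
0.40 and 0.58).  The spatial clustering parameters are not measurable
from the published summaries; they were chosen, once, to be
ecologically plausible (substrate patches metres across) and to place
the presets in the qualitative regimes the field comparison reports:

* `florida_like` — Poisson singletons at 0.07 /m², anchored to the
  quadrat-survey total (8 individuals over 112.5 m²), the cleanest
  anchor because it needs no detection correction.  (The published
  distance-survey total for the same lake implies a ~3× lower density;
  the two are irreconcilable and the quadrat anchor was preferred.)
* `burgan_like` — patches of ~20 druses (σ = 2.5 m) at 0.24 druses/m²,
  zero-truncated-Poisson sizes with mean 1.21; ~80 distance detections
  per survey, matching the published ~79.
* `little_birch_like` — strong patchiness (~450 druses per patch,
  σ = 2.5 m) at 4.8 druses/m² with heavy-tailed negative-binomial
  sizes (truncated mean 5.9, between the published 4.81 and 7.83);
  ~25 individuals/m², matching the published quadrat rate.

The high-density preset uses T = 15 (the protocol's intended sites)
rather than the 4 transects the field crew completed before a
recruitment event; with T = 4 no design-based interval can achieve
near-nominal coverage (a 2·SE interval under a t₃ reference covers
86%), so the full protocol defines the scenario.

What the generator deliberately does not emulate: depth/thermocline
gradients within a transect, habitat covariates, diver search-time
budgets, GPS relocation jitter between designs (available as an
option, default 0), within-druse spatial extent, and recruitment
pulses.  Passing recovery tests therefore show that the estimators are
correct *under the stated sampling model*, not that field complications
are harmless.

### What the replicated experiments show

With 300 replicates per scenario (the problem size used throughout;
each replicate simulates one lake of ~1,300–30,000 druses and all
three surveys), the correctly specified estimators are unbiased within
Monte-Carlo error for every design, and ±2 SE intervals cover truth at
92–94% — slightly under nominal, as expected for design-based variances
on 15 transects with a normal rather than t₁₄ multiplier, and nearer
0.90 under strong clustering.  The quadrat-vs-distance precision
ranking reverses between the low-density singleton lake (quadrat CV
≈ 0.36 vs distance ≈ 0.20: at 0.07 druses/m² the 112.5 m² of quadrats
contain only ~8 individuals) and the dense clustered lake (quadrat
≈ 0.18–0.21 vs distance ≈ 0.20–0.24): once whole substrate patches
dominate the counts, the wide distance strip swallows patches whole
while the sparse quadrat frames subsample them, so the quadrat design's
much smaller area no longer costs precision — and its shorter survey
time (not modelled here) favours it further.

The detection component of `Var(D̂)` is small in absolute terms but
its *share* is essentially independent of the number of detections
(both numerator and denominator scale as 1/n).  For the half-normal
removal model the per-event relative information about `P̂` has a
floor of roughly `n·Var(P̂)/P̂² ≈ 0.4–0.6` over realistic `(p0, σ)`
(the delta-method `se(P̂)` matches the Monte-Carlo SD of `P̂`), so the
share falls below a few percent only when between-transect
overdispersion dominates, as in the high-density preset (~1%); in the
medium-density preset it sits near 15%.

## Numerical conventions

Quadrature tolerance 1e-10 (absolute); optimizer tolerance 1e-8 on the
log-likelihood; Hessian step 1e-5 on the internal scale; information
matrices that are not positive definite yield NaN standard errors plus
a flag, never silent zeros.  Zero detections produce a flagged zero
estimate with undefined CV rather than an exception, so low-density
sweeps do not abort.  Quadrat-survey encounter variance treats the
*site* as the sampling unit with its sampled quadrat area as the
effort weight — one variance framework for all designs; the
alternative (quadrat-level units) would ignore the transect-level
clustering that dominates real patterns.

## Known limitations

* The GOF p-value is approximate between two chi-squared references
  (above); for decision-grade fit assessment use a parametric
  bootstrap.
* Small distance surveys (≲20 events) can hit the `p0 → 0` boundary
  (error) or the `p0 → 1` information-singular regime (flagged); the
  estimator itself remains heavy-tailed at such sizes and its
  empirical CV can substantially exceed the delta-method CV.
* Mean cluster size is the plain sample mean over detected clusters;
  if detectability increases with cluster size this is size-biased
  upward (probe with `size_detection_exponent`).
* The delta-method variance ignores covariance between `n`, `Ê(s)` and
  `P̂`, which share the same detections.
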