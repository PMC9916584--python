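# Methods

## Canonical frame and angle conventions

All analysis happens in a canonical frame: the left-turn version of a path
with the start S at the origin and leg 1 along +y, so the walker's final
heading is +x. Pointing directions are signed degrees in (−180°, 180°]
with 0° = final heading and positive = physically clockwise; the boundary
wraps to +180° (an exact about-face is +180, never −180). Right-turn paths
are exact mirror images; their raw responses are sign-flipped onto the
canonical chirality before averaging. The flip rule is derived from the
trial's chirality relative to a per-path-family canonical chirality rather
than hard-coded per experiment — both published flip conventions (flip
right-turn trials; flip left-turn trials of families whose reference
version turns right) are instances of this one rule, and the pipeline's
mirror invariance is tested end to end.

Geometric equalities use a 1e−9 m / 1e−9° tolerance. Leg lengths at a
topology boundary (L3 = L1 or L4 = L2, which put the crossing exactly at a
vertex) raise an explicit error rather than being silently classified. Leg
lengths are validated against a configurable arena bound (default 3.4 m,
the maximum leg used in the walking experiments); long-L3 fixtures that
need a longer third leg pass a larger bound explicitly.

## Predicted arcs

Each hypothesis's arc is bounded by bearings between path landmarks; on
crossed paths four bounds are exact constants (I→S = 90°, E→I = 180°,
I→T1 = −90°, T3→I = 0°). Arcs are traversed clockwise from their first
boundary and may wrap across ±180° (CtoN1 does). Boundary membership is
closed; disjointness of the admissible arcs (which holds for every path
family here) is measured as zero intersection arc length, so shared
endpoints do not count as overlap.

Two arcs need non-obvious choices:

* **NtoC1** (short-L4 paths, leg 4 imagined extended to cross leg 1): the
  arc is the short side between I′→S (90°) and E′→S, where E′ extends leg 4
  by twice the E–I′ gap. The long complement would overlap every other
  hypothesis and contradict the design's stated disjointness.
* **NtoN1 on long-L3 paths** ("leg 1 noisily resized"): the remembered
  start S′ sweeps the leg-1 line from T1 (maximal shortening) down past S.
  The extension is capped at min(arena bound, L3): a remembered leg 1
  longer than L3 would cross leg 4 — the representation would no longer be
  uncrossed, contradicting the hypothesis — and the arc would overlap the
  crossed-topology predictions. With the cap, the arc's far bound is
  exactly 180° for typical paths, touching (not overlapping) NtoC2.
* **F1**, the false intersection rendered on leg 1 of long-L3 paths, has no
  stated position along the leg and no predicted range uses it; it is
  placed at the leg midpoint purely as a rendering placeholder.

The mean of a predicted arc is the circular mean of 1000 random angles in
the arc. The draws are stratified-uniform (one uniform draw per equal
sub-arc): each angle is still random within the range, but the mean's
Monte-Carlo error drops from ~0.8° (iid, 90° arc) to well under 0.1°, so
the ±2° agreement with the analytic midpoint asserted in the acceptance
checks holds for every seed rather than for most.

## Circular statistics

Descriptives use the vector-sum mean and mean resultant length r; κ is the
maximum-likelihood inversion of A₁(κ) = r via the Best–Fisher piecewise
starting value refined by Newton iteration (tolerance 1e−10), with
Fisher's small-sample correction for n ≤ 15. The 95% CI of the mean
direction is the large-sample circular-dispersion method. The Rayleigh
test uses z = n·r² with the standard series p-value (type-I error
calibrated at 0.05 ± 0.01 under a uniform null in the acceptance suite).
The Mardia–Watson–Wheeler test is the uniform-scores statistic referred to
χ²(2), with midranks and a logged warning under ties. The paired Hotelling
test embeds each angle as (cos, sin), takes paired differences, and refers
T² to F(2, n−2) — the textbook bivariate convention; published reports of
this test sometimes print F(1, n−2)-style degrees of freedom whose
provenance is unclear, and no attempt is made to emulate that.

## Outlier screening

The C-statistic of observation i is (r₋ᵢ − r)/r, computed from the total
resultant vector and its leave-one-out reductions. The cutoff is the 90%
quantile (configurable) of the per-sample *maximum* C over 1000 simulated
von Mises samples of size n_sim (a caller parameter: the original analysis
rounded the actual n up to a convenient simulation size, without a stated
rule; the default is the actual n). Because contamination biases the
observed κ low, the simulation concentration is searched on a grid above
the observed value (κ_obs + 0.05 … κ_obs + 3.00) and the **largest**
candidate satisfying the three acceptance rules wins: (a) candidate κ
exceeds the post-exclusion κ by less than 1.5, (b) post-exclusion κ is at
least the pre-exclusion κ, and (c) fewer than 10% of points are excluded.
Preferring the largest admissible candidate is what gives the screen its
power — the smallest-inflation candidate accepts trivially with zero
exclusions — while rule (a) caps the inflation at roughly κ_after + 1.5,
matching the published bookkeeping pattern. Exclusion is one-pass (no
iterative re-screening). Von Mises draws use numpy's generator, which
implements Best–Fisher rejection sampling.

A detection-power note: a contaminant drawn uniformly on the circle often
lands near the sample mean, where it is statistically indistinguishable
from a clean von Mises(κ = 2) point, so no discordancy screen — not even
an oracle that always excludes the maximum the 10% cap allows — can
reliably recover a majority of uniform contaminants. Recovery guarantees
only make sense for contaminants in the far field (beyond ~140° from the
mean), where the screen reliably flags them; that is the property the unit
suite asserts.

## Projected-normal mixed-effects regression

Each angle is the direction of a latent bivariate normal vector with
identity covariance; the mean has a two-component linear predictor with
path (cell) fixed effects and, at group level, subject random intercepts
per component. Priors: improper flat on the fixed effects,
inverse-gamma(0.001, 0.001) on the random-intercept variances. The Gibbs
sampler (default 1000 iterations, burn-in 200 — the iteration count
follows the original analysis, which does not state its burn-in):

* (β, b) per component: one exact blocked multivariate-normal draw from
  the joint conditional (the full precision matrix is small — cells +
  subjects — so a dense Cholesky is cheap). Blocking removes the slow
  random walk between fixed effects and the random-intercept mean.
* σ² per component: conjugate inverse-gamma.
* latent lengths rᵢ: the known univariate conditional
  f(r) ∝ r·exp(−(r − m)²/2) on r > 0, with m = uᵢ′μᵢ, is sampled by
  independence Metropolis from a normal proposal centered at the
  conditional's mode ½(m + √(m² + 4)); acceptance is near 1, so the
  latent lengths are effectively refreshed each scan (two sub-steps per
  scan by default).

The per-cell posterior direction is atan2(β₂c, β₁c). Convergence is
flagged by a split-chain potential-scale-reduction computed on the cos/sin
embedding of the per-cell direction draws — the functional the model
reports. The latent *norm* of the coefficients is only weakly identified
in a projected-normal model and mixes slowly by construction; it is
irrelevant to circular inference and deliberately excluded from the
diagnostic.

The published model formula ("pointing angle ~ hypothesis + subject") is
ambiguous — the data do not vary by hypothesis — so the fit uses path
fixed effects with subject random intercepts per condition, and the
resulting per-path posteriors are compared against *every* admissible
hypothesis's predicted range. That reproduces the reported outputs
(per-path HPD arcs vs. predicted ranges, overlap ratios, best hypothesis)
without duplicating data. The per-participant variant fits path fixed
effects only, on raw canonicalized trials with no outlier exclusion.

The 95% HPD is the shortest arc containing 95% of the direction draws
(draws unwrapped around their circular mean, sorted, sliding window); it
requires at least 100 draws with resultant > 0.1, since a shortest arc of
a near-uniform posterior is meaningless. The overlap ratio divides the
intersection arc length by the **HPD width** (not the predicted-range
width): a fully covered posterior then scores 1 even when the predicted
range is wider, which is the behavior the published perfect-fit cases
require. Ties within 1e−6 of the top mean ratio are reported as ambiguous
with all tied hypotheses listed.

## Synthetic experiments

The generator emulates the study conditions: per subject a von Mises
angular offset (default concentration κ_subject = 8, giving ≈ 20° SD of
stable subject bias); per trial the hypothesis target (the predicted
range's mean by default, or a fresh uniform draw within the range) plus
von Mises trial noise (default κ_trial = 4, ≈ 30° SD); a 2% uniform
contamination rate (the observed outlier proportions across conditions
span 0–8%); and remembered distances shrunk by a truncated-normal
proportion with mean 0.29, SD 0.20 on (−1, 1) — the reported
underestimation. Condition-level concentration defaults mirroring the
observed spread (0.7 for the conflicting crossed condition up to ~8 for
the matched uncrossed conditions) ship as `DEFAULT_CONDITION_KAPPAS`.
Trials alternate between the left- and right-turn mirror versions of each
shape, and responses are emitted raw (pre-flip, 0–360°), so the generator
exercises the full canonicalization path.

Path families: the first-experiment style samples four crossed and four
short-L4 uncrossed shapes with legs ≤ 3.4 m; the second-experiment style
derives each uncrossed long-L3 partner by swapping L1 and L3 of a crossed
shape, which *exactly* preserves total path length and end-to-start
distance and mirrors the correct pointing angle — the matching the paired
design requires, verified by the geometry module rather than searched for.

What the generator does not emulate: sequential effects between trials
(priming by the preceding condition), forward-pointing response biases,
subject-specific concentrations, multiplicative (leg-length-proportional)
encoding noise, and any coupling between angular and distance errors.
Subject heterogeneity enters as an additive angular offset, a good
approximation to projected-normal random intercepts at moderate
concentration but not identical to them. Passing recovery tests therefore
demonstrates that the pipeline identifies the generating hypothesis under
the assumed noise structure, not that real data are this clean.

## Problem sizes and defaults

Recovery tests use the study-scale design: 32 subjects, 4 path shapes per
condition, 4 trials per shape (128 subject-path means per condition),
trial concentration 4; hypothesis-recovery acceptance runs 20 replicates
per condition-hypothesis cell with fresh path families per replicate.
Outlier calibration uses 1000 simulated samples per candidate
concentration. MCMC runs 1000 iterations; HPD/bootstrap agreement is
checked at 2000 iterations against a 2000-resample bootstrap. All
randomness flows through explicit numpy Generators seeded per run.

## Known limitations

* The latent-length Metropolis step, while near-independent, is still MCMC:
  overlap ratios carry Monte-Carlo error of order 0.01 at the default
  iteration count.
* The HPD estimator is a sample quantile construction; below a few hundred
  draws its endpoints wobble by a few degrees.
* The outlier screen inherits the identifiability ceiling described above:
  it cannot, even in principle, flag contaminants that land near the mean.
* Degenerate zero-resultant trial cells (exactly antipodal responses) are
  excluded with a warning rather than averaged; none arise at realistic
  concentrations.
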