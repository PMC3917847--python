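# Methods

## Model

LIR values y₁…y_N on one chromosome of one sample are modelled as a step
function

    y_i ≈ Σ_j β(k_j) · I(i > k_j),

where a jump at k ∈ {0, …, N−1} sits between probes k and k+1 and β(k) is
the change in fitted level across it.  There is no intercept: normalized
LIR data are centered, and the region before the first retained jump is
pinned at baseline 0.  The jump at k = 0 plays the intercept's role and is
itself subject to elimination, so a CNV flush against the track start can
still be represented.  The fit minimizes the L1 loss Σ|y_i − ŷ_i|
(robust to the isolated outliers that survive quantile normalization), so
each free segment's fitted level is its median and a jump's height is the
difference of the two flanking segment medians.  A least-squares variant
(segment means) is available behind `objective="l2"` for comparison.

Even-length segment medians use the mid-mean of the two central order
statistics.  The level of the merged segment after a removal is recomputed
exactly; an incremental removal updates only the two neighboring jumps and
is contract-tested against a from-scratch refit.

## Elimination and the cutoff function

Each active jump carries a gap g (probe distance to the nearest remaining
jump, with the track edges 0 and N acting as sentinels; the leftmost jump
at k = 0 counts only its right-hand distance, since its left side is the
unbounded baseline) and a priority δ = |β|·g^α − C(g).  The cutoff

    C(g) = M                         for g < m_min
         = S*                        for m_min ≤ g ≤ m_max
         = max(S*, μ_min · g^α)      for g > m_max

enforces, respectively: no call shorter than m_min probes; the user score
threshold; and an intensity floor for long calls, so that faint drifts
spanning many probes are not reported.  The outer branch keeps the score
threshold in force rather than replacing it, the conservative choice.
Defaults m_min = 6, m_max = 30, μ_min = 0.25, α = 0.5.  S\* is
deliberately user-facing (the CLI defaults to 2.5, a threshold at which
score-filtering retains the clearly validating calls in our experience
with the score family).

The jump with the most negative δ is removed first (leftmost on exact
ties), until all δ ≥ 0.  M is nominally 10¹⁶, but δ is never *computed*
that way: at double precision the subtraction |β|g^α − 10¹⁶ rounds away
the score term entirely (the float spacing at 10¹⁶ is 2.0), collapsing all
short-gap jumps into exact ties and degenerating the removal order.  The
priority queue therefore orders short-gap jumps by |β|·g^α directly and
all other jumps by δ — exactly the ordering infinite-precision arithmetic
with a very large M would produce.  The queue is a binary heap with lazy
invalidation; each removal refreshes at most the removed entry and its two
neighbors.

### Adjacent same-direction jumps

When a CNV flank is split into two steps of the same sign, plain
most-negative-δ removal can delete the outer step first and shorten — or
entirely lose — the call.  The override: if the removal candidate and its
right neighbor have same-sign heights and both move the fitted level away
from zero, the neighbor is removed instead (preserving the outer left
edge); symmetrically for toward-zero pairs and the left neighbor.  Both
clauses require the segment *between* the paired jumps to reach μ_min in
magnitude.  That gate is essential: without it the override fires on
ordinary noise jumps adjacent to a true boundary and ratchets the boundary
outward, absorbing baseline probes until the call's level dilutes below
the intensity floor and the call dissolves (in simulation, detection of a
μ = 0.5, m = 50 CNV fell from ~100% to ~25% without the gate).  With the
gate, a genuine split flank — whose intervening shoulder sits at CNV-grade
level — is still protected, and all noiseless staircase fixtures behave
as the verbal rule prescribes.

### Cleanup and consolidation

Elimination does not force the fit back to 0 between calls.  The cleanup
pass re-runs elimination over the surviving jumps with truncated levels
T(x) = x·I(|x| ≥ μ_min), so inter-CNV plateaus below the floor are treated
as baseline, the jumps bounding them are re-scored against the larger
effective drop, and at termination every fitted level is 0 or ≥ μ_min in
magnitude.  Maximal runs of adjacent same-sign nonzero segments become
single calls; a sign change is a boundary between two adjacent calls.  A
call's intensity is the probe-count-weighted mean of its segment levels
and its score |intensity|·m^α; the median normalized LIR over its probes
is recorded alongside, being the more outlier-resistant intensity measure
for downstream prioritization.  Levels below 10⁻¹² in magnitude are
treated as exactly zero.  A final filter re-checks m ≥ m_min,
score ≥ S\*, and the long-call floor.

## Block mode

For large N the dominant cost is recomputing medians of the long
between-CNV segments late in elimination.  The track is cut into blocks of
50,000 probes overlapping by 5,000 (the overlap is configurable; it only
needs to exceed the longest call of interest so a boundary-straddling CNV
has both jumps inside one block, and block-vs-single equivalence is the
tested guard).  Elimination runs to termination per block, the retained
jumps are pooled in global coordinates, and elimination restarts once on
the full track restricted to the pooled candidates (levels refit on the
candidate set before eliminating), followed by the usual cleanup and
consolidation.  On simulated 120,000-probe tracks the block and
single-block call sets are identical.

## Normalization

`quantile_normalize` maps value ranks (average ranks for ties; plotting
position (r − 0.5)/n, which avoids p ∈ {0,1} and is symmetric) onto the
quantiles of a t distribution with 5 df scaled by
target_mad / t₅⁻¹(0.75) ≈ 0.2752 so the population MAD is 0.2.  All
probes supplied in one file are normalized together by default
(per-chromosome normalization is a CLI flag); missing values are rejected
rather than imputed, because the engine assumes a dense ordered track.
Raw values can be passed through (`--no-normalize`); the default cutoffs
remain reasonable for centered data on a comparable scale.

## Score exponent estimation

`fit_score_exponent` fits logit P(V=1) = b₀ + b_lnμ ln μ + b_lnm ln m by
maximum likelihood (records treated as independent, including overlapping
calls — deliberately, matching how such validation sets are assembled),
and reports α̂ = b_lnm / b_lnμ with a 95% CI from the delta method on
ln α̂ (gradient (−1/b_lnμ, 1/b_lnm) against the coefficient covariance),
plus the decision boundary ln μ = −b₀/b_lnμ − α̂ ln m.  A restricted fit
with α fixed uses the single predictor ln μ + α ln m.  Perfect separation
and non-convergence raise informative errors.  Simulation at n = 500
shows the CI covers a true α = 0.5 at close to nominal rate (≈95% over
200 replicates).

## Synthetic data

`simulate_track` emulates the data model the caller assumes: an evenly
spaced probe grid (default 50 bp, i.e. 20 probes/kb, typical of
high-density designs) with additive mean-shift CNVs on a noise floor that
is marginally t₅ scaled to MAD 0.2 — identical to the normalization
target, so simulated data and normalized real data share one scale.
Serial correlation (real high-density arrays violate independence) is
available through a Gaussian AR(1) copula: a stationary unit-variance
AR(1) driver is mapped through Φ and then the scaled-t quantile function,
preserving the marginal exactly.  The generator does *not* emulate GC/wave
artifacts, probe-specific variances, allele-specific dosage, or platform
spatial effects; passing tests therefore demonstrate correctness of the
algorithm under its own noise model, not field performance on any
particular platform.

## Problem sizes used in the tests

Unit and property tests run at N ≤ 12,500; the block-equivalence check
uses two 120,000-probe tracks with ten planted CNVs each; planted-CNV
recovery uses 100 tracks of N = 2,000; exponent-CI calibration uses 200
datasets of n = 500; the Monte-Carlo calibration uses 499 null and 200
observed replicates of N = 2,000 at S\* = 0.7 (low enough that every null
replicate yields a call, keeping the null max-score distribution
continuous — a precondition for uniform p-values).

## Known limitations

* Backward elimination is greedy: once a true boundary jump is removed
  (its height estimate is a noisy single-probe difference early on), the
  boundary can only be represented by a surviving neighbor.  At μ = 0.5
  against MAD-0.2 t₅ noise, both boundaries of an m = 50 CNV land within
  ±3 probes of truth in roughly 70% of replicates; for reference, even the
  exhaustive L1-optimal single-interval fit achieves only ≈88% at that
  tolerance, because heavy-tailed noise occasionally moves the L1 optimum
  itself by 5–10 probes.  Detection (any overlap) is ≈100%.
* The Monte-Carlo p-value machinery assumes the null generator matches the
  real data's noise; with serially correlated data, use `--ar-rho` to
  match, or p-values will be anti-conservative.
* No multi-sample joint calling, no forward-selection or lasso path, and
  no upstream platform normalization (spatial correction, GC waves) —
  inputs are assumed to be honest per-probe LIRs.
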