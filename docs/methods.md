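# Methods

This note documents the models, conventions and numerical choices behind
`era_lfp`, and what the synthetic studies do and do not demonstrate.

## Signal model and identification

The pipeline treats an observed q-channel series `y_1..y_m` as the
impulse response of a discrete-time linear system (Markov parameters
`y_k = C A^{k-1} B`, with `y_0 = 0` and `x_0 = 0`). No external input is
estimated; the series itself is the data matrix. Identification is the
Eigensystem Realization Algorithm: build the block-Hankel pair `(H, H')`
with `s` block rows ("number of stacks", NS), truncate the SVD of `H` at
rank `r`, and read off `(A_r, B_r, C_r)`.

Conventions that matter:

- **Input dimension.** Hankel blocks are the observed q-vectors, so the
  realization has `p = 1` input; multi-input ground-truth systems are
  collapsed to a q-channel response by applying a unit impulse on every
  input simultaneously (`B · 1_p`). For generic random systems this
  collapsed system is minimal of the same order, which the
  exact-recovery tests rely on.
- **Multi-channel handling.** One joint realization per phase
  (`q` = number of channels); per-channel fits are available by passing a
  single row.
- **Sign convention.** After each SVD the largest-magnitude entry of
  every left singular vector is forced non-negative (ties: earliest
  index), making realizations bit-reproducible.
- **Rank policy.** Default `r` = numerical rank of `H` at relative
  tolerance `1e-10 · σ_1`, optionally capped (`r_max`). This is the right
  tolerance for noise-free impulse responses (rank = true order to
  machine precision). For stochastic field recordings the studies use a
  noise-aware tolerance of `2e-2 · σ_1` instead: singular directions
  below a few percent of the dominant one are measurement/estimation
  noise there, and realizing them produces unstable replay. The
  tolerance is a config field (`SelectionConfig.rank_rtol`).
- **Replay guard.** Reconstruction propagates the state iteratively and
  aborts with a diagnostic once the state norm exceeds `1e12 ×` its
  initial value; selection treats such candidates as infinitely bad
  rather than returning non-finite samples.

## Change-point downsampling

Long phases are compressed to the knots of a continuous piecewise-linear
fit minimizing `RSS + penalty × (number of interior knots)`, with knot
values pinned to observed samples. The optimizer has two passes:

1. **Grow** — greedy top-down splitting, always expanding the segment
   whose best split gains the most RSS; the split point is the interior
   sample whose through-the-point split reduces the segment RSS the most
   (computed in O(1) per candidate via prefix sums; ties go to the
   earliest index). Growth stops at a small numerical floor
   (`1e-10 ×` the root-segment RSS) or at `max_cps` knots and does not
   depend on the penalty.
2. **Prune** — backward elimination, repeatedly removing the interior
   knot whose removal increases the RSS the least, while that increase is
   at most the penalty.

Splitting at the point of maximum RSS gain, rather than maximum absolute
deviation from the chord, is essential: with values pinned to samples,
the max-deviation point on a stochastic signal is typically a noise
extremum and routing the polyline through it *increases* the RSS, which
stalls the greedy immediately. Making growth and prune order
penalty-independent has a second benefit: knot sets for different
penalties are nested, so raising the penalty can never increase the knot
count (a property the tests assert).

Limits: binary through-point splitting cannot refine an alternating
(sample-rate zigzag) signal, and very shallow kinks whose removal costs
less than the penalty are absorbed — exact knot recovery holds for
noise-free piecewise-linear signals whose knots lie on the sampling grid
and whose kinks each cost more than the penalty.

Smoothing (centered moving average, default window 5, symmetric truncated
windows at the boundaries) precedes segmentation; the boundary rule
differs from implementations that shrink the span asymmetrically, and the
first/last samples pass through unchanged.

## Uniform regridding and the adaptive grid

Per phase, each channel's knot polyline is sampled on one shared uniform
grid. The grid size is adaptive: `grid_per_knot` (default 3) points per
detected interior knot, averaged over channels, clamped to
`[min_grid, target_points]`. The cap (`target_points`, default 3000)
plays the role of a fixed coarse grid; the adaptive floor matters because
interpolating a near-dead phase with a handful of knots onto the same
grid as a knot-dense baseline phase would let the series *length*, not
the signal, set the stack-count scale. With the adaptive grid the length
of the series handed to ERA reflects the complexity the segmenter
actually found — which is what makes the selected NS a meaningful
complexity readout. Each phase's series is mean-centered per channel by
default (`center=True`): field potentials are AC-coupled, and uncentered
ramps make impulse-response replay diverge.

## Stack-count selection

Candidates start on the dyadic grid `NS = 2^k` (default `k = 1..13`,
clipped to the validity interval `[1, m-2]`), refined around the AIC
minimizer by step halving down to unit steps. The AIC is the Gaussian
form

    AIC = N ln(RSS/N + 1e-300) + 2 k,   k = r² + r·p + q·r,

i.e. the free-entry count of the fitted realization; the guard keeps
numerically exact fits finite. Ties in the argmin go to the smallest NS.
Three nested outcomes:

1. **min_aic** — the AIC minimizer NS\* is accepted if its relative
   error is at most `rel_err_accept` (default 0.25 — the automated
   stand-in for visual inspection of a reconstruction).
2. **neighboring** — otherwise NS\* ± 10 (clipped) are tried and the
   better one accepted under the same threshold.
3. **distant** — otherwise the search expands outward from NS\* in steps
   of 10 within an evaluation budget (default 50 realizations) and
   returns the **smallest** NS whose relative error is acceptable, or
   failing that within `rel_err_margin` (default 1.2×) of the best error
   seen anywhere. Parsimony is deliberate: the absolute error minimum on
   stochastic data sits at a geometry artifact — when `s·q ≈ m - s` a
   full-rank realization can memorize any series — whose location depends
   only on the series length. Selecting the first comparable NS instead
   anchors the readout to where acceptable reconstructions *begin*,
   which tracks signal complexity.

Every evaluation (NS, AIC, RelErr, rank) is returned in the audit trail,
so the reported strategy can be re-checked from the result alone.

## Reconstruction metrics and spectra

RelErr is the joint relative Frobenius error over all channels of a
phase; per-channel mean squared error and Pearson correlation accompany
it (a zero-variance channel reports correlation as undefined, not a
number). Windowed power spectra use a rectangular window (default 30 s,
50% hop) with per-window mean removal; one-sided periodogram bins are
scaled so their sum equals the window energy (Parseval), averaged across
channels, and reported as `10 log10(power + 1e-12)` dB.

## Group statistics

Per-subject, per-phase selected NS values form the phase table. Group
comparisons (AW vs AN) use the two-sided Mann-Whitney U test — exact
enumeration when the pooled sample is tie-free and at most 20, normal
approximation with tie correction otherwise — and Welch's
unequal-variance t-test. The phase-drop test applies Welch's t to
per-subject `|NS(phase a) − NS(phase b)|`. Degenerate inputs (all values
identical) report `None`, never a numeric placeholder. No multiple-testing
correction is applied by default; a Benjamini–Hochberg helper is
provided.

## The synthetic generator

`generate_synthetic_lfp` emulates a euthanasia session: 4 channels at
3000 Hz, seven 5-minute phases (pre-CO2 baseline + six euthanasia
phases). Per phase, white noise is filtered through a random stable
system, normalized to unit RMS jointly over channels, scaled by the
phase's amplitude, and summed with an optional piecewise-linear trend and
i.i.d. Gaussian measurement noise. All randomness flows from one integer
seed through a single generator.

The default system construction is **modal**: two slow real poles
(coherence times 4–8 s) model aperiodic drift, and the remaining order is
2×2 rotation blocks — damped oscillators with coherence times of 2–8 s,
frequencies stratified over a per-phase band. The defaults decay jointly
across phases:

- system order 18 → 2 (fewer rhythms),
- RMS amplitude 1.0 → 0.016 (halving per phase, ~6 dB/phase — by the
  final phases the signal sinks into the fixed 0.02-SD noise floor, as a
  dying brain's activity sinks into electrode noise),
- spectral ceiling 10 → 1.2 Hz (slowing).

A broadband profile (dense random state matrix rescaled to spectral
radius 0.95) is retained for identification tests. What the modal choice
buys: broadband filtered noise has a flat Hankel spectrum, making every
phase equally incompressible regardless of order — no downsampling or
selection rule can then see the schedule. Near-coherent slow rhythms over
drift, with amplitude decaying into the noise floor, reproduce the
qualitative texture that makes real recordings compressible by trend
change points. What it does not buy: no biophysics, no spike content, no
quantitative match to any real spectrum, and no cross-channel anatomy
beyond a shared dense mixing matrix — so passing studies demonstrate
parameter recovery under the stated surrogate, not performance on rat
data.

## Study sizes

The canned studies (`era_lfp.studies`, used by `scripts/acceptance.py`
and the acceptance tests) run at desk scale, chosen as the package's own
study sizes:

- **Exact recovery**: 20 random systems, orders 1–8, 1–4 channels,
  series length 8n, NS = 2n, rank n.
- **NS decay**: 10 seeds × 7 phases at 250 Hz / 8-s phases (the full
  3000 Hz / 5-min defaults are unchanged and available); smoothing
  window 7, change-point penalty 0.03, grid cap 900, `k = 1..9`,
  `rank_rtol 2e-2`. Headline statistic: per-phase median selected NS
  across seeds, which decreases monotonically (≈ 300 at baseline to ≈ 10
  in the final phase).
- **Mann-Whitney power**: 200 synthetic tables, 5 vs 5 subjects, 4
  pooled-SD group gap, exact test at α = 0.01. The gap reflects the
  near-complete rank separation real groups show early in euthanasia
  (the exact 5-vs-5 test can only reach p ≤ 0.01 under complete
  separation, so a criterion-level rejection rate presupposes an effect
  of this size; at exactly 3 SD, normal groups separate completely only
  about three quarters of the time).
- **Determinism**: one 2-phase, 2-channel synthetic subject run twice
  through the full pipeline; every output checksum must match.

## Known limitations

- ERA replay from a single initial state cannot track stationary
  stochastic signals at sub-memorization ranks; reconstruction quality on
  such data is governed by Hankel geometry more than by dynamics. The
  pipeline's complexity readout therefore rests on the change-point
  stage detecting how much deterministic structure a phase has.
- The segmenter is greedy, not optimal; it recovers exact piecewise
  linearity but only approximates the penalized optimum on noise.
- The AIC parameter count is a declared convention (the free entries of
  the fitted realization); it is isolated in `compute_aic` callers for
  easy replacement.
- Group tests assume independent subjects; no longitudinal or
  mixed-effects modelling.
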