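# Methods

This note documents the models, conventions and design choices behind
`tacticalspace`, in the spirit of a statistical package's methods appendix.

## Configuration-state encoding

A player-second is a 4-hot binary vector over 37 categories (10 tactical
actions, 9 target-distance bins, 12 opponent-distance bins, 6 speed bands).
Conventions:

- **Intervals are `[lower, upper)`** with open-ended extremes, so every
  finite value maps to exactly one bin (a speed of exactly 3.6 km/h is a
  jog; a position exactly on the target line is in the 0–5.35 m bin).
- **Target-distance bins step by 5.35 m** from 0 to 37.45 m (= 7 × 5.35),
  descend from `>37.45 m` (id 11) to `0–5.35 m` (id 18), and `<0 m` (id 19)
  covers positions past the target-zone boundary line. The signed distance
  is `target_line_x − x` with +x the attacking direction.
- **Preprocessing**: raw 5 Hz tracks get a two-frame moving average (frame
  i ← mean of raw frames i−1, i; frame 0 unchanged), then are collapsed to
  one position per second (window mean). Speeds are displacements between
  consecutive *per-second* positions (÷1 s, ×3.6 to km/h), consistent with
  the 1 s analysis window; the first second copies the second value. A
  trailing partial second is dropped with a warning.
- **Tactical actions** are assigned by a deterministic rule table over
  positions relative to the carrier, since the underlying coaching
  principles have no canonical formulas. Attacking team: carrier →
  penetration; lateral offset from the ball > 15 m → width and length;
  ahead of the ball → depth mobility; within 10 m of the ball → offensive
  coverage; else offensive unity. Defending team: the single nearest
  defender within 5 m of the carrier → delay; goal-side of the delayer
  within 10 m → defensive coverage; goal-side of the ball inside the
  central corridor (half-width 10 m) → concentration; within 5 m of some
  attacker → balance; else defensive unity. Precedence is the listed
  order; the press tie-break is iteration order. All thresholds are
  configurable (`TacticalThresholds`). These operationalizations are this
  package's own; they are deterministic and documented rather than
  validated against expert-coded video.
- **Dead-ball seconds** (no possession interval covering the second
  midpoint) carry the previous tactical category forward, with a logged
  count; the first second of a trial defaults to offensive/defensive unity.

## Dynamic overlap and the relaxation fit

Overlap between two 4-hot columns is cosine similarity = shared active
categories / 4 ∈ {0, 0.25, 0.5, 0.75, 1}. The curve ⟨q_d(t)⟩ averages all
T − t column pairs at each lag t = 1…max_lag; max_lag defaults to T/2
(150 for 300 s trials) so every lag keeps at least T/2 pairs.

The fitted law is `(1 − q_stat)·t^(−α) + q_stat`. The exponent is negative:
the model is a decaying relaxation whose asymptote is q_stat, and at t = 1
it equals 1 identically, so the fit domain starts at lag 1. Nonlinear least
squares (trust-region, bounds q_stat ∈ [0, 1], α ∈ (0, 10]) is initialized
with q_stat₀ = mean of the last 10% of lags and α₀ = 0.5 — a robust,
derivative-free start. A curve constant at 1 is degenerate (α
unidentifiable) and returns q_stat = 1 with a flag; non-convergence is
flagged, never raised. Repeated trials are pooled *before* fitting by a
pair-count-weighted average of their curves (one fit per player per
condition). `T* = ((1 − q_stat)/ε)^(1/α)` with ε = 0.05; when
q_stat ≥ 1 − ε the curve is already within ε of its asymptote at lag 1 and
T* = 1 is returned with a saturated flag. Lags are in seconds, matching the
1 s encoding window.

## Ball flow

An interaction is a completed possession outcome: pass, turnover or goal.
A possession truncated by the trial end (outcome `out_of_time`) has an
undefined outcome and is excluded from counts and durations. Transition
probabilities divide each holder's outcome counts by that holder's total
interactions; holders with zero interactions keep an all-zero flagged row.
Probable channels are found by exhaustive loop-free path enumeration up to
6 hops — exact at team scale, no heuristic — ranked by the product of edge
probabilities with lexicographic tie-breaks.

## Potential landscape

Carrier states are pooled over all analyzed players (and repeated trials)
per condition. With p_i = n_i/N over the 9 × 12 grid, the potential is
V_i = −Q ln(p_i · C), Q = 1, where **C = 108 is the number of cells in the
spanned space, not the observation total** — the two Ns are kept as
distinct named quantities. The negative sign makes probable states wells
(minima), the physically conventional reading of a stability landscape; the
positive-sign variant is available via `sign="printed"` and only flips the
surface, leaving the |V| ranking invariant. Empty cells are masked (NaN),
never ±∞.

## Statistical comparisons

`mbi_compare` log-transforms both samples, computes the difference of log
means with a pooled-variance t interval (90% CL), and back-transforms:
percent difference = 100(e^Δ − 1), with the CL reported as the symmetric
multiplicative half-width 100(e^{t·SE} − 1). Cohen's d and its 90% CL are
computed on the log scale (d = Δ/s_pooled; SE(d) =
√((n_a+n_b)/(n_a n_b) + d²/(2 df)), a standard large-sample
approximation). The smallest worthwhile change is 0.2 pooled log-scale SD
(the conventional standardized threshold). Chances that the true change is
substantially positive/trivial/negative come analytically from the same t
distribution; labels use the scale 25–75% possibly, 75–95% likely, 95–99%
very likely, >99% most likely, with "unclear" whenever the 90% CI covers
both ±SWC. The chi-square statistic is computed on the 2 × K contingency
table without continuity correction; cells empty in both samples drop from
the statistic but df stays K − 1 over the full support (107 for the
state-space grid). η² = χ²/(χ² + n), documented here because no canonical
formula exists for this design. No multiple-testing correction is applied.

In the pipeline report, count-valued comparisons (passing-interaction cells,
n = 110 = 10 holders × 11 outcomes; configuration-space cells, n = 108) add
+1 before the log transform since empty cells are legitimate zeros;
possession times (n = holders × trials) need no offset. Fitted quantities
(q_stat, α, T*) are floored at 10⁻⁶ before the log step.

## The synthetic-match generator

The generator emulates the *structure* the analysis assumes, not football
realism: 10 attacking vs 9 defending outfield players (goalkeepers are not
simulated), each anchored to one of nine 12.5 × 20 m sub-areas of a
37.5 × 60 m playing area between the penalty-area edge and the target-zone
boundary line, with the target point at the centre of that line and a 5 m
target zone beyond it. Five-minute trials at 5 Hz, repeated twice per
condition in the default design.

- **Dynamics**: a damped mean-reverting walk toward the home-zone centroid
  (anchor strength 1.2 s⁻¹, base noise 1.8 m/√s, 8 m/s speed cap), with
  per-player activity multipliers spread over [0.25, 1.6] so that encoded
  speeds populate the speed bands from standing to running. The carrier
  instead drifts at 4.5 m/s toward the target point.
- **Constraints**: permitted regions are rectangles (under 8-neighbour
  adjacency a zone plus its neighbours is itself a rectangle); positions
  are folded back by boundary reflection, so compliance is exact by
  construction. The carrier is exempt from possession start to end and may
  enter the target zone; at possession end the ex-carrier is projected back
  into their permitted region. "Adjacent" includes diagonal neighbours —
  diagonal support runs are natural in football, though edge-only adjacency
  would also have been defensible.
- **Ball events**: a possession chain with exponential durations (mean 3 s,
  consistent with observed small-sided-game possession times of ~2.7–3.2 s)
  and outcomes drawn from a known row-stochastic holder → outcome matrix
  (default: passes weighted 2:1 toward zone-adjacent teammates, turnover
  0.13, goal 0.06/0.02 for front/back holders). After a turnover or goal a
  uniformly random attacker restarts. The final possession is truncated at
  the trial end and marked `out_of_time`. The matrix, duration mean and
  home map are returned as ground truth for recovery tests.
- **Not modelled**: collisions, defensive pressing strategy, any spatial
  coupling between the notated events and player positions beyond the
  carrier's target drift, goalkeeper behaviour, and opponent-team ball
  possession. Consequently, passing tests demonstrate that the estimators
  recover known generating processes and that the pipeline's contracts
  hold — they do not certify effect sizes on real match data.

Defenders occupy one zone each; the spatial distribution of a real opposing
team is unknown, so one-per-zone is the neutral choice.

## Determinism and problem sizes

Every stochastic component draws from one `numpy` Generator seeded from the
run configuration; identical configurations reproduce tracks, events,
matrices and reports bit for bit, and the pipeline manifest records the
configuration hash and per-trial seeds. The default study design (3
conditions × 2 trials × 19 players × 300 s) runs the complete pipeline in a
few seconds on one core; validation suites use trial lengths of 60–1800 s
chosen to give each statistical check adequate power while keeping the full
test run fast.

## Known limitations

- The tactical-action rule table is an operationalization, not a validated
  classifier; only its determinism and block-exclusivity are guaranteed.
- The overlap model assumes a single power-law relaxation; multi-timescale
  behaviour would call for richer models out of scope here.
- Magnitude-based inference is reported in its conventional form; its
  error-rate properties are debated in the methods literature, and the
  chance labels should be read as descriptive, not confirmatory.
- The equirectangular lat/lon projection is adequate at pitch scale
  (<0.1% distance error over ~100 m) but not for larger extents.
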