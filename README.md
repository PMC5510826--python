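# tacticalspace

Exploratory tactical dynamics of association-football players under spatial
constraints.

When a coach restricts where players may move — confining each player to a
home sub-area of the pitch, allowing movement into adjacent sub-areas only,
or leaving movement free — the breadth and speed of the players' tactical
exploration change, and so do the ball's flow and the contexts in which the
carrier acts. `tacticalspace` is a library for quantifying those effects
from player tracking data and ball-event logs. It is aimed at performance
analysts and researchers in team-sports behavioural dynamics; because
tracking data of this kind is rarely shareable, the package includes a
synthetic constrained-match simulator with known ground truth so every
estimator can be validated end to end by parameter recovery.

## The analysis

**Configuration states.** Each player-second is encoded as a 37-component
binary vector with exactly one active category in each of four blocks:
tactical action (10 categories: penetration, offensive coverage, depth
mobility, width and length, offensive unity; delay, defensive coverage,
balance, concentration, defensive unity), distance from the target
(9 bins of 5.35 m, from >37.45 m down to <0 m inside the target zone),
distance from the nearest opponent (12 bins: <1 m to >11 m) and movement
speed (6 bands from standing, <0.7 km/h, to sprinting, >19.8 km/h).
A 5-minute trial becomes a 37 × 300 Boolean matrix per player.

**Dynamic overlap.** Exploration is measured by the lagged mean cosine
similarity of configuration states,

    q_d(t) = ⟨ cos(c_s, c_{s+t}) ⟩_s ,

which for 4-hot vectors is the mean shared-category fraction. The curve is
fitted with the hierarchical-relaxation law

    ⟨q_d(t)⟩ = (1 − q_stat) · t^(−α) + q_stat ,

giving the asymptotic overlap `q_stat` (long-term exploratory breadth: lower
means broader), the relaxation exponent `α` (short-term exploration rate)
and the saturation lag `T* = ((1 − q_stat)/ε)^(1/α)` with ε = 0.05.

**Ball flow.** Possession durations and a row-stochastic transition matrix
per holder over teammates ∪ {turnover, goal}, with exhaustive ranking of the
most probable loop-free passing channels to goal.

**Potential landscape.** The carrier's state space is the 9 × 12 grid of
(target-distance, opponent-distance) bins. Occupancy probabilities
p_i = n_i/N map to potentials V_i = −Q ln(p_i · C) with C = 108 cells and
Q = 1, so frequently occupied (stable) carrier contexts are wells.

**Inference.** Conditions are compared with magnitude-based inference
(log-transformed means, percent differences ±90% confidence limits, Cohen's
d with pooled SD, qualitative chance labels) and chi-square tests over the
108-cell frequency grids (df = 107).

## Worked example

```python
from tacticalspace import (SimulationConfig, simulate_match, encode_all,
                           dynamic_overlap, pool_curves, fit_overlap_model)

for condition in ("restricted", "free"):
    curves = []
    for seed in (1, 2):                      # two repeated 5-minute trials
        cfg = SimulationConfig(condition=condition, duration_s=300.0, seed=seed)
        tracks, events, _ = simulate_match(cfg)
        cm = encode_all(tracks, events, cfg.pitch)["A5"]
        curves.append(dynamic_overlap(cm, max_lag=150))
    fit = fit_overlap_model(pool_curves(curves))
    print(f"{condition:>10}: q_stat={fit.q_stat:.3f}  alpha={fit.alpha:.2f}  "
          f"T*={fit.t_star:.2f} s")
```

prints

```
restricted: q_stat=0.469  alpha=2.52  T*=2.56 s
      free: q_stat=0.437  alpha=2.27  T*=2.91 s
```

Confining this player to the home sub-area leaves a higher asymptotic
overlap (narrower long-term exploration), a larger α (the overlap decays
faster, i.e. quicker short-term exploration) and an earlier saturation lag
than free play — the qualitative signature spatial restriction is expected
to produce. The `examples/` directory holds one short script per
capability: simulation + encoding, exploration dynamics, passing networks,
potential landscapes, condition comparison, and the full pipeline
(`run_pipeline` writes fits, networks, landscapes, a comparison report and
a seeded manifest).

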