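"""Possession times, the pass-transition matrix and probable scoring channels.

Simulates a trial, estimates each holder's outcome probabilities (pass to a
given teammate, turnover, goal), and ranks the most probable loop-free pass
sequences that end in a goal.
"""

from tacticalspace import (
    SimulationConfig,
    possession_summary,
    probable_channels,
    simulate_match,
    transition_matrix,
)

cfg = SimulationConfig(condition="semi", duration_s=600.0, seed=3)
_, events, truth = simulate_match(cfg)

per_holder, pooled = possession_summary(events)
print(f"pooled mean possession time: {pooled:.2f} s "
      f"(generator mean {truth.possession_mean_s:.1f} s)")

net = transition_matrix(events, players=list(truth.transition.index))
print(f"interactions: {net.n_interactions} "
      "(passes + turnovers + goals; rows of the matrix divide by this per holder)")
row = net.probabilities.loc["A5"]
print("\nA5 outcome probabilities (top 5):")
print(row.sort_values(ascending=False).head(5).round(3).to_string())

print("\nmost probable passing channels to goal from A1:")
for path, prob in probable_channels(net, sources=["A1"], sink="goal", k=3, max_len=3):
    print(f"  {' -> '.join(path)}   p = {prob:.4f}")
print("(path probability is the product of the transition probabilities "
      "along the pass sequence)")
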