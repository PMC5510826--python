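"""Simulate one constrained trial and encode a player's configuration states.

Generates a 60 s restricted-condition trial (non-carriers confined to their
home sub-area), encodes every player-second into the 37-category binary
configuration state, and shows one player's state at a single second.
"""

from tacticalspace import SimulationConfig, encode_all, simulate_match

cfg = SimulationConfig(condition="restricted", duration_s=60.0, seed=1)
tracks, events, truth = simulate_match(cfg)
print(f"tracks: {len(tracks)} rows ({tracks['player'].nunique()} players x "
      f"{int(cfg.duration_s * cfg.rate_hz)} frames at {cfg.rate_hz:g} Hz)")
print(f"events: {len(events)} possession intervals, "
      f"{(events['outcome'] == 'pass').sum()} passes")

matrices = encode_all(tracks, events, cfg.pitch, condition="restricted")
cm = matrices["A3"]
print(f"\nplayer A3 encodes to a {cm.matrix.shape[0]} x {cm.matrix.shape[1]} binary matrix")
second = 10
ids = cm.active_ids(second)
names = [cm.category_names[i - 1] for i in ids]
print(f"active categories at second {second}: {ids} -> {names}")
print("(one category per block: tactical action, distance from target, "
      "distance from nearest opponent, movement speed)")
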