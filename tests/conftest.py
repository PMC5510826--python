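import numpy as np
import pytest

from tacticalspace import SimulationConfig, build_pitch, encode_all, simulate_match


@pytest.fixture(scope="session")
def pitch():
    return build_pitch()


@pytest.fixture(scope="session")
def short_trial():
    """One 60 s restricted trial: (config, tracks, events, truth)."""
    cfg = SimulationConfig(condition="restricted", duration_s=60.0, seed=7)
    tracks, events, truth = simulate_match(cfg)
    return cfg, tracks, events, truth


@pytest.fixture(scope="session")
def short_matrices(short_trial):
    cfg, tracks, events, _ = short_trial
    return encode_all(tracks, events, cfg.pitch, condition="restricted")


def random_four_hot(rng: np.random.Generator, n_seconds: int) -> np.ndarray:
    """Random 37 x T matrix with one active category per variable block."""
    m = np.zeros((37, n_seconds), dtype=np.uint8)
    blocks = [(0, 10), (10, 19), (19, 31), (31, 37)]
    for lo, hi in blocks:
        rows = rng.integers(lo, hi, size=n_seconds)
        m[rows, np.arange(n_seconds)] = 1
    return m
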