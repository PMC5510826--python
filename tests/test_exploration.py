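"""Dynamic overlap, relaxation fit and the saturation lag T*."""

import numpy as np
import pytest
from scipy.optimize import brentq

from tacticalspace import (
    OverlapCurve,
    configuration_overlap,
    dynamic_overlap,
    fit_overlap_model,
    pool_curves,
    relaxation_model,
    t_star,
)
from tacticalspace.errors import InvalidStateError
from .conftest import random_four_hot


def _four_hot(ids):
    v = np.zeros(37)
    v[[i - 1 for i in ids]] = 1
    return v


def oracle_overlap_curve(m: np.ndarray, max_lag: int) -> np.ndarray:
    """Naive double-loop oracle: mean shared-active/4 per lag."""
    T = m.shape[1]
    active = [frozenset(np.flatnonzero(m[:, t])) for t in range(T)]
    out = np.empty(max_lag)
    for lag in range(1, max_lag + 1):
        vals = [len(active[s] & active[s + lag]) / 4.0 for s in range(T - lag)]
        out[lag - 1] = float(np.mean(vals))
    return out


class TestOverlap:
    def test_identical_columns_overlap_one(self):
        v = _four_hot([1, 11, 20, 32])
        assert configuration_overlap(v, v) == pytest.approx(1.0)

    def test_disjoint_columns_overlap_zero(self):
        u = _four_hot([1, 11, 20, 32])
        v = _four_hot([2, 12, 21, 33])
        assert configuration_overlap(u, v) == pytest.approx(0.0)

    def test_half_shared_overlap(self):
        u = _four_hot([1, 11, 20, 32])
        v = _four_hot([1, 11, 21, 33])
        assert configuration_overlap(u, v) == pytest.approx(0.5)

    def test_zero_vector_rejected(self):
        with pytest.raises(InvalidStateError):
            configuration_overlap(np.zeros(37), _four_hot([1, 11, 20, 32]))

    def test_overlaps_quantized_to_quarters(self):
        rng = np.random.default_rng(0)
        m = random_four_hot(rng, 80)
        curve = dynamic_overlap(m, max_lag=20)
        # every mean is a mean of multiples of 0.25
        for lag, q, n in zip(curve.lags, curve.q_mean, curve.n_pairs):
            assert (q * 4 * n) == pytest.approx(round(q * 4 * n), abs=1e-9)

    def test_constant_matrix_gives_unit_curve(self):
        m = np.tile(_four_hot([1, 11, 20, 32])[:, None], (1, 50)).astype(np.uint8)
        curve = dynamic_overlap(m, max_lag=10)
        assert np.allclose(curve.q_mean, 1.0)

    def test_alternating_disjoint_states(self):
        a = _four_hot([1, 11, 20, 32])
        b = _four_hot([2, 12, 21, 33])
        m = np.stack([a, b] * 20, axis=1).astype(np.uint8)
        curve = dynamic_overlap(m, max_lag=4)
        assert curve.q_mean[0] == pytest.approx(0.0)  # lag 1
        assert curve.q_mean[1] == pytest.approx(1.0)  # lag 2

    def test_pair_counts_strictly_decrease(self):
        m = random_four_hot(np.random.default_rng(1), 60)
        curve = dynamic_overlap(m, max_lag=30)
        assert (np.diff(curve.n_pairs) < 0).all()
        assert np.array_equal(curve.n_pairs, 60 - curve.lags)

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            m = random_four_hot(rng, 60)
            curve = dynamic_overlap(m, max_lag=30)
            assert np.max(np.abs(curve.q_mean - oracle_overlap_curve(m, 30))) < 1e-12

    def test_max_lag_bounds_enforced(self):
        m = random_four_hot(np.random.default_rng(2), 20)
        with pytest.raises(ValueError):
            dynamic_overlap(m, max_lag=20)


class TestPooling:
    def test_pooling_with_itself_is_identity(self):
        m = random_four_hot(np.random.default_rng(3), 40)
        c = dynamic_overlap(m, max_lag=10)
        pooled = pool_curves([c, c])
        assert np.allclose(pooled.q_mean, c.q_mean)
        assert np.array_equal(pooled.n_pairs, 2 * c.n_pairs)

    def test_equal_count_pooling_is_the_mean(self):
        lags = np.arange(1, 6)
        a = OverlapCurve(lags, np.full(5, 0.4), np.full(5, 100))
        b = OverlapCurve(lags, np.full(5, 0.6), np.full(5, 100))
        assert np.allclose(pool_curves([a, b]).q_mean, 0.5)

    def test_unequal_count_pooling_weights_by_pairs(self):
        lags = np.arange(1, 6)
        a = OverlapCurve(lags, np.full(5, 0.4), np.full(5, 100))
        b = OverlapCurve(lags, np.full(5, 0.6), np.full(5, 300))
        assert np.allclose(pool_curves([a, b]).q_mean, 0.55)

    def test_mismatched_grids_rejected(self):
        a = OverlapCurve(np.arange(1, 6), np.full(5, 0.4), np.full(5, 10))
        b = OverlapCurve(np.arange(1, 7), np.full(6, 0.4), np.full(6, 10))
        with pytest.raises(ValueError):
            pool_curves([a, b])


class TestFit:
    def _model_curve(self, q, a, L=150):
        lags = np.arange(1, L + 1)
        return OverlapCurve(lags, relaxation_model(lags, q, a), np.full(L, 100))

    def test_noiseless_recovery(self):
        fit = fit_overlap_model(self._model_curve(0.4, 0.8))
        assert fit.converged
        assert fit.q_stat == pytest.approx(0.4, abs=1e-6)
        assert fit.alpha == pytest.approx(0.8, abs=1e-6)

    def test_unit_curve_is_degenerate(self):
        lags = np.arange(1, 20)
        fit = fit_overlap_model(OverlapCurve(lags, np.ones(19), np.full(19, 10)))
        assert fit.degenerate and fit.q_stat == 1.0

    def test_noisy_recovery_is_nearly_unbiased(self):
        rng = np.random.default_rng(9)
        lags = np.arange(1, 151)
        truth = relaxation_model(lags, 0.4, 0.8)
        qs, als = [], []
        for _ in range(20):
            noisy = np.clip(truth + rng.normal(0, 0.02, len(lags)), 0, 1)
            f = fit_overlap_model(OverlapCurve(lags, noisy, np.full(len(lags), 100)))
            qs.append(f.q_stat)
            als.append(f.alpha)
        assert abs(np.mean(qs) - 0.4) < 0.02
        assert abs(np.mean(als) - 0.8) < 0.05

    def test_fitted_t_star_agrees_with_numerical_intersection(self):
        for q, a in [(0.3, 0.5), (0.5, 1.0), (0.7, 1.6)]:
            ts, saturated = t_star(q, a)
            assert not saturated
            root = brentq(lambda t: relaxation_model(t, q, a) - q - 0.05, 1e-9, 1e9, xtol=1e-12)
            assert abs(ts - root) < 1e-9


class TestTStar:
    @pytest.mark.parametrize("q,a,expected", [(0.5, 1.0, 10.0), (0.9, 1.0, 2.0)])
    def test_worked_values(self, q, a, expected):
        ts, saturated = t_star(q, a)
        assert not saturated
        assert ts == pytest.approx(expected)

    def test_saturated_immediately(self):
        ts, saturated = t_star(0.96, 1.0)
        assert saturated and ts == 1.0

    def test_t_star_monotone_in_inverse_alpha(self):
        # faster relaxation (larger alpha) saturates sooner at fixed q_stat
        alphas = np.linspace(0.2, 2.0, 10)
        values = [t_star(0.5, a)[0] for a in alphas]
        assert (np.diff(values) < 0).all()
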