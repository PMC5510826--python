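"""Exploratory dynamics via the dynamic overlap of configuration states.

The dynamic overlap ``q_d(t)`` is the mean cosine similarity between a
player's binary configuration vectors separated by a time lag ``t``. For
4-hot vectors the cosine similarity reduces to (shared active categories)/4,
so individual overlaps are quantized to {0, 0.25, 0.5, 0.75, 1}. The lagged
mean curve decays from 1 (by construction at lag 0) toward an asymptote and
is fitted by the hierarchical-relaxation law

    <q_d(t)> = (1 - q_stat) * t**(-alpha) + q_stat,   t >= 1

where ``q_stat`` is the asymptotic overlap (long-term exploratory breadth:
lower q_stat = broader exploration) and ``alpha`` the relaxation exponent
(larger alpha = faster short-term exploration). ``T*`` is the lag at which
the model curve comes within ``epsilon`` (default 0.05) of the asymptote:

    T* = ((1 - q_stat) / epsilon) ** (1 / alpha)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .encoding import ConfigurationMatrix
from .errors import InsufficientDataError, InvalidStateError

DEFAULT_EPSILON = 0.05
ALPHA_MAX = 10.0


@dataclass
class OverlapCurve:
    """Mean overlap per lag, with the number of contributing vector pairs."""

    lags: np.ndarray      # (L,), lag in seconds, 1..L
    q_mean: np.ndarray    # (L,), mean overlap per lag in [0, 1]
    n_pairs: np.ndarray   # (L,), pairs contributing per lag

    def __post_init__(self):
        self.lags = np.asarray(self.lags, dtype=int)
        self.q_mean = np.asarray(self.q_mean, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)


@dataclass
class OverlapFit:
    """Fitted relaxation parameters."""

    q_stat: float
    alpha: float
    t_star: float
    epsilon: float
    rss: float
    converged: bool
    degenerate: bool = False   # curve was (numerically) constant at 1
    saturated: bool = False    # q_stat >= 1 - epsilon: saturates at lag 1


def configuration_overlap(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity between two binary configuration columns."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise InvalidStateError("configuration vector is all-zero")
    return float(np.dot(u, v) / (nu * nv))


def dynamic_overlap(matrix: ConfigurationMatrix | np.ndarray, max_lag: int | None = None) -> OverlapCurve:
    """Mean overlap between columns at lags 1..max_lag.

    ``max_lag`` defaults to T // 2 so every lag retains at least T/2 pairs.
    """
    m = matrix.matrix if isinstance(matrix, ConfigurationMatrix) else np.asarray(matrix)
    T = m.shape[1]
    if max_lag is None:
        max_lag = T // 2
    if not 1 <= max_lag < T:
        raise ValueError(f"max_lag must satisfy 1 <= max_lag < T={T}, got {max_lag}")
    mf = m.astype(float)
    norms = np.linalg.norm(mf, axis=0)
    if np.any(norms == 0):
        raise InvalidStateError("matrix contains an all-zero column")
    unit = mf / norms
    lags = np.arange(1, max_lag + 1)
    q = np.empty(max_lag)
    n = np.empty(max_lag, dtype=int)
    for i, lag in enumerate(lags):
        q[i] = float(np.einsum("it,it->t", unit[:, :-lag], unit[:, lag:]).mean())
        n[i] = T - lag
    return OverlapCurve(lags=lags, q_mean=q, n_pairs=n)


def pool_curves(curves: list[OverlapCurve]) -> OverlapCurve:
    """Pair-count-weighted mean of overlap curves sharing one lag grid."""
    if not curves:
        raise InsufficientDataError("no curves to pool")
    lags = curves[0].lags
    for c in curves[1:]:
        if not np.array_equal(c.lags, lags):
            raise ValueError("curves must share the same lag grid")
    counts = np.sum([c.n_pairs for c in curves], axis=0)
    weighted = np.sum([c.q_mean * c.n_pairs for c in curves], axis=0)
    return OverlapCurve(lags=lags.copy(), q_mean=weighted / counts, n_pairs=counts)


def relaxation_model(t, q_stat, alpha):
    """(1 - q_stat) * t^(-alpha) + q_stat."""
    return (1.0 - q_stat) * np.power(np.asarray(t, dtype=float), -alpha) + q_stat


def t_star(fit_or_q, alpha: float | None = None, epsilon: float = DEFAULT_EPSILON) -> tuple[float, bool]:
    """Saturation lag T* = ((1 - q_stat)/epsilon)^(1/alpha).

    Accepts either an :class:`OverlapFit` or ``(q_stat, alpha)``. Returns
    ``(t_star, saturated)``; when ``q_stat >= 1 - epsilon`` the curve is
    within epsilon of its asymptote from lag 1 on, so T* = 1 with the
    saturated flag set.
    """
    if isinstance(fit_or_q, OverlapFit):
        q, a, epsilon = fit_or_q.q_stat, fit_or_q.alpha, fit_or_q.epsilon
    else:
        q, a = float(fit_or_q), float(alpha)
    if q >= 1.0 - epsilon:
        return 1.0, True
    return float(((1.0 - q) / epsilon) ** (1.0 / a)), False


def fit_overlap_model(curve: OverlapCurve, epsilon: float = DEFAULT_EPSILON) -> OverlapFit:
    """Nonlinear least-squares fit of the relaxation law over lags t >= 1.

    Bounds: q_stat in [0, 1], alpha in (0, 10]. Initialization: q_stat from
    the mean of the last 10% of lags, alpha = 0.5. A constant curve at 1 is
    degenerate (alpha unidentifiable) and returns q_stat = 1 without fitting;
    non-convergence is flagged, not raised.
    """
    mask = curve.n_pairs > 0
    t = curve.lags[mask].astype(float)
    q = curve.q_mean[mask]
    if len(t) < 5:
        raise InsufficientDataError("need at least 5 lags with positive pair counts")
    if np.allclose(q, 1.0, atol=1e-12):
        return OverlapFit(
            q_stat=1.0, alpha=np.nan, t_star=1.0, epsilon=epsilon,
            rss=0.0, converged=True, degenerate=True, saturated=True,
        )
    tail = max(1, len(t) // 10)
    q0 = float(np.clip(np.mean(q[-tail:]), 0.0, 1.0))
    try:
        popt, _ = curve_fit(
            relaxation_model, t, q,
            p0=(q0, 0.5),
            bounds=((0.0, 1e-9), (1.0, ALPHA_MAX)),
            maxfev=20000,
        )
        converged = True
    except RuntimeError:
        popt, converged = (q0, 0.5), False
    q_hat, a_hat = float(popt[0]), float(popt[1])
    rss = float(np.sum((relaxation_model(t, q_hat, a_hat) - q) ** 2))
    ts, saturated = t_star(q_hat, a_hat, epsilon)
    return OverlapFit(
        q_stat=q_hat, alpha=a_hat, t_star=ts, epsilon=epsilon,
        rss=rss, converged=converged, saturated=saturated,
    )
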