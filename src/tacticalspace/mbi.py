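"""Magnitude-based inference and frequency comparisons between conditions.

``mbi_compare`` follows the standard sports-science workflow: natural-log
transform both samples, express the mean difference as a back-transformed
percent change with 90% confidence limits from the t distribution with
pooled degrees of freedom, compute Cohen's d on the log scale with the
pooled SD, and convert the probability that the true standardized change
exceeds the smallest worthwhile change (0.2 pooled SD) into the qualitative
scale: 25-75% possible, 75-95% likely, 95-99% very likely, >99% most likely.
A comparison whose 90% CI spans both substantial thresholds is "unclear".
Effect magnitudes: 0-0.2 trivial, >0.2-0.6 small, >0.6-1.2 moderate,
>1.2-2 large, >2 very large.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import InsufficientDataError, UndefinedEffectError

MAGNITUDE_BANDS = ((0.2, "trivial"), (0.6, "small"), (1.2, "moderate"), (2.0, "large"))
CHANCE_BANDS = ((0.25, ""), (0.75, "possibly"), (0.95, "likely"), (0.99, "very likely"))


@dataclass
class EffectReport:
    """Condition-comparison summary in the magnitude-based-inference style."""

    percent_diff: float          # back-transformed % difference in means
    percent_cl: float            # symmetric multiplicative 90% half-width, %
    cohens_d: float              # on the log scale, pooled SD
    d_cl: float                  # 90% half-width of d
    chance_smaller: float        # % chance the true change is substantially -
    chance_similar: float        # % chance it is trivial
    chance_greater: float        # % chance it is substantially +
    qualitative: str             # e.g. "likely ↑", "most likely ↓", "unclear"
    magnitude: str               # trivial / small / moderate / large / very large


@dataclass
class FrequencyComparison:
    """Chi-square comparison of two count distributions on one support."""

    chi2: float
    df: int
    p_value: float
    eta_squared: float           # chi2 / (chi2 + n_total)


def cohens_d(sample_a, sample_b) -> float:
    """Standardized mean difference (a - b) / pooled SD."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("Cohen's d needs n >= 2 in each sample")
    na, nb = len(a), len(b)
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        raise UndefinedEffectError("pooled standard deviation is zero")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def magnitude_label(d: float) -> str:
    """Qualitative effect-size band for |d|."""
    ad = abs(d)
    for bound, label in MAGNITUDE_BANDS:
        if ad <= bound:
            return label
    return "very large"


def chance_label(chances: tuple[float, float, float], unclear: bool = False) -> str:
    """Qualitative label from the (smaller, similar, greater) % triple.

    The dominant category fixes the direction arrow (↓ / trivial / ↑) and its
    chance fixes the qualifier. An explicitly unclear comparison overrides.
    """
    if unclear:
        return "unclear"
    smaller, similar, greater = chances
    direction = int(np.argmax(chances))
    arrow = ("↓", "trivial", "↑")[direction]
    top = chances[direction] / 100.0
    qualifier = "most likely"
    for bound, label in CHANCE_BANDS:
        if top <= bound:
            qualifier = label
            break
    if not qualifier:  # dominant chance below 25%: cannot happen with 3 bins
        qualifier = "possibly"
    return f"{qualifier} {arrow}".strip()


def mbi_compare(sample_a, sample_b, swc_factor: float = 0.2, confidence: float = 0.90) -> EffectReport:
    """Magnitude-based comparison of two positive-valued samples (a vs b)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("mbi_compare needs n >= 2 in each sample")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("log transform requires strictly positive values")
    la, lb = np.log(a), np.log(b)
    na, nb = len(a), len(b)
    df = na + nb - 2
    pooled_var = ((na - 1) * la.var(ddof=1) + (nb - 1) * lb.var(ddof=1)) / df
    if pooled_var == 0:
        raise UndefinedEffectError("pooled standard deviation is zero on the log scale")
    s = float(np.sqrt(pooled_var))
    delta = float(la.mean() - lb.mean())
    se = s * np.sqrt(1.0 / na + 1.0 / nb)
    tcrit = float(sps.t.ppf(0.5 + confidence / 2.0, df))

    percent_diff = 100.0 * (np.exp(delta) - 1.0)
    percent_cl = 100.0 * (np.exp(tcrit * se) - 1.0)

    d = delta / s
    se_d = np.sqrt((na + nb) / (na * nb) + d * d / (2.0 * df))
    d_cl = float(tcrit * se_d)

    swc = swc_factor * s
    p_greater = float(sps.t.cdf((delta - swc) / se, df))
    p_smaller = float(sps.t.cdf((-swc - delta) / se, df))
    p_similar = 1.0 - p_greater - p_smaller
    chances = (100.0 * p_smaller, 100.0 * p_similar, 100.0 * p_greater)

    ci_lo, ci_hi = delta - tcrit * se, delta + tcrit * se
    unclear = ci_lo < -swc and ci_hi > swc
    return EffectReport(
        percent_diff=percent_diff,
        percent_cl=percent_cl,
        cohens_d=float(d),
        d_cl=d_cl,
        chance_smaller=chances[0],
        chance_similar=chances[1],
        chance_greater=chances[2],
        qualitative=chance_label(chances, unclear=unclear),
        magnitude=magnitude_label(d),
    )


def chi_square_compare(counts_a, counts_b) -> FrequencyComparison:
    """Chi-square test of two count distributions over the same support.

    The statistic is computed on the 2 x K contingency table (no continuity
    correction); cells empty in both samples contribute nothing and are
    dropped from the statistic, but degrees of freedom are reported over the
    full support (K - 1), matching the convention of comparing two
    distributions on a fixed grid.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("count vectors must share the same support")
    if a.sum() == 0 or b.sum() == 0:
        raise InsufficientDataError("each sample needs a positive total count")
    support = len(a)
    keep = (a + b) > 0
    table = np.vstack([a[keep], b[keep]])
    chi2, _, _, _ = sps.chi2_contingency(table, correction=False)
    df = support - 1
    p = float(sps.chi2.sf(chi2, df))
    n_total = float(a.sum() + b.sum())
    return FrequencyComparison(
        chi2=float(chi2), df=df, p_value=p, eta_squared=float(chi2 / (chi2 + n_total))
    )
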