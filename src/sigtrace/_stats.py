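"""Low-level statistical primitives shared across modules.

Implements the Benjamini-Hochberg step-up adjustment, exact and
normal-approximation two-sided Wilcoxon rank-sum p-values, and the
empirical-Bayes variance shrinkage (scaled F / log-chi-square moment
matching) used for moderated t-statistics.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import special, stats

__all__ = [
    "benjamini_hochberg",
    "rank_sum_exact",
    "rank_sum_normal_p",
    "trigamma_inverse",
    "fit_scaled_f",
    "squeeze_variances",
]


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1).

    Raises ``ValueError`` for values outside [0, 1] or NaN.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-d vector")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1] and be non-missing")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m, dtype=float)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def _rank_sum_distribution(ranks: np.ndarray, n1: int) -> np.ndarray:
    """All possible rank sums of size-n1 subsets of the pooled ranks."""
    n = ranks.size
    idx = np.array(list(combinations(range(n), n1)), dtype=np.intp)
    return ranks[idx].sum(axis=1)


def rank_sum_exact(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Wilcoxon rank-sum test by full enumeration.

    Returns ``(W, p)`` where W is the rank sum of ``x`` (mid-ranks for
    ties) and p = P(|W' - mu| >= |W - mu|) under random assignment of the
    pooled ranks, enumerated over all C(n1+n2, n1) subsets.  With no ties
    this equals the classical two-tailed exact p (2 * min tail, capped).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1 = x.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = ranks[:n1].sum()
    mu = n1 * (pooled.size + 1) / 2.0
    sums = _rank_sum_distribution(ranks, n1)
    dev = abs(w - mu)
    p = float(np.mean(np.abs(sums - mu) >= dev - 1e-9))
    return float(w), p


def rank_sum_normal_p(
    w: np.ndarray, n1: int, n2: int, tie_term: np.ndarray
) -> np.ndarray:
    """Two-sided normal-approximation p for rank sums with tie correction.

    ``tie_term`` is sum(t^3 - t) over tied groups, per test. Zero-variance
    (fully tied) entries get p = 1.
    """
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1.0)))
    var = np.asarray(var, dtype=float)
    p = np.ones_like(var)
    ok = var > 0
    z = (np.asarray(w, dtype=float)[ok] - mu) / np.sqrt(var[ok])
    p[ok] = 2.0 * stats.norm.sf(np.abs(z))
    return np.minimum(p, 1.0)


def trigamma_inverse(x: np.ndarray) -> np.ndarray:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    x = np.asarray(x, dtype=float)
    y = np.where(x > 1e7, 1.0 / np.sqrt(x), 0.5 + 1.0 / x)
    y = np.where(x < 1e-6, 1.0 / np.maximum(x, 1e-300), y)
    mask = (x >= 1e-6) & (x <= 1e7)
    y = np.array(y, dtype=float)
    for _ in range(50):
        tri = special.polygamma(1, y[mask])
        dif = tri * (1.0 - tri / x[mask]) / special.polygamma(2, y[mask])
        y[mask] = y[mask] + dif
        if not np.any(np.abs(dif / y[mask]) > 1e-10):
            break
    return y


def fit_scaled_f(s2: np.ndarray, df1: float) -> tuple[float, float]:
    """Moment-match residual variances to a scaled F model on the log scale.

    Models s2 ~ s2_prior * F(df1, df_prior); hyperparameters are estimated
    from the mean and variance of log(s2) via digamma/trigamma identities.
    Returns ``(s2_prior, df_prior)``; df_prior is ``inf`` when the observed
    log-variance spread does not exceed its sampling expectation.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = np.maximum(s2, 1e-300)
    z = np.log(s2)
    e = z - special.digamma(df1 / 2.0) + np.log(df1 / 2.0)
    emean = float(np.mean(e))
    if e.size < 2:
        return float(np.exp(emean)), np.inf
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df1 / 2.0))
    if evar > 0:
        df_prior = 2.0 * float(trigamma_inverse(np.array([evar]))[0])
        s2_prior = float(
            np.exp(emean + special.digamma(df_prior / 2.0) - np.log(df_prior / 2.0))
        )
    else:
        df_prior = np.inf
        s2_prior = float(np.exp(emean))
    return s2_prior, df_prior


def squeeze_variances(
    s2: np.ndarray,
    df1: float,
    df_prior: float | None = None,
    var_prior: float | None = None,
) -> tuple[np.ndarray, float, float]:
    """Shrink per-gene residual variances toward the fitted prior.

    Returns ``(s2_post, var_prior, df_prior)``. Passing ``df_prior=0``
    forces no shrinkage (posterior equals the raw variances).
    """
    s2 = np.asarray(s2, dtype=float)
    if df_prior is None or var_prior is None:
        fit_var, fit_df = fit_scaled_f(s2, df1)
        if df_prior is None:
            df_prior = fit_df
        if var_prior is None:
            var_prior = fit_var
    if np.isinf(df_prior):
        s2_post = np.full_like(s2, var_prior)
    elif df_prior == 0:
        s2_post = s2.copy()
    else:
        s2_post = (df1 * s2 + df_prior * var_prior) / (df1 + df_prior)
    return s2_post, float(var_prior), float(df_prior)
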