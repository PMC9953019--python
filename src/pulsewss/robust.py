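"""Outlier- and heteroscedasticity-robust factorial statistics.

The analysis core is a two-way factorial ANOVA on 20% trimmed means with
Johansen-type heteroscedasticity adjustment: per-cell trimmed means are
tested through linear contrasts, with squared standard errors estimated
from winsorized variances, ``d = (n - 1) s_w^2 / (h (h - 1))`` where
``h = n - 2 floor(trim n)`` is the effective (post-trim) cell size.  The
chi-square critical value carries Johansen's small-sample correction, and
p-values are located by scanning the significance level over the grid
``0.001 ... 0.999`` until the statistic crosses the corrected critical
value - the convention of the WRS family of robust procedures, whose
reported p-values are therefore bounded by [0.001, 0.999].

Post hoc pairwise contrasts between factor levels are Yuen-type tests on
POOLED level data (all observations at a level, across the other factor),
with Welch-Satterthwaite degrees of freedom and Hochberg step-up control of
the family-wise error rate.  Confidence intervals are widened to the
per-comparison level implied by each comparison's Hochberg rank.

With ``trim = 0`` everything reduces to the classical heteroscedastic
(Welch/Johansen) analysis on ordinary means.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "trimmed_mean", "winsorized_variance", "trimmed_mean_squared_se",
    "johansen_statistic", "johansen_critical",
    "RobustAnovaResult", "robust_two_way_anova",
    "yuen_contrast", "ContrastResult", "posthoc_main_effect_contrasts",
    "hochberg_adjust", "evidence_label",
]

DEFAULT_TRIM = 0.20


# ---------------------------------------------------------------------------
# Robust location / scale estimators
# ---------------------------------------------------------------------------

def trimmed_mean(values, trim: float = DEFAULT_TRIM) -> float:
    """Mean after dropping ``floor(trim * n)`` values from each end."""
    x = np.sort(np.asarray(values, dtype=float))
    if x.size == 0:
        raise ValueError("cannot trim an empty sample")
    if not 0.0 <= trim < 0.5:
        raise ValueError("trim must lie in [0, 0.5)")
    g = int(trim * x.size)
    return float(x[g:x.size - g].mean())


def winsorized_variance(values, trim: float = DEFAULT_TRIM) -> float:
    """Sample variance (ddof=1) after winsorizing ``floor(trim * n)``
    values at each end to the nearest retained order statistics."""
    x = np.sort(np.asarray(values, dtype=float))
    if x.size < 2:
        raise ValueError("winsorized variance needs at least 2 values")
    if not 0.0 <= trim < 0.5:
        raise ValueError("trim must lie in [0, 0.5)")
    g = int(trim * x.size)
    w = np.clip(x, x[g], x[x.size - g - 1])
    return float(w.var(ddof=1))


def trimmed_mean_squared_se(values, trim: float = DEFAULT_TRIM) -> float:
    """Squared standard error of the trimmed mean,
    ``(n - 1) s_w^2 / (h (h - 1))``."""
    n = len(values)
    h = n - 2 * int(trim * n)
    if h < 2:
        raise ValueError("sample too small for the requested trimming")
    return (n - 1) * winsorized_variance(values, trim) / (h * (h - 1))


# ---------------------------------------------------------------------------
# Johansen-type contrast test on trimmed means
# ---------------------------------------------------------------------------

def johansen_statistic(cmat: np.ndarray, means: np.ndarray,
                       sq_se: np.ndarray, h: np.ndarray):
    """Johansen's heteroscedastic test of ``C mu = 0``.

    Returns ``(statistic, A)`` where ``A`` is the small-sample correction
    term built from the effective sizes ``h``.
    """
    cmat = np.atleast_2d(np.asarray(cmat, dtype=float))
    means = np.asarray(means, dtype=float)
    V = np.diag(np.asarray(sq_se, dtype=float))
    M = cmat @ V @ cmat.T
    # pseudo-inverse so that degenerate (zero-variance) designs yield a
    # zero statistic instead of a singular-matrix failure
    Minv = np.linalg.pinv(M)
    stat = float(means @ cmat.T @ Minv @ cmat @ means)
    R = V @ cmat.T @ Minv @ cmat
    A = float(np.sum(np.diag(R) ** 2 / (np.asarray(h) - 1)))
    return stat, A


def johansen_critical(A: float, df: int, alpha) -> np.ndarray:
    """Corrected chi-square critical value at level(s) ``alpha``."""
    c = stats.chi2.ppf(1.0 - np.asarray(alpha, dtype=float), df)
    return c + (c / (2.0 * df)) * A * (1.0 + 3.0 * c / (df + 2.0))


def _scan_p_value(stat: float, A: float, df: int) -> float:
    """Smallest level on the 0.001 grid at which the test rejects."""
    alphas = np.arange(1, 1000) / 1000.0
    crossed = stat > johansen_critical(A, df, alphas)
    idx = np.nonzero(crossed)[0]
    return float(alphas[idx[0]]) if idx.size else 0.999


@dataclass(frozen=True)
class RobustAnovaResult:
    """Trimmed-mean two-way ANOVA: statistics and p-values for the two main
    effects and their interaction.  p-values live on the [0.001, 0.999]
    scan grid."""

    statistic_a: float
    p_a: float
    statistic_b: float
    p_b: float
    statistic_ab: float
    p_ab: float
    trim: float
    factor_a: str
    factor_b: str


def _cell_arrays(table: pd.DataFrame, factors, value: str, trim: float):
    fa, fb = factors
    levels_a = sorted(table[fa].unique())
    levels_b = sorted(table[fb].unique())
    if len(levels_a) < 2 or len(levels_b) < 2:
        raise ValueError("each factor needs at least 2 levels")
    means, sq_se, h, sizes = [], [], [], []
    for la in levels_a:
        for lb in levels_b:
            x = table.loc[(table[fa] == la) & (table[fb] == lb),
                          value].to_numpy(dtype=float)
            n = x.size
            if n < 2 or (trim > 0 and n < 4):
                raise ValueError(
                    f"cell ({la}, {lb}) has n = {n}; too small for the "
                    f"requested trimming")
            sizes.append(n)
            means.append(trimmed_mean(x, trim))
            sq_se.append(trimmed_mean_squared_se(x, trim))
            h.append(n - 2 * int(trim * n))
    if len(set(sizes)) != 1:
        raise ValueError("design is unbalanced: unequal cell sizes "
                         f"{sorted(set(sizes))}")
    return (levels_a, levels_b, np.array(means), np.array(sq_se),
            np.array(h))


def robust_two_way_anova(table: pd.DataFrame,
                         factors: Sequence[str] = ("rheology", "inlet"),
                         value: str = "value",
                         trim: float = DEFAULT_TRIM) -> RobustAnovaResult:
    """Heteroscedasticity-robust two-way ANOVA on cell trimmed means.

    ``table`` is a long-format balanced design; ``factors`` names the two
    grouping columns and ``value`` the response column.
    """
    fa, fb = factors
    levels_a, levels_b, means, sq_se, h = _cell_arrays(
        table, factors, value, trim)
    J, K = len(levels_a), len(levels_b)
    ones_a, ones_b = np.ones((1, J)), np.ones((1, K))
    diff_a = np.eye(J - 1, J) - np.eye(J - 1, J, 1)
    diff_b = np.eye(K - 1, K) - np.eye(K - 1, K, 1)
    results = []
    for cmat in (np.kron(diff_a, ones_b),      # main effect A
                 np.kron(ones_a, diff_b),      # main effect B
                 np.kron(diff_a, diff_b)):     # interaction
        stat, A = johansen_statistic(cmat, means, sq_se, h)
        results.append((stat, _scan_p_value(stat, A, cmat.shape[0])))
    return RobustAnovaResult(
        statistic_a=results[0][0], p_a=results[0][1],
        statistic_b=results[1][0], p_b=results[1][1],
        statistic_ab=results[2][0], p_ab=results[2][1],
        trim=trim, factor_a=fa, factor_b=fb)


# ---------------------------------------------------------------------------
# Post hoc pairwise contrasts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContrastResult:
    """One pairwise trimmed-mean comparison (``level1 - level2``)."""

    level1: str
    level2: str
    estimate: float
    ci_lower: float
    ci_upper: float
    df: float
    p_raw: float
    p_adjusted: float


def yuen_contrast(x, y, trim: float = DEFAULT_TRIM):
    """Yuen's heteroscedastic trimmed-mean comparison of two samples.

    Returns ``(estimate, squared SE, df, p)`` for the difference of trimmed
    means, with Welch-Satterthwaite degrees of freedom.
    """
    d1 = trimmed_mean_squared_se(x, trim)
    d2 = trimmed_mean_squared_se(y, trim)
    est = trimmed_mean(x, trim) - trimmed_mean(y, trim)
    h1 = len(x) - 2 * int(trim * len(x))
    h2 = len(y) - 2 * int(trim * len(y))
    df = (d1 + d2) ** 2 / (d1 ** 2 / (h1 - 1) + d2 ** 2 / (h2 - 1))
    t = est / np.sqrt(d1 + d2)
    p = 2.0 * stats.t.sf(abs(t), df)
    return est, d1 + d2, float(df), float(p)


def hochberg_adjust(p_values) -> np.ndarray:
    """Hochberg step-up adjusted p-values (family-wise error control)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="simes-hochberg")[1]


def posthoc_main_effect_contrasts(table: pd.DataFrame, factor: str,
                                  value: str = "value",
                                  trim: float = DEFAULT_TRIM,
                                  alpha: float = 0.05,
                                  pooled: bool = True):
    """All pairwise trimmed-mean contrasts between the levels of a factor.

    Levels are compared in alphabetical order, first minus second.  With
    ``pooled=True`` (default) each level's location is the trimmed mean of
    ALL observations at that level, pooled across the other factor; with
    ``pooled=False`` the unweighted average of per-cell trimmed means is
    compared instead (the standard error is pooled either way).  Hochberg
    step-up adjustment is applied across the family, and each confidence
    interval uses the per-comparison level implied by its Hochberg rank.

    Returns a list of :class:`ContrastResult`, one per level pair.
    """
    levels = sorted(table[factor].unique())
    if len(levels) < 2:
        raise ValueError("need at least 2 levels for contrasts")
    groups = {lv: table.loc[table[factor] == lv, value].to_numpy(dtype=float)
              for lv in levels}
    raw = []
    for l1, l2 in combinations(levels, 2):
        est, sq_se, df, p = yuen_contrast(groups[l1], groups[l2], trim)
        if not pooled:
            other = [c for c in table.columns
                     if c not in (factor, value, "case", "variable")]
            est = (_cell_mean_average(table, factor, l1, other, value, trim)
                   - _cell_mean_average(table, factor, l2, other, value,
                                        trim))
        raw.append((l1, l2, est, sq_se, df, p))
    p_adj = hochberg_adjust([r[5] for r in raw])
    # Hochberg per-comparison levels: alpha / rank when ranked by
    # decreasing raw p-value
    order = np.argsort([-r[5] for r in raw])
    rank = np.empty(len(raw), dtype=int)
    rank[order] = np.arange(1, len(raw) + 1)
    out = []
    for i, (l1, l2, est, sq_se, df, p) in enumerate(raw):
        crit = stats.t.ppf(1.0 - alpha / (2.0 * rank[i]), df)
        half = crit * np.sqrt(sq_se)
        out.append(ContrastResult(level1=l1, level2=l2, estimate=est,
                                  ci_lower=est - half, ci_upper=est + half,
                                  df=df, p_raw=p, p_adjusted=p_adj[i]))
    return out


def _cell_mean_average(table, factor, level, other_cols, value, trim):
    sub = table[table[factor] == level]
    if not other_cols:
        return trimmed_mean(sub[value], trim)
    cells = sub.groupby(other_cols[0])[value]
    return float(np.mean([trimmed_mean(x, trim) for _, x in cells]))


def evidence_label(p: float) -> str:
    """Categorize the evidence a p-value provides against the null:
    ``strong`` (p < 0.005), ``weak`` (0.005 <= p <= 0.05), else ``none``."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p-value must lie in [0, 1]")
    if p < 0.005:
        return "strong"
    if p <= 0.05:
        return "weak"
    return "none"
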