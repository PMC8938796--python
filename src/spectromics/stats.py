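"""Univariate feature-vs-class association with FDR control.

Each feature is tested with an unpaired two-sided Wilcoxon-Mann-Whitney
test (exact null distribution for small tie-free samples, mid-rank /
tie-corrected normal approximation otherwise), and significance is declared
after Benjamini-Hochberg correction at alpha = 0.05 — applied within each
feature space (EID / PCD / material maps) separately, mirroring per-group
reporting; a pooled option exists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "UnivariateResult",
    "wilcoxon_mw",
    "bh_correct",
    "univariate_screen",
    "pooled_screen",
]

_EXACT_MAX_N = 20


@dataclass(frozen=True)
class UnivariateResult:
    feature: str
    u_statistic: float
    p_value: float
    bh_adjusted_p: float
    significant: bool
    degenerate: bool = False  # constant across both groups


def wilcoxon_mw(x, y) -> tuple:
    """Two-sided Wilcoxon-Mann-Whitney test.

    Returns ``(U, p)`` where U counts the (x, y) pairs with x > y (+ half
    the ties).  Exact p for combined n <= 20 without ties; tie-corrected
    normal approximation otherwise.  Identical constant samples give p = 1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(x.size * y.size / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if x.size + y.size <= _EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def bh_correct(p_values, alpha: float = 0.05) -> tuple:
    """Benjamini-Hochberg step-up correction.

    Returns ``(flags, adjusted)``; a feature is significant when its
    adjusted p is at most ``alpha``.
    """
    p_values = np.asarray(p_values, float)
    if p_values.size == 0:
        return np.zeros(0, bool), np.zeros(0)
    if np.any((p_values < 0) | (p_values > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    flags, adjusted, _, _ = multipletests(p_values, alpha=alpha, method="fdr_bh")
    return flags, adjusted


def univariate_screen(table, labels=None, alpha: float = 0.05) -> list:
    """Screen every feature column of a table for class association.

    ``table`` is a FeatureTable (labels taken from it) or a DataFrame with
    ``labels`` given separately.  BH correction is applied across the
    columns of this table (i.e. within the feature group).
    """
    from .features import FeatureTable

    if isinstance(table, FeatureTable):
        df = table.data
        labels = table.labels if labels is None else np.asarray(labels)
    else:
        df = table
        if labels is None:
            raise ValueError("labels required when passing a bare DataFrame")
        labels = np.asarray(labels)
    labels = labels.astype(int)
    if min(np.bincount(labels, minlength=2)) < 2:
        raise ValueError("need at least two subjects per class")

    pos = labels == 1
    stats_p = []
    for col in df.columns:
        v = df[col].to_numpy(float)
        u, p = wilcoxon_mw(v[pos], v[~pos])
        degenerate = bool(np.all(v == v[0]))
        stats_p.append((col, u, p, degenerate))
    flags, adjusted = bh_correct([s[2] for s in stats_p], alpha=alpha)
    return [
        UnivariateResult(
            feature=col,
            u_statistic=u,
            p_value=p,
            bh_adjusted_p=float(adj),
            significant=bool(flag),
            degenerate=deg,
        )
        for (col, u, p, deg), flag, adj in zip(stats_p, flags, adjusted)
    ]


def pooled_screen(tables: dict, alpha: float = 0.05) -> dict:
    """Screen several feature tables with one BH correction across all.

    The per-group screen above corrects within each feature space; this
    pooled variant corrects jointly over every column of every table.
    Returns ``{group: [UnivariateResult, ...]}`` in the input grouping.
    """
    all_p = []
    per_group = {}
    for group, table in tables.items():
        df = table.data if hasattr(table, "labels") else table
        labels = np.asarray(table.labels).astype(int)
        pos = labels == 1
        rows = []
        for col in df.columns:
            v = df[col].to_numpy(float)
            u, p = wilcoxon_mw(v[pos], v[~pos])
            rows.append((col, u, p, bool(np.all(v == v[0]))))
            all_p.append(p)
        per_group[group] = rows
    flags, adjusted = bh_correct(all_p, alpha=alpha)
    out = {}
    i = 0
    for group, rows in per_group.items():
        res = []
        for col, u, p, deg in rows:
            res.append(
                UnivariateResult(
                    feature=col,
                    u_statistic=u,
                    p_value=p,
                    bh_adjusted_p=float(adjusted[i]),
                    significant=bool(flags[i]),
                    degenerate=deg,
                )
            )
            i += 1
        out[group] = res
    return out
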