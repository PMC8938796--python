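"""Dimensionality estimation and minimum-redundancy feature ranking.

``pca_dim`` estimates how many features are worth carrying: the number of
principal components of the standardized feature table needed to explain
90% of its variance.  ``mrmr_rank`` then greedily ranks features by mutual
information (MI) with the class label, penalizing redundancy with the
features already selected (the MID "difference" criterion; MIQ available).
MI is estimated on equal-frequency 3-bin discretized features, which makes
the ranking invariant to monotone transforms of any feature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from sklearn.feature_selection import SelectorMixin

from ._tabular import as_matrix

__all__ = ["RankedFeatures", "MRMRSelector", "pca_dim", "mrmr_rank"]

_N_MI_BINS = 3


@dataclass
class RankedFeatures:
    names: list
    indices: np.ndarray
    relevance: np.ndarray  # MI(feature, label) per selected feature
    score: np.ndarray  # greedy objective value at each selection step
    criterion: str = "MID"

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate features in ranking")


def pca_dim(table, var_frac: float = 0.90) -> int:
    """Components needed to capture ``var_frac`` of the table's variance.

    Columns are standardized first; zero-variance columns are dropped with
    a warning.  Result never exceeds min(n_rows - 1, n_cols).
    """
    X, _, _ = as_matrix(table)
    if X.shape[0] < 2:
        raise ValueError("need at least two rows")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        warnings.warn(
            f"dropping {(sd == 0).sum()} zero-variance column(s)", stacklevel=2
        )
        X = X[:, sd > 0]
        sd = sd[sd > 0]
    X = (X - X.mean(axis=0)) / sd
    ratios = PCA(svd_solver="full").fit(X).explained_variance_ratio_
    return int(np.searchsorted(np.cumsum(ratios), var_frac - 1e-12) + 1)


def _discretize_ef(X: np.ndarray, n_bins: int = _N_MI_BINS) -> np.ndarray:
    """Columnwise equal-frequency discretization using data-point edges.

    Edges are order statistics, so any strictly monotone increasing
    transform of a column yields identical codes.
    """
    X = np.atleast_2d(np.asarray(X, float))
    n = X.shape[0]
    srt = np.sort(X, axis=0)
    codes = np.zeros(X.shape, dtype=np.int64)
    for k in range(1, n_bins):
        codes += X >= srt[(k * n) // n_bins]
    return codes


def _mi_with_vector(codes_matrix: np.ndarray, v: np.ndarray, n_levels_v: int) -> np.ndarray:
    """MI of every column of a coded matrix with a coded vector, in nats."""
    n, p = codes_matrix.shape
    onehot = np.stack([(v == b).astype(float) for b in range(n_levels_v)])
    # counts[b, a, j] = #{i: v_i = b and codes[i, j] = a}
    counts = np.empty((n_levels_v, _N_MI_BINS, p))
    for a in range(_N_MI_BINS):
        counts[:, a, :] = onehot @ (codes_matrix == a).astype(float)
    pj = counts / n
    row = pj.sum(axis=1, keepdims=True)
    col = pj.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = pj * np.log(pj / (row * col))
    return np.nansum(terms, axis=(0, 1))


def mrmr_rank(table, labels=None, k: int = 11, criterion: str = "MID") -> RankedFeatures:
    """Greedy MRMR ranking of ``k`` features.

    Step 1 takes the feature with maximal MI with the class label; each
    subsequent step maximizes relevance minus mean redundancy with the
    already-selected set (MID) or relevance over mean redundancy (MIQ).
    Ties break toward the earlier column, making the ranking deterministic.
    """
    X, names, labels = as_matrix(table, labels)
    if labels is None:
        raise ValueError("labels required")
    n, p = X.shape
    if k > p:
        raise ValueError(f"k={k} exceeds the {p} available features")
    y = labels.astype(np.int64)
    if np.unique(y).size < 2:
        raise ValueError("need at least two classes")
    if criterion not in ("MID", "MIQ"):
        raise ValueError("criterion must be MID or MIQ")

    codes = _discretize_ef(X)
    relevance = _mi_with_vector(codes, y, int(y.max()) + 1)

    selected: list = []
    scores: list = []
    redundancy_sum = np.zeros(p)
    remaining = np.ones(p, bool)
    for step in range(k):
        if step == 0:
            objective = relevance.copy()
        else:
            mean_red = redundancy_sum / step
            if criterion == "MID":
                objective = relevance - mean_red
            else:
                objective = relevance / (mean_red + 1e-12)
        objective = np.where(remaining, objective, -np.inf)
        j = int(np.argmax(objective))  # argmax takes the first max: column-order ties
        selected.append(j)
        scores.append(float(objective[j]))
        remaining[j] = False
        if step < k - 1:
            redundancy_sum += _mi_with_vector(codes, codes[:, j], _N_MI_BINS)

    idx = np.asarray(selected)
    return RankedFeatures(
        names=[names[j] for j in idx],
        indices=idx,
        relevance=relevance[idx],
        score=np.asarray(scores),
        criterion=criterion,
    )


class MRMRSelector(SelectorMixin, BaseEstimator):
    """Sklearn transformer selecting the top-k MRMR-ranked features.

    Composes with ``sklearn.pipeline.Pipeline``; ``fit`` must only ever see
    training rows, which is what makes in-fold selection leak-free.
    """

    def __init__(self, k: int = 11, criterion: str = "MID"):
        self.k = k
        self.criterion = criterion

    def fit(self, X, y):
        X = np.asarray(X, float)
        self.ranking_ = mrmr_rank(X, np.asarray(y), k=self.k, criterion=self.criterion)
        self.n_features_in_ = X.shape[1]
        support = np.zeros(X.shape[1], bool)
        support[self.ranking_.indices] = True
        self.support_ = support
        return self

    def _get_support_mask(self):
        return self.support_
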