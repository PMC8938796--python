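"""Stratified Monte Carlo repeated cross-validation with in-fold selection.

The classification harness mirrors a small-cohort radiomics workflow: 50
random 5-fold partitions (stratified so every validation fold holds at
least two subjects of each class), and, within each fold, MRMR feature
ranking and feature standardization computed on the training subjects only,
followed by an L2-regularized logistic classifier.  Validation predictions
are pooled across the folds of a repeat to give per-repeat ROC/AUC samples;
accuracy, precision and recall are evaluated at the threshold where
precision and recall intersect.  Per-repeat AUC vectors support pairwise
Wilcoxon signed-rank comparison between feature spaces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression

from . import selection
from ._tabular import as_matrix

__all__ = [
    "CVConfig",
    "FoldResult",
    "ModelReport",
    "stratified_mc_folds",
    "run_cv",
    "roc_and_auc",
    "auc_score",
    "decision_threshold",
    "selection_histogram",
    "sweep_k",
    "compare_models",
]


@dataclass(frozen=True)
class CVConfig:
    n_repeats: int = 50
    n_folds: int = 5
    min_per_class_per_fold: int = 2
    k_features: int = 11
    seed: int = 0
    C: float = 1.0  # inverse L2 regularization strength of the classifier
    criterion: str = "MID"

    def __post_init__(self):
        if self.n_folds < 2:
            raise ValueError("n_folds must be at least 2")


@dataclass
class FoldResult:
    repeat: int
    fold: int
    selected: list
    val_indices: np.ndarray
    probabilities: np.ndarray
    val_labels: np.ndarray


@dataclass
class ModelReport:
    accuracy: float
    precision: float
    recall: float
    auc: float
    accuracy_sd: float
    precision_sd: float
    recall_sd: float
    auc_sd: float
    per_repeat_auc: np.ndarray
    pooled_roc: tuple  # (fpr, tpr)
    pooled_auc: float
    selection_frequency: pd.Series
    mean_threshold: float
    fold_results: list = field(repr=False, default_factory=list)
    config: CVConfig | None = None

    def summary(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "accuracy_sd": self.accuracy_sd,
            "precision": self.precision,
            "precision_sd": self.precision_sd,
            "recall": self.recall,
            "recall_sd": self.recall_sd,
            "auc": self.auc,
            "auc_sd": self.auc_sd,
            "pooled_auc": self.pooled_auc,
            "mean_threshold": self.mean_threshold,
        }


def stratified_mc_folds(labels, config: CVConfig):
    """Draw per-repeat stratified validation-fold partitions.

    Every fold receives at least ``min_per_class_per_fold`` subjects of each
    class; each subject appears in exactly one validation fold per repeat.
    Returns a list (length ``n_repeats``) of lists of index arrays.
    """
    labels = np.asarray(labels, int)
    rng = np.random.default_rng(config.seed)
    classes = np.unique(labels)
    for c in classes:
        smallest = (labels == c).sum() // config.n_folds
        if smallest < config.min_per_class_per_fold:
            need = config.min_per_class_per_fold * config.n_folds
            raise ValueError(
                f"class {c} has {(labels == c).sum()} subjects but "
                f"{need} are required for {config.n_folds} folds with "
                f">={config.min_per_class_per_fold} per class per fold"
            )
    repeats = []
    for _ in range(config.n_repeats):
        folds = [[] for _ in range(config.n_folds)]
        for c in classes:
            idx = rng.permutation(np.flatnonzero(labels == c))
            for f, chunk in enumerate(np.array_split(idx, config.n_folds)):
                folds[f].extend(chunk.tolist())
        repeats.append([np.sort(np.asarray(f)) for f in folds])
    return repeats


def auc_score(scores, labels) -> float:
    """AUC as the normalized Mann-Whitney U (ties get half credit)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_and_auc(scores, labels):
    """ROC curve (monotone from (0,0) to (1,1)) plus rank-based AUC."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    auc = auc_score(scores, labels)
    order = np.argsort(-scores, kind="stable")
    y = labels[order]
    s = scores[order]
    # group tied scores so the curve steps once per distinct threshold
    distinct = np.r_[np.flatnonzero(np.diff(s)), y.size - 1]
    tp = np.cumsum(y)[distinct]
    fp = np.cumsum(1 - y)[distinct]
    tpr = np.r_[0.0, tp / tp[-1]] if tp[-1] > 0 else np.r_[0.0, np.zeros(len(tp))]
    fpr = np.r_[0.0, fp / fp[-1]] if fp[-1] > 0 else np.r_[0.0, np.zeros(len(fp))]
    return fpr, tpr, auc


def decision_threshold(scores, labels):
    """Score threshold where precision equals recall.

    Candidate cut-points are the midpoints between consecutive distinct
    scores; the crossing of ``precision(t) - recall(t)`` is located by sweep
    and linear interpolation.  When the two curves coincide over an interval
    (e.g. perfectly separated scores), the midpoint of that interval is
    returned.  Returns ``(threshold, flagged)``; no crossing falls back to
    0.5 with the flag set.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    uniq = np.unique(scores)
    if uniq.size < 2:
        return 0.5, True
    cand = (uniq[:-1] + uniq[1:]) / 2.0
    diffs = []
    for t in cand:
        pred = scores >= t
        npred = pred.sum()
        if npred == 0:
            diffs.append(np.nan)
            continue
        tp = int((pred & (labels == 1)).sum())
        prec = tp / npred
        rec = tp / max(1, (labels == 1).sum())
        diffs.append(prec - rec)
    diffs = np.asarray(diffs)
    ok = ~np.isnan(diffs)
    cand, diffs = cand[ok], diffs[ok]
    if cand.size == 0:
        return 0.5, True
    zero = np.flatnonzero(diffs == 0)
    if zero.size:
        return float((cand[zero[0]] + cand[zero[-1]]) / 2.0), False
    sign_change = np.flatnonzero(np.sign(diffs[:-1]) != np.sign(diffs[1:]))
    if sign_change.size == 0:
        return 0.5, True
    i = int(sign_change[0])
    d1, d2 = diffs[i], diffs[i + 1]
    t1, t2 = cand[i], cand[i + 1]
    return float(t1 - d1 * (t2 - t1) / (d2 - d1)), False


def _fit_predict_fold(X, y, train_idx, val_idx, config: CVConfig):
    Xtr, ytr = X[train_idx], y[train_idx]
    if np.unique(ytr).size < 2:
        raise RuntimeError("degenerate training split")
    ranking = selection.mrmr_rank(Xtr, ytr, k=config.k_features, criterion=config.criterion)
    cols = ranking.indices
    mu = Xtr[:, cols].mean(axis=0)
    sd = Xtr[:, cols].std(axis=0)
    sd[sd == 0] = 1.0
    clf = LogisticRegression(C=config.C, solver="lbfgs", max_iter=2000)
    clf.fit((Xtr[:, cols] - mu) / sd, ytr)
    probs = clf.predict_proba((X[np.ix_(val_idx, cols)] - mu) / sd)[:, 1]
    return ranking, probs


def run_cv(table, labels=None, config: CVConfig | None = None, folds=None,
           feature_names=None) -> ModelReport:
    """Run the full repeated-CV classification harness on one feature table.

    Selection and standardization are fit on training subjects only.  A
    repeat whose training split degenerates (a class absent) is redrawn from
    fresh random folds and logged.  ``folds`` may be supplied to share fold
    assignments across runs (e.g. the k-sweep).
    """
    config = config or CVConfig()
    X, names, labels = as_matrix(table, labels, feature_names)
    if labels is None:
        raise ValueError("labels required")
    y = labels.astype(int)
    if X.shape[1] < config.k_features:
        raise ValueError("fewer feature columns than k_features")
    if np.isnan(X).any():
        raise ValueError("feature table contains missing values")

    if folds is None:
        folds = stratified_mc_folds(y, config)
    all_idx = np.arange(len(y))

    fold_results = []
    accs, precs, recs, aucs, thresholds = [], [], [], [], []
    pooled_scores, pooled_labels = [], []
    redraw_rng = np.random.default_rng(config.seed + 10_007)
    for r, fold_sets in enumerate(folds):
        attempts = 0
        while True:
            try:
                repeat_results = []
                for f, val_idx in enumerate(fold_sets):
                    train_idx = np.setdiff1d(all_idx, val_idx)
                    ranking, probs = _fit_predict_fold(X, y, train_idx, val_idx, config)
                    repeat_results.append(
                        FoldResult(
                            repeat=r,
                            fold=f,
                            selected=[names[j] for j in ranking.indices],
                            val_indices=val_idx,
                            probabilities=probs,
                            val_labels=y[val_idx],
                        )
                    )
                break
            except RuntimeError:
                attempts += 1
                if attempts > 10:
                    raise
                warnings.warn(
                    f"repeat {r}: degenerate split, redrawing folds", stacklevel=2
                )
                sub = CVConfig(
                    n_repeats=1,
                    n_folds=config.n_folds,
                    min_per_class_per_fold=config.min_per_class_per_fold,
                    k_features=config.k_features,
                    seed=int(redraw_rng.integers(0, 2**31 - 1)),
                    C=config.C,
                    criterion=config.criterion,
                )
                fold_sets = stratified_mc_folds(y, sub)[0]
        fold_results.extend(repeat_results)

        # pool the repeat's validation predictions (each subject appears once)
        scores_r = np.empty(len(y))
        for fr in repeat_results:
            scores_r[fr.val_indices] = fr.probabilities
        aucs.append(auc_score(scores_r, y))
        t, _ = decision_threshold(scores_r, y)
        thresholds.append(t)
        pred = scores_r >= t
        tp = int((pred & (y == 1)).sum())
        accs.append(float((pred == (y == 1)).mean()))
        precs.append(tp / pred.sum() if pred.sum() else 0.0)
        recs.append(tp / (y == 1).sum())
        pooled_scores.append(scores_r)
        pooled_labels.append(y)

    pooled_scores = np.concatenate(pooled_scores)
    pooled_labels = np.concatenate(pooled_labels)
    fpr, tpr, pooled_auc = roc_and_auc(pooled_scores, pooled_labels)

    return ModelReport(
        accuracy=float(np.mean(accs)),
        precision=float(np.mean(precs)),
        recall=float(np.mean(recs)),
        auc=float(np.mean(aucs)),
        accuracy_sd=float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
        precision_sd=float(np.std(precs, ddof=1)) if len(precs) > 1 else 0.0,
        recall_sd=float(np.std(recs, ddof=1)) if len(recs) > 1 else 0.0,
        auc_sd=float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0,
        per_repeat_auc=np.asarray(aucs),
        pooled_roc=(fpr, tpr),
        pooled_auc=float(pooled_auc),
        selection_frequency=selection_histogram(fold_results),
        mean_threshold=float(np.mean(thresholds)),
        fold_results=fold_results,
        config=config,
    )


def selection_histogram(fold_results) -> pd.Series:
    """How often each feature was selected across all folds, descending."""
    counts: dict = {}
    for fr in fold_results:
        for name in fr.selected:
            counts[name] = counts.get(name, 0) + 1
    return pd.Series(counts, dtype=int).sort_values(ascending=False)


def sweep_k(table, labels=None, config: CVConfig | None = None, k_max: int = 11
            ) -> pd.DataFrame:
    """Exhaustive sweep of the selected-feature count from 1 to ``k_max``.

    Fold assignments are drawn once from the config seed and shared across
    all k so rows are comparable.
    """
    config = config or CVConfig()
    _, _, y = as_matrix(table, labels)
    folds = stratified_mc_folds(y.astype(int), config)
    rows = []
    for k in range(1, k_max + 1):
        cfg = CVConfig(
            n_repeats=config.n_repeats,
            n_folds=config.n_folds,
            min_per_class_per_fold=config.min_per_class_per_fold,
            k_features=k,
            seed=config.seed,
            C=config.C,
            criterion=config.criterion,
        )
        report = run_cv(table, labels, cfg, folds=folds)
        rows.append(
            {"k": k, "accuracy": report.accuracy, "precision": report.precision,
             "recall": report.recall, "auc": report.auc}
        )
    return pd.DataFrame(rows).set_index("k")


def _exact_signed_rank_p(d: np.ndarray) -> float:
    """Exact two-sided sign-flip p-value of the Wilcoxon signed-rank test.

    Uses the dynamic-programming distribution of the positive-rank sum over
    all sign assignments; mid-ranks (tied |d|) are handled by doubling so
    the support stays integral.
    """
    ranks = sps.rankdata(np.abs(d))
    doubled = np.rint(2 * ranks).astype(int)
    total = doubled.sum()
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in doubled:
        nxt = dist.copy()
        nxt[r:] += dist[: total + 1 - r]
        dist = nxt
    dist /= dist.sum()
    w_pos = int(np.rint(doubled[d > 0].sum()))
    lower = dist[: w_pos + 1].sum()
    upper = dist[w_pos:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def compare_models(auc_a, auc_b) -> float:
    """Paired two-sided Wilcoxon signed-rank test on per-repeat AUC vectors.

    Zero differences are dropped; exact sign-flip distribution for up to 25
    non-zero pairs, normal approximation beyond.  All-zero differences give
    p = 1 with a warning.
    """
    a = np.asarray(auc_a, float)
    b = np.asarray(auc_b, float)
    if a.shape != b.shape:
        raise ValueError("AUC vectors must be paired (equal length)")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 1.0
    if d.size <= 25:
        return _exact_signed_rank_p(d)
    res = sps.wilcoxon(d, alternative="two-sided", method="approx")
    return float(res.pvalue)
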