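"""Cross-validation harness: stratification, metrics, leakage, comparisons."""

from itertools import product

import numpy as np
import pytest
from scipy import stats as sps

import spectromics.selection as selection
from spectromics.crossval import (
    CVConfig,
    auc_score,
    compare_models,
    decision_threshold,
    roc_and_auc,
    run_cv,
    selection_histogram,
    stratified_mc_folds,
    sweep_k,
)


def labels_13_12():
    return np.r_[np.ones(13), np.zeros(12)].astype(int)


def test_stratified_folds_constraints():
    y = labels_13_12()
    cfg = CVConfig(n_repeats=6, n_folds=5, seed=0)
    repeats = stratified_mc_folds(y, cfg)
    assert len(repeats) == 6
    for folds in repeats:
        assert len(folds) == 5
        all_idx = np.concatenate(folds)
        np.testing.assert_array_equal(np.sort(all_idx), np.arange(25))  # partition
        for f in folds:
            assert (y[f] == 1).sum() >= 2 and (y[f] == 0).sum() >= 2


def test_stratified_folds_infeasible():
    y = np.r_[np.ones(6), np.zeros(6)].astype(int)
    with pytest.raises(ValueError, match="required"):
        stratified_mc_folds(y, CVConfig(n_folds=5))


def test_auc_rank_sum_oracle(rng):
    scores = rng.normal(size=40)
    y = (rng.random(40) < 0.5).astype(int)
    y[:2] = [0, 1]  # both classes present
    n1, n0 = (y == 1).sum(), (y == 0).sum()
    u = sum(
        1.0 if a > b else 0.5 if a == b else 0.0
        for a in scores[y == 1]
        for b in scores[y == 0]
    )
    assert auc_score(scores, y) == pytest.approx(u / (n1 * n0), abs=1e-12)


def test_auc_edge_conventions():
    assert auc_score([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
    assert auc_score([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5
    fpr, tpr, auc = roc_and_auc([0.2, 0.4, 0.6, 0.8], [0, 1, 0, 1])
    assert fpr[0] == 0 and tpr[0] == 0 and fpr[-1] == 1 and tpr[-1] == 1
    assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)


def sweep_threshold_oracle(scores, labels):
    """Brute-force: evaluate |precision-recall| on a fine grid of cutpoints."""
    grid = np.unique(
        np.concatenate([np.linspace(min(scores), max(scores), 2001)])
    )
    best_t, best_d = 0.5, np.inf
    npos = (labels == 1).sum()
    for t in grid:
        pred = scores >= t
        if pred.sum() == 0:
            continue
        tp = (pred & (labels == 1)).sum()
        d = abs(tp / pred.sum() - tp / npos)
        if d < best_d - 1e-12:
            best_t, best_d = t, d
    return best_t, best_d


def test_threshold_symmetric_and_separated():
    t, flag = decision_threshold(np.array([0.2, 0.4, 0.6, 0.8]), np.array([0, 0, 1, 1]))
    assert t == pytest.approx(0.5) and not flag
    t, flag = decision_threshold(np.array([0.1, 0.2, 0.8, 0.9]), np.array([0, 0, 1, 1]))
    assert t == pytest.approx(0.5) and not flag


@pytest.mark.parametrize("seed", range(4))
def test_threshold_agrees_with_sweep_oracle(seed):
    rng = np.random.default_rng(seed)
    y = (rng.random(30) < 0.5).astype(int)
    y[:2] = [0, 1]
    scores = np.clip(rng.normal(0.4 + 0.25 * y, 0.2), 0, 1)
    t, flag = decision_threshold(scores, y)
    t_oracle, d_oracle = sweep_threshold_oracle(scores, y)
    # both must reach the same |precision - recall| gap
    pred = scores >= t
    tp = (pred & (y == 1)).sum()
    d = abs(tp / max(1, pred.sum()) - tp / (y == 1).sum())
    assert d <= d_oracle + 1e-9


def test_run_cv_separable_and_chance(rng):
    y = labels_13_12()
    X = rng.normal(size=(25, 20))
    X[:, 4] = y * 10.0 + rng.normal(0, 0.01, 25)  # perfect separator
    cfg = CVConfig(n_repeats=8, n_folds=5, k_features=3, seed=1)
    rep = run_cv(X, y, cfg)
    assert rep.auc > 0.99 and rep.accuracy > 0.95

    Xn = rng.normal(size=(25, 20))
    rep_null = run_cv(Xn, y, CVConfig(n_repeats=25, n_folds=5, k_features=3, seed=2))
    assert 0.3 <= rep_null.auc <= 0.7


def test_run_cv_deterministic(rng):
    y = labels_13_12()
    X = rng.normal(size=(25, 15))
    cfg = CVConfig(n_repeats=4, k_features=3, seed=3)
    a = run_cv(X, y, cfg)
    b = run_cv(X, y, cfg)
    np.testing.assert_array_equal(a.per_repeat_auc, b.per_repeat_auc)
    assert a.summary() == b.summary()
    assert a.selection_frequency.equals(b.selection_frequency)


def test_in_fold_selection_sees_training_rows_only(rng, monkeypatch):
    y = labels_13_12()
    X = rng.normal(size=(25, 10))
    seen = []
    orig = selection.mrmr_rank

    def spy(table, labels=None, **kw):
        seen.append(np.asarray(table).shape[0])
        return orig(table, labels, **kw)

    monkeypatch.setattr(selection, "mrmr_rank", spy)
    cfg = CVConfig(n_repeats=2, n_folds=5, k_features=2, seed=4)
    run_cv(X, y, cfg)
    assert seen and all(n <= 25 - 4 for n in seen)  # never the full cohort


def test_leakage_canary(rng):
    """A feature informative only outside each training split cannot raise
    AUC; a training-wide informative feature must."""
    y = labels_13_12()
    X = rng.normal(size=(25, 10))
    # half-informative feature: equals the label on a fixed half of the
    # cohort, constant elsewhere (2 folds -> informative only in validation)
    half = np.zeros(25, bool)
    half[::2] = True
    X[:, 0] = np.where(half, y, 0.0) + rng.normal(0, 0.01, 25)
    cfg = CVConfig(n_repeats=20, n_folds=2, k_features=2, seed=5)
    rep = run_cv(X, y, cfg)
    assert rep.auc <= 0.75  # chance band: no leakage amplification

    X[:, 0] = y + rng.normal(0, 0.01, 25)  # training-wide informative
    rep2 = run_cv(X, y, cfg)
    assert rep2.auc > 0.95


def test_selection_histogram_counting(rng):
    y = labels_13_12()
    X = rng.normal(size=(25, 30))
    X[:, 0] = y * 8.0 + rng.normal(0, 0.01, 25)  # always selected first
    cfg = CVConfig(n_repeats=5, n_folds=5, k_features=2, seed=6)
    rep = run_cv(X, y, cfg)
    hist = rep.selection_frequency
    assert hist.iloc[0] == 25  # 5 repeats x 5 folds
    assert hist.idxmax() == "f0"
    assert hist.sum() == 2 * 5 * 5  # k x repeats x folds counting identity
    assert selection_histogram(rep.fold_results).equals(hist)


def test_sweep_k_shared_folds(rng):
    y = labels_13_12()
    X = rng.normal(size=(25, 12))
    X[:, 2] += y * 2
    cfg = CVConfig(n_repeats=3, k_features=4, seed=7)
    table = sweep_k(X, y, cfg, k_max=4)
    assert list(table.index) == [1, 2, 3, 4]
    # determinism: the k=4 row equals a direct run with shared folds
    folds = stratified_mc_folds(y, cfg)
    direct = run_cv(X, y, cfg, folds=folds)
    assert table.loc[4, "auc"] == pytest.approx(direct.auc)


# ---------------------------------------------------------------------------
# signed-rank comparison


def bruteforce_signed_rank_p(d):
    """Enumerate all 2^n sign assignments of |d| with mid-ranks."""
    ranks = sps.rankdata(np.abs(d))
    n = len(d)
    w_obs = ranks[np.asarray(d) > 0].sum()
    total = ranks.sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in product([False, True], repeat=n)
    ]
    ws = np.asarray(ws)
    lower = np.mean(ws <= w_obs + 1e-9)
    upper = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2 * min(lower, upper))


def test_compare_models_identical_and_offset():
    with pytest.warns(UserWarning, match="zero"):
        assert compare_models(np.ones(10), np.ones(10)) == 1.0
    p = compare_models(np.arange(6) + 1.0, np.arange(6) + 0.5)
    assert p == pytest.approx(2 / 64)


@pytest.mark.parametrize("seed", range(5))
def test_compare_models_matches_bruteforce(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 10))
    a = rng.normal(size=n)
    b = a + rng.normal(0.3, 0.5, size=n)
    assert compare_models(b, a) == pytest.approx(bruteforce_signed_rank_p(b - a))


def test_compare_models_requires_pairing():
    with pytest.raises(ValueError, match="paired"):
        compare_models(np.ones(5), np.ones(6))
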