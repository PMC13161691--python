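"""Standardization, boosted-tree classification, threshold tuning, screening."""

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cytovoxel.classify import (
    ClassifierConfig,
    Standardizer,
    evaluate,
    leave_one_batch_out,
    screen_features,
    standardize,
    train_classifier,
    tune_threshold,
)
from cytovoxel.core import ConfigurationError


# ---------------------------------------------------------------------------
# standardization


def test_zscore_population_sd_convention():
    x = np.array([[1.0], [2.0], [3.0]])
    z, scaler = standardize(x)
    assert np.allclose(z.ravel(), [-1.224744871, 0.0, 1.224744871])
    assert scaler.sd[0] == pytest.approx(np.sqrt(2 / 3))


def test_constant_feature_maps_to_zero_with_warning():
    x = np.column_stack([np.ones(5), np.arange(5.0)])
    with pytest.warns(UserWarning, match="zero-variance"):
        z, _ = standardize(x)
    assert np.all(z[:, 0] == 0)


def test_fit_rows_statistics_never_leak(rng):
    x = rng.uniform(0, 1, (20, 4))
    scaler = Standardizer.fit(x[:10])
    test_a = scaler.transform(x[10:15])
    # transforming the same rows alongside different companions is identical
    test_b = scaler.transform(np.vstack([x[10:15], rng.uniform(100, 200, (5, 4))]))[:5]
    assert np.array_equal(test_a, test_b)
    assert np.allclose(scaler.transform(x[:10]).mean(axis=0), 0, atol=1e-12)


# ---------------------------------------------------------------------------
# training & threshold


def planted_features(rng, n_per_class=30, n_features=20, shift=1.5):
    x = rng.normal(0, 1, (2 * n_per_class, n_features))
    y = np.repeat(["neg", "pos"], n_per_class)
    x[y == "pos", 0] += shift
    return x, y


def test_single_class_rejected(rng):
    x, _ = planted_features(rng)
    with pytest.raises(ConfigurationError):
        train_classifier(x, ["pos"] * len(x), ClassifierConfig(n_trees=5))


def test_training_is_deterministic(rng):
    x, y = planted_features(rng)
    cfg = ClassifierConfig(n_trees=30, seed=9)
    a = train_classifier(x, y, cfg).scores(x)
    b = train_classifier(x, y, cfg).scores(x)
    assert np.array_equal(a, b)


def _stub_classifier(scores):
    return SimpleNamespace(
        classes=np.array([0, 1]), scores=lambda _: np.column_stack([1 - scores, scores])
    )


def test_threshold_sweep_matches_exhaustive_oracle():
    scores = np.array([0.1, 0.4, 0.6, 0.9])
    labels = np.array([0, 0, 1, 1])
    t = tune_threshold(_stub_classifier(scores), None, labels)
    assert 0.4 < t <= 0.6
    pred = scores >= t
    assert np.array_equal(pred, labels.astype(bool))  # F1 = 1
    # exhaustive oracle: no candidate threshold does better
    for cand in scores:
        p = scores >= cand
        tp = np.sum(p & (labels == 1)); fp = np.sum(p & (labels == 0)); fn = np.sum(~p & (labels == 1))
        assert 2 * tp / (2 * tp + fp + fn) <= 1.0


def test_threshold_perfectly_separated():
    scores = np.array([0.05, 0.1, 0.8, 0.95])
    labels = np.array([0, 0, 1, 1])
    t = tune_threshold(_stub_classifier(scores), None, labels)
    pred = scores >= t
    assert np.array_equal(pred, labels.astype(bool))


def test_threshold_degenerate_cases():
    with pytest.warns(UserWarning, match="one class"):
        assert tune_threshold(_stub_classifier(np.array([0.2, 0.7])), None, np.array([1, 1])) == 0.5
    with pytest.warns(UserWarning, match="single-score"):
        assert tune_threshold(_stub_classifier(np.full(4, 0.3)), None, np.array([0, 1, 0, 1])) == 0.5


# ---------------------------------------------------------------------------
# evaluation


def test_perfect_and_antiperfect_scores():
    y = np.array([0, 0, 1, 1])
    rep = evaluate(None, None, y, scores=np.column_stack([[0.9, 0.8, 0.1, 0.2], [0.1, 0.2, 0.9, 0.8]]))
    assert rep.roc_auc == 1.0
    assert rep.pr_auc == pytest.approx(1.0)
    anti = evaluate(None, None, y, scores=np.column_stack([[0.1, 0.2, 0.9, 0.8], [0.9, 0.8, 0.1, 0.2]]))
    assert anti.roc_auc == 0.0


def _u_statistic_auc(scores, y):
    """Brute-force pair counting: P(score_pos > score_neg) + 0.5 ties."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_roc_area_equals_normalized_u_statistic(rng):
    for _ in range(25):
        n = rng.integers(4, 12)
        y = np.zeros(n, dtype=int)
        y[rng.choice(n, rng.integers(1, n), replace=False)] = 1
        if y.sum() in (0, n):
            continue
        scores = rng.choice(np.linspace(0, 1, 6), size=n)  # ties likely
        rep = evaluate(None, None, y, scores=np.column_stack([1 - scores, scores]))
        assert rep.roc_auc == pytest.approx(_u_statistic_auc(scores, y), abs=1e-12)


def test_six_point_hand_set():
    y = np.array([0, 1, 0, 1, 1, 0])
    scores = np.array([0.2, 0.3, 0.5, 0.6, 0.9, 0.4])
    rep = evaluate(None, None, y, scores=np.column_stack([1 - scores, scores]))
    assert rep.roc_auc == pytest.approx(_u_statistic_auc(scores, y))


def test_confusion_matrix_rows_sum_to_class_counts():
    y = np.array([0, 0, 0, 1, 1])
    scores = np.array([0.1, 0.6, 0.2, 0.7, 0.4])
    rep = evaluate(None, None, y, threshold=0.5, scores=np.column_stack([1 - scores, scores]))
    assert rep.confusion.sum(axis=1).tolist() == [3, 2]


def test_lobo_folds_partition_samples_exactly_once(rng):
    x, y = planted_features(rng, n_per_class=12, shift=2.0)
    batches = np.tile(["b1", "b2", "b3"], 8)
    pooled, folds = leave_one_batch_out(pd.DataFrame(x), y, batches, ClassifierConfig(n_trees=20, seed=1))
    assert len(folds) == 3
    assert sum(f.confusion.to_numpy().sum() for f in folds) == len(y)
    assert pooled.roc_auc > 0.8  # planted shift is easily recoverable


def test_multiclass_one_vs_rest_report(rng):
    x = rng.normal(0, 1, (60, 5))
    y = np.repeat(["a", "b", "c"], 20)
    x[y == "a", 0] += 3
    x[y == "b", 1] += 3
    clf = train_classifier(x, y, ClassifierConfig(n_trees=30, seed=2))
    rep = evaluate(clf, x, y)
    assert set(rep.per_class_auc.index) == {"a", "b", "c"}
    assert rep.confusion.to_numpy().sum() == 60
    assert (rep.per_class_auc > 0.9).all()  # training-set separability


# ---------------------------------------------------------------------------
# screening


def test_mann_whitney_exact_small_sample():
    df = pd.DataFrame({"f": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]})
    res = screen_features(df, ["a", "a", "a", "b", "b", "b"])
    # fully separated ranks: exact two-sided p = 2/20
    assert res.loc[0, "p_value"] == pytest.approx(0.1, abs=1e-12)
    assert res.loc[0, "test"] == "mann_whitney_u"
    exact = stats.mannwhitneyu([1, 2, 3], [4, 5, 6], alternative="two-sided", method="exact").pvalue
    assert res.loc[0, "p_value"] == exact


def test_identical_groups_not_significant():
    df = pd.DataFrame({"f": [0.3, 0.5, 0.7, 0.3, 0.5, 0.7]})
    res = screen_features(df, ["a", "a", "a", "b", "b", "b"])
    assert res.loc[0, "p_value"] >= 0.9


def test_three_groups_use_anova(rng):
    df = pd.DataFrame(rng.normal(0, 1, (30, 3)), columns=["f1", "f2", "f3"])
    res = screen_features(df, np.repeat(["a", "b", "c"], 10))
    assert (res["test"] == "one_way_anova").all()
    assert (res["p_adjusted"] >= res["p_value"] - 1e-15).all()


def test_screen_sorted_with_occupancy_range(rng):
    x = rng.uniform(0, 0.3, (20, 5))
    x[:10, 2] += 0.5  # strongly group-associated feature
    df = pd.DataFrame(x, columns=[f"f{i}" for i in range(5)])
    res = screen_features(df, ["a"] * 10 + ["b"] * 10)
    assert res.loc[0, "feature"] == "f2"
    assert (res["p_value"].diff().dropna() >= 0).all()
    assert (res["min_occupancy"] <= res["max_occupancy"]).all()


def test_small_group_rejected():
    df = pd.DataFrame({"f": [1.0, 2.0, 3.0]})
    with pytest.raises(ConfigurationError, match="fewer than 2"):
        screen_features(df, ["a", "a", "b"])
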