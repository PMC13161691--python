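"""Phenotype classification on voxel features and univariate feature
screening.

Classification uses gradient-boosted decision trees (500 trees, depth 6 by
default) on z-scored occupancy features, with inverse-frequency class weights
and an F1-tuned decision threshold for binary tasks. Evaluation supports a
held-out batch or leave-one-batch-out cross-validation, so generalization is
always measured across technical conditions. Screening ranks features by
two-sided Mann-Whitney U (two groups) or one-way ANOVA (three or more),
reporting raw and Benjamini-Hochberg adjusted p values plus each feature's
occupancy range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import (
    auc,
    confusion_matrix,
    precision_recall_curve,
    roc_curve,
)
from statsmodels.stats.multitest import multipletests
from xgboost import XGBClassifier

from .core import ConfigurationError
from .voxels import VoxelFeatureMatrix

__all__ = [
    "ClassifierConfig",
    "EvaluationReport",
    "standardize",
    "train_classifier",
    "tune_threshold",
    "evaluate",
    "leave_one_batch_out",
    "screen_features",
]


@dataclass
class ClassifierConfig:
    n_trees: int = 500
    max_depth: int = 6
    class_weighting: bool = True
    standardize: bool = True
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.max_depth < 1:
            raise ConfigurationError("n_trees and max_depth must be positive")
        if not 0.0 < self.threshold < 1.0:
            raise ConfigurationError("decision threshold must lie in (0, 1)")


@dataclass
class Standardizer:
    """Per-feature z-scoring with statistics fitted on training rows only.

    Population-sd convention; zero-variance features map to 0."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, x: np.ndarray) -> "Standardizer":
        if x.shape[0] == 0:
            raise ConfigurationError("cannot fit a standardizer on zero rows")
        mean = x.mean(axis=0)
        sd = x.std(axis=0)  # population sd (ddof=0)
        n_const = int((sd == 0).sum())
        if n_const:
            warnings.warn(f"{n_const} zero-variance features standardized to 0", stacklevel=2)
        return cls(mean=mean, sd=sd)

    def transform(self, x: np.ndarray) -> np.ndarray:
        safe_sd = np.where(self.sd == 0, 1.0, self.sd)
        out = (x - self.mean) / safe_sd
        out[:, self.sd == 0] = 0.0
        return out


def standardize(x: np.ndarray, fit_rows: np.ndarray | None = None) -> tuple[np.ndarray, Standardizer]:
    """Z-score ``x`` using statistics from ``x[fit_rows]`` (all rows by
    default); returns the transformed matrix and the fitted scaler."""
    x = np.asarray(x, dtype=np.float64)
    scaler = Standardizer.fit(x if fit_rows is None else x[fit_rows])
    return scaler.transform(x), scaler


@dataclass
class FittedClassifier:
    model: XGBClassifier
    scaler: Standardizer | None
    classes: np.ndarray
    config: ClassifierConfig

    def scores(self, x: np.ndarray) -> np.ndarray:
        """Predicted probabilities; column 1 is the positive class for binary
        tasks."""
        if self.scaler is not None:
            x = self.scaler.transform(np.asarray(x, dtype=np.float64))
        return self.model.predict_proba(x)


def _encode_labels(labels) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    classes, encoded = np.unique(labels, return_inverse=True)
    return classes, encoded


def train_classifier(
    features: np.ndarray | pd.DataFrame,
    labels,
    cfg: ClassifierConfig | None = None,
) -> FittedClassifier:
    """Fit the boosted-tree ensemble (seeded, single-threaded for
    reproducibility)."""
    cfg = cfg or ClassifierConfig()
    x = np.asarray(features, dtype=np.float64)
    classes, y = _encode_labels(labels)
    if classes.size < 2:
        raise ConfigurationError("training labels contain a single class")
    scaler = None
    if cfg.standardize:
        x, scaler = standardize(x)
    weights = None
    if cfg.class_weighting:
        counts = np.bincount(y)
        weights = (len(y) / (classes.size * counts))[y]
    model = XGBClassifier(
        n_estimators=cfg.n_trees,
        max_depth=cfg.max_depth,
        random_state=cfg.seed,
        n_jobs=1,
        tree_method="hist",
        eval_metric="logloss",
    )
    model.fit(x, y, sample_weight=weights)
    return FittedClassifier(model=model, scaler=scaler, classes=classes, config=cfg)


def tune_threshold(clf: FittedClassifier, features, labels) -> float:
    """F1-maximizing decision threshold over the validation scores.

    Candidates are the sorted unique predicted scores; ties in F1 break
    toward the lower threshold. Degenerate validation sets fall back to 0.5
    with a warning.
    """
    if clf.classes.size != 2:
        raise ConfigurationError("threshold tuning applies to binary tasks only")
    _, y = _encode_labels(labels)
    if np.unique(y).size < 2:
        warnings.warn("validation labels contain one class; keeping threshold 0.5", stacklevel=2)
        return 0.5
    scores = clf.scores(features)[:, 1]
    candidates = np.unique(scores)
    if candidates.size < 2:
        warnings.warn("degenerate single-score output; keeping threshold 0.5", stacklevel=2)
        return 0.5
    best_t, best_f1 = None, -1.0
    for t in candidates:  # ascending, so strict improvement keeps lowest tie
        pred = scores >= t
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        fn = int(np.sum(~pred & (y == 1)))
        f1 = 2 * tp / (2 * tp + fp + fn) if tp else 0.0
        if f1 > best_f1:
            best_t, best_f1 = float(t), f1
    return best_t


@dataclass
class EvaluationReport:
    roc_auc: float
    pr_auc: float
    roc_points: pd.DataFrame  # fpr, tpr, threshold
    pr_points: pd.DataFrame  # precision, recall, threshold
    confusion: pd.DataFrame
    per_class_accuracy: pd.Series
    split: str = ""
    per_class_auc: pd.Series | None = None  # one-vs-rest, multi-class only

    def to_dict(self) -> dict:
        out = {
            "roc_auc": self.roc_auc,
            "pr_auc": self.pr_auc,
            "split": self.split,
            "per_class_accuracy": self.per_class_accuracy.to_dict(),
        }
        if self.per_class_auc is not None:
            out["per_class_auc"] = self.per_class_auc.to_dict()
        return out


def _binary_report(y: np.ndarray, scores: np.ndarray, threshold: float, classes, split: str) -> EvaluationReport:
    fpr, tpr, roc_th = roc_curve(y, scores)
    precision, recall, pr_th = precision_recall_curve(y, scores)
    pred = (scores >= threshold).astype(int)
    cm = confusion_matrix(y, pred, labels=[0, 1])
    with np.errstate(invalid="ignore"):
        per_class = pd.Series(np.diag(cm) / cm.sum(axis=1), index=classes)
    return EvaluationReport(
        roc_auc=float(auc(fpr, tpr)),
        pr_auc=float(auc(recall, precision)),
        roc_points=pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": roc_th}),
        pr_points=pd.DataFrame(
            {"precision": precision, "recall": recall,
             "threshold": np.append(pr_th, np.nan)}
        ),
        confusion=pd.DataFrame(cm, index=classes, columns=classes),
        per_class_accuracy=per_class,
        split=split,
    )


def evaluate(
    clf: FittedClassifier | None,
    features,
    labels,
    threshold: float = 0.5,
    scores: np.ndarray | None = None,
    split: str = "holdout",
) -> EvaluationReport:
    """Score a test set: ROC/PR curves and areas, confusion matrix at the
    decision threshold, per-class accuracy.

    Multi-class tasks report one-vs-rest ROC areas and argmax predictions;
    the scalar ``roc_auc`` is then the unweighted mean over classes.
    Pre-computed ``scores`` may be passed (pooled cross-validation folds).
    """
    classes, y = _encode_labels(labels)
    if scores is None:
        if clf is None:
            raise ConfigurationError("either a classifier or scores must be supplied")
        if features is not None and clf.model.n_features_in_ != np.asarray(features).shape[1]:
            raise ConfigurationError(
                f"test set has {np.asarray(features).shape[1]} feature columns, "
                f"model expects {clf.model.n_features_in_}"
            )
        scores = clf.scores(features)
        classes = clf.classes
        y = np.searchsorted(classes, np.asarray(labels))
    if classes.size == 2:
        return _binary_report(y, scores[:, 1] if scores.ndim == 2 else scores, threshold, classes, split)

    # multi-class: one-vs-rest areas + argmax confusion
    aucs = {}
    for i, cls in enumerate(classes):
        fpr, tpr, _ = roc_curve((y == i).astype(int), scores[:, i])
        aucs[cls] = float(auc(fpr, tpr))
    pred = scores.argmax(axis=1)
    cm = confusion_matrix(y, pred, labels=range(classes.size))
    per_class = pd.Series(np.diag(cm) / cm.sum(axis=1), index=classes)
    per_auc = pd.Series(aucs)
    return EvaluationReport(
        roc_auc=float(per_auc.mean()),
        pr_auc=float("nan"),
        roc_points=pd.DataFrame(),
        pr_points=pd.DataFrame(),
        confusion=pd.DataFrame(cm, index=classes, columns=classes),
        per_class_accuracy=per_class,
        split=split,
        per_class_auc=per_auc,
    )


def leave_one_batch_out(
    features: pd.DataFrame,
    labels,
    batches,
    cfg: ClassifierConfig | None = None,
) -> tuple[EvaluationReport, list[EvaluationReport]]:
    """Batch-wise cross-validation: train on n-1 batches, test on the held-out
    one; folds partition the samples exactly once. Returns the pooled report
    (scores concatenated over folds) plus per-fold reports."""
    cfg = cfg or ClassifierConfig()
    x = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    batches = np.asarray(batches)
    classes = np.unique(labels)
    pooled_scores = np.zeros((len(labels), classes.size))
    fold_reports = []
    for batch in np.unique(batches):
        test = batches == batch
        train = ~test
        if np.unique(labels[train]).size < 2:
            raise ConfigurationError(f"training fold excluding {batch!r} has a single class")
        clf = train_classifier(x[train], labels[train], cfg)
        scores = clf.scores(x[test])
        pooled_scores[test] = scores
        fold_reports.append(
            evaluate(None, None, labels[test], cfg.threshold, scores=scores, split=f"holdout:{batch}")
        )
    pooled = evaluate(None, None, labels, cfg.threshold, scores=pooled_scores, split="leave-one-batch-out")
    return pooled, fold_reports


def screen_features(
    vfm: VoxelFeatureMatrix | pd.DataFrame,
    groups,
) -> pd.DataFrame:
    """Univariate screen of every voxel feature between sample groups.

    Two groups: two-sided Mann-Whitney U, exact when the combined sample size
    is at most 20 with no ties, normal approximation with tie and continuity
    correction otherwise. Three or more groups: one-way ANOVA F test. Returns
    a table sorted by ascending raw p with Benjamini-Hochberg adjusted p and
    the feature's occupancy range across samples.
    """
    data = vfm.data if isinstance(vfm, VoxelFeatureMatrix) else vfm
    groups = np.asarray(groups)
    if len(groups) != len(data):
        raise ConfigurationError("group labels must match the number of samples")
    names, counts = np.unique(groups, return_counts=True)
    if names.size < 2:
        raise ConfigurationError("screening needs at least two groups")
    for name, count in zip(names, counts):
        if count < 2:
            raise ConfigurationError(f"group {name!r} has fewer than 2 samples")

    rows = []
    x = data.to_numpy()
    for col, feature in enumerate(data.columns):
        by_group = [x[groups == g, col] for g in names]
        if names.size == 2:
            a, b = by_group
            has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
            method = "exact" if (a.size + b.size <= 20 and not has_ties) else "asymptotic"
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)
            test = "mann_whitney_u"
        else:
            p = float(stats.f_oneway(*by_group).pvalue)
            test = "one_way_anova"
        rows.append(
            {
                "feature": feature,
                "test": test,
                "p_value": p,
                "min_occupancy": float(x[:, col].min()),
                "max_occupancy": float(x[:, col].max()),
            }
        )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out["adjust_method"] = "benjamini-hochberg"
    return out.sort_values("p_value", kind="mergesort", ignore_index=True)
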