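"""Scaffold-stratified multiclass QSAR classification.

Pipeline per modeling group: class balancing by oversampling, a train/test
split, variance + correlation feature filtering (fitted on the training set
only), a one-vs-rest classifier from a 12-algorithm registry, stratified
10-fold cross-validation pooled into a single out-of-fold confusion matrix,
and held-out test evaluation.

Metrics are computed from the confusion matrix (rows = true class,
columns = predicted):

* accuracy      = trace / total;
* micro recall  = sum_i (support_i / total) * (TP_i / support_i)
                  — algebraically identical to accuracy in the multiclass
                  setting, so the two are asserted against each other;
* multiclass MCC (the R_k statistic)
                  = (c*s - sum_k p_k t_k) /
                    sqrt((s^2 - sum p_k^2)(s^2 - sum t_k^2))
  with c the trace, s the total, p the column (predicted) marginals and t
  the row (true) marginals; a zero denominator scores 0 by convention.

Collapsing the 4-class matrix to binary (positive = potent + active) yields
Q2 (binary accuracy), the chance agreement of the marginals
Q2_rnd = sum_k row_k * col_k / total^2 (0.5 for perfectly balanced
marginals), and their difference dQ2.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold
from sklearn.multiclass import OneVsRestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .curation import (
    DEFAULT_SEED,
    CompoundRecord,
    balance_by_oversampling,
    split_train_test,
)
from .descriptors import compute_fingerprint
from .errors import (
    ConfigurationError,
    DegenerateFeaturesError,
    DegenerateLabelError,
)

log = logging.getLogger(__name__)

CLASS_ORDER = ("potent", "active", "intermediate", "inactive")


def _make_estimator(name: str, seed: int):
    if name == "DT":
        return DecisionTreeClassifier(random_state=seed)
    if name == "ET":
        return ExtraTreesClassifier(random_state=seed)
    if name == "RF":
        return RandomForestClassifier(random_state=seed)
    if name == "GB":
        return GradientBoostingClassifier(random_state=seed)
    if name == "LGBM":
        from lightgbm import LGBMClassifier

        return LGBMClassifier(random_state=seed, verbose=-1)
    if name == "XGB":
        from xgboost import XGBClassifier

        return XGBClassifier(random_state=seed)
    if name == "MLP":
        return MLPClassifier(random_state=seed)
    if name == "LR":
        return LogisticRegression(random_state=seed)
    if name == "KNN":
        return KNeighborsClassifier()
    if name == "SVM":
        return SVC(random_state=seed)
    if name == "NB":
        return GaussianNB()
    if name == "GP":
        return GaussianProcessClassifier(random_state=seed)
    raise ConfigurationError(f"unknown algorithm {name!r}")


ALGORITHMS = ("DT", "ET", "RF", "GB", "LGBM", "XGB", "MLP", "LR", "KNN", "SVM", "NB", "GP")


@dataclass(frozen=True)
class ModelConfig:
    algorithm: str
    fingerprint_scheme: str = "ecfp4"
    seed: int = DEFAULT_SEED
    cv_folds: int = 10
    test_fraction: float = 0.2
    stratify_split: bool = True

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ConfigurationError(
                f"algorithm must be one of {ALGORITHMS}, got {self.algorithm!r}"
            )


@dataclass(frozen=True)
class ConfusionMatrix:
    labels: tuple[str, ...]
    counts: np.ndarray  # (k, k); rows = true, columns = predicted

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ConfigurationError("confusion matrix must be square")
        if counts.shape[0] != len(self.labels):
            raise ConfigurationError("label count must match matrix size")
        if np.any(counts < 0):
            raise ConfigurationError("confusion matrix entries must be >= 0")

    @classmethod
    def from_predictions(
        cls, y_true: Sequence[str], y_pred: Sequence[str], labels: Sequence[str]
    ) -> "ConfusionMatrix":
        return cls(tuple(labels), _sk_confusion(y_true, y_pred, labels=list(labels)))

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of correct predictions: trace / total."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def micro_recall(cm: ConfusionMatrix) -> float:
    """Support-weighted mean of per-class recalls (micro-averaged recall)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    support = cm.counts.sum(axis=1)  # TP_i + FN_i
    tp = np.diag(cm.counts)
    total = cm.total
    out = 0.0
    for t_i, tp_i in zip(support, tp):
        if t_i > 0:
            out += (t_i / total) * (tp_i / t_i)
    return float(out)


def multiclass_mcc(cm: ConfusionMatrix) -> float:
    """Multiclass Matthews correlation (R_k); 0 when the denominator vanishes."""
    counts = cm.counts.astype(float)
    s = counts.sum()
    c = np.trace(counts)
    t = counts.sum(axis=1)  # true-class marginals
    p = counts.sum(axis=0)  # predicted-class marginals
    num = c * s - float(t @ p)
    den = math.sqrt((s * s - float(p @ p)) * (s * s - float(t @ t)))
    if den == 0:
        return 0.0
    return float(num / den)


def collapse_binary(
    cm: ConfusionMatrix, positive: Sequence[str] = ("potent", "active")
) -> tuple[ConfusionMatrix, dict[str, float]]:
    """Block-sum a multiclass matrix into positive vs negative.

    Returns the 2x2 matrix plus q2 (binary accuracy), q2_rnd (chance
    agreement of the marginals) and delta_q2 = q2 - q2_rnd.
    """
    pos_idx = [i for i, lbl in enumerate(cm.labels) if lbl in set(positive)]
    neg_idx = [i for i in range(len(cm.labels)) if i not in pos_idx]
    if not pos_idx or not neg_idx:
        raise ConfigurationError("positive set must split the labels into two blocks")
    groups = (pos_idx, neg_idx)
    out = np.zeros((2, 2), dtype=np.int64)
    for a, rows in enumerate(groups):
        for b, colns in enumerate(groups):
            out[a, b] = cm.counts[np.ix_(rows, colns)].sum()
    cm2 = ConfusionMatrix(("positive", "negative"), out)
    s = cm2.total
    q2 = accuracy(cm2)
    rows = cm2.counts.sum(axis=1)
    cols = cm2.counts.sum(axis=0)
    q2_rnd = float((rows * cols).sum() / (s * s))
    return cm2, {"q2": q2, "q2_rnd": q2_rnd, "delta_q2": q2 - q2_rnd}


def feature_select(
    X: np.ndarray, var_threshold: float = 0.1, corr_threshold: float = 0.90
) -> np.ndarray:
    """Boolean mask of retained feature columns.

    Columns with sample variance below ``var_threshold`` are dropped first;
    the survivors are scanned in index order, dropping any column whose
    absolute Pearson correlation with an earlier *retained* column exceeds
    ``corr_threshold`` (the earlier column wins — a deterministic tie-break).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ConfigurationError("need an (n>=2, d) feature matrix")
    n, d = X.shape
    mask = np.zeros(d, dtype=bool)
    var = X.var(axis=0, ddof=1)
    candidates = np.flatnonzero(var >= var_threshold)
    if candidates.size == 0:
        raise DegenerateFeaturesError("variance filter removed every feature")
    Z = X[:, candidates] - X[:, candidates].mean(axis=0)
    norms = np.sqrt((Z**2).sum(axis=0))
    Z = Z / norms
    kept: list[int] = []
    for j in range(candidates.size):
        if kept:
            r = np.abs(Z[:, kept].T @ Z[:, j])
            if np.any(r > corr_threshold):
                continue
        kept.append(j)
    mask[candidates[kept]] = True
    return mask


def _evaluate(y_true: Sequence[str], y_pred: Sequence[str], labels: Sequence[str]) -> dict:
    cm = ConfusionMatrix.from_predictions(y_true, y_pred, labels)
    return {
        "confusion": cm,
        "accuracy": accuracy(cm),
        "micro_recall": micro_recall(cm),
        "mcc": multiclass_mcc(cm),
    }


def train_model(config: ModelConfig, X: np.ndarray, y: Sequence[str]):
    """Fit a one-vs-rest classifier with seed-fixed randomness."""
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise DegenerateLabelError("training data contains a single class")
    if config.algorithm == "KNN":
        est = _make_estimator("KNN", config.seed)
        if est.n_neighbors > len(y):
            raise ConfigurationError(
                f"KNN needs k <= n ({est.n_neighbors} > {len(y)})"
            )
    model = OneVsRestClassifier(_make_estimator(config.algorithm, config.seed))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    return model


def cross_validate(config: ModelConfig, X: np.ndarray, y: Sequence[str],
                   labels: Sequence[str] | None = None) -> dict:
    """Stratified k-fold CV; out-of-fold predictions pooled into one matrix.

    Returns the pooled metrics plus per-fold accuracies. A class smaller
    than the fold count reduces the fold count with a warning.
    """
    y = np.asarray(y)
    labels = list(labels) if labels is not None else sorted(np.unique(y))
    min_class = int(np.min(np.unique(y, return_counts=True)[1]))
    folds = config.cv_folds
    if min_class < folds:
        log.warning("reducing CV folds from %d to %d (smallest class)", folds, min_class)
        folds = max(2, min_class)
    if len(y) < folds:
        raise ConfigurationError(f"n={len(y)} smaller than fold count {folds}")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=config.seed)
    oof = np.empty(len(y), dtype=object)
    fold_acc = []
    for train_idx, val_idx in skf.split(X, y):
        model = train_model(config, X[train_idx], y[train_idx])
        pred = model.predict(X[val_idx])
        oof[val_idx] = pred
        fold_acc.append(float(np.mean(pred == y[val_idx])))
    result = _evaluate(list(y), list(oof), labels)
    result["fold_accuracies"] = fold_acc
    result["n_folds"] = folds
    return result


@dataclass
class EvalReport:
    group: str
    config: ModelConfig
    feature_mask: np.ndarray
    training: dict
    cv: dict
    test: dict
    hyperparameters: dict = field(default_factory=dict)
    is_best: bool = False

    @property
    def test_accuracy(self) -> float:
        return self.test["accuracy"]


def evaluate_dataset(
    records: Sequence[CompoundRecord],
    config: ModelConfig,
    group: str = "all",
    fingerprint_bits: int = 2048,
) -> EvalReport:
    """Run the full modeling pipeline on one group of curated records.

    Balance -> split -> feature-select (train only) -> train -> CV -> test.
    Fingerprints are computed from each record's structure, so oversampled
    duplicates share their source's features.
    """
    balanced = balance_by_oversampling(records, seed=config.seed)
    train, test = split_train_test(
        balanced, config.test_fraction, seed=config.seed, stratify=config.stratify_split
    )
    labels = [l for l in CLASS_ORDER if any(r.activity_class == l for r in balanced)]

    def fp_matrix(rs):
        return np.vstack(
            [compute_fingerprint(r.smiles, config.fingerprint_scheme, fingerprint_bits).bits
             for r in rs]
        )

    X_train_full = fp_matrix(train).astype(float)
    X_test_full = fp_matrix(test).astype(float)
    mask = feature_select(X_train_full)
    X_train = X_train_full[:, mask]
    X_test = X_test_full[:, mask]
    y_train = np.array([r.activity_class for r in train])
    y_test = np.array([r.activity_class for r in test])

    model = train_model(config, X_train, y_train)
    train_eval = _evaluate(list(y_train), list(model.predict(X_train)), labels)
    cv_eval = cross_validate(config, X_train, y_train, labels)
    test_eval = _evaluate(list(y_test), list(model.predict(X_test)), labels)
    inner = model.estimators_[0] if model.estimators_ else None
    return EvalReport(
        group=group,
        config=config,
        feature_mask=mask,
        training=train_eval,
        cv=cv_eval,
        test=test_eval,
        hyperparameters=dict(inner.get_params()) if inner is not None else {},
    )


def run_model_suite(
    records: Sequence[CompoundRecord],
    configs: Sequence[ModelConfig],
    scaffold_groups: Mapping[str, Sequence[str]] | None = None,
    min_group_size: int = 20,
    fingerprint_bits: int = 2048,
) -> tuple[list[EvalReport], list[dict]]:
    """Run every config on every modeling group.

    ``scaffold_groups`` maps group name -> member compound ids (None = one
    group with everything). Groups too small for a split + CV, or with a
    single class, are skipped with a structured warning. Reports are ranked
    by test accuracy within each group and the best per group is flagged.
    """
    by_id = {r.compound_id: r for r in records}
    if scaffold_groups is None:
        groups = {"all": list(records)}
    else:
        groups = {}
        for name, ids in scaffold_groups.items():
            unknown = [i for i in ids if i not in by_id]
            if unknown:
                raise ConfigurationError(f"group {name!r} references unknown ids {unknown[:5]}")
            groups[name] = [by_id[i] for i in ids]

    reports: list[EvalReport] = []
    skipped: list[dict] = []
    for name, members in groups.items():
        classes = {r.activity_class for r in members}
        if len(members) < min_group_size:
            skipped.append({"group": name, "reason": "too_few_compounds", "n": len(members)})
            log.warning("skipping group %s: only %d compounds", name, len(members))
            continue
        if len(classes) < 2:
            skipped.append({"group": name, "reason": "single_class", "n": len(members)})
            log.warning("skipping group %s: single activity class", name)
            continue
        group_reports = [
            evaluate_dataset(members, cfg, group=name, fingerprint_bits=fingerprint_bits)
            for cfg in configs
        ]
        group_reports.sort(key=lambda r: (-r.test_accuracy, r.config.algorithm))
        if group_reports:
            group_reports[0].is_best = True
        reports.extend(group_reports)
    return reports, skipped


def summary_frame(reports: Sequence[EvalReport]) -> pd.DataFrame:
    """Model-comparison summary (one row per group x algorithm)."""
    return pd.DataFrame(
        [
            {
                "group": r.group,
                "algorithm": r.config.algorithm,
                "fingerprint": r.config.fingerprint_scheme,
                "train_accuracy": r.training["accuracy"],
                "cv_accuracy": r.cv["accuracy"],
                "test_accuracy": r.test["accuracy"],
                "train_mcc": r.training["mcc"],
                "cv_mcc": r.cv["mcc"],
                "test_mcc": r.test["mcc"],
                "n_features": int(r.feature_mask.sum()),
                "best": r.is_best,
            }
            for r in reports
        ]
    )
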