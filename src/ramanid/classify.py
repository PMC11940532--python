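"""Random-Forest classification of windowed peak features with repeated
stratified 70/30 train/test evaluation.

The evaluation protocol is three stratified random 70/30 splits
(Monte-Carlo cross-validation): per class, a shuffled index order is cut
into disjoint per-iteration test blocks whenever class sizes permit, so
every iteration tests on previously unseen samples.  Test predictions are
pooled into a single confusion matrix from which accuracy and
macro-averaged precision/recall/F1 are derived.  A standard stratified
k-fold plan is available as an alternative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .errors import ConfigError, ValidationError

__all__ = [
    "SplitPlan",
    "ClassificationReport",
    "make_splits",
    "make_kfold_splits",
    "train_forest",
    "cross_validate",
    "report_from_predictions",
]


@dataclass
class SplitPlan:
    """Per-iteration train/test index assignments, fully determined by the seed."""

    n_iterations: int
    test_fraction: float
    stratified: bool
    seed: int
    assignments: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)


@dataclass
class ClassificationReport:
    """Pooled confusion matrix and derived metrics.

    ``confusion`` rows are true classes, columns predicted classes, in the
    order of ``class_names``.  Metrics are recomputed from the confusion
    matrix so the report is self-consistent by construction.
    """

    class_names: list[str]
    confusion: np.ndarray
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    per_class: dict[str, dict[str, float]]
    n_iterations: int
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "class_names": self.class_names,
                "confusion": self.confusion.tolist(),
                "accuracy": self.accuracy,
                "macro_precision": self.macro_precision,
                "macro_recall": self.macro_recall,
                "macro_f1": self.macro_f1,
                "per_class": self.per_class,
                "n_iterations": self.n_iterations,
                "seed": self.seed,
            },
            sort_keys=True,
        )


def _class_indices(labels: Sequence[str]) -> dict[str, np.ndarray]:
    labels = np.asarray(labels)
    return {c: np.nonzero(labels == c)[0] for c in sorted(set(labels))}


def make_splits(
    labels: Sequence[str],
    n_iterations: int = 3,
    test_fraction: float = 0.30,
    stratified: bool = True,
    seed: int = 0,
) -> SplitPlan:
    """Stratified random 70/30-style iteration plan.

    Per class, ``round(test_fraction * n_class)`` samples (at least one)
    are assigned to each iteration's test set.  When
    ``n_iterations * per_class_test <= n_class`` the test blocks are drawn
    without replacement across iterations (disjoint); otherwise each
    iteration redraws independently.
    """
    if not 0 < test_fraction < 1:
        raise ConfigError(f"test_fraction must be in (0, 1), got {test_fraction}")
    if n_iterations < 1:
        raise ConfigError("n_iterations must be >= 1")
    labels = np.asarray(labels)
    n = labels.size
    rng = np.random.default_rng(seed)
    plan = SplitPlan(n_iterations, test_fraction, stratified, seed)

    if stratified:
        groups = _class_indices(labels)
        for c, idx in groups.items():
            if idx.size < 2:
                raise ValidationError(f"class {c!r} has fewer than 2 samples")
        shuffled = {c: rng.permutation(idx) for c, idx in groups.items()}
        sizes = {c: max(1, round(test_fraction * idx.size)) for c, idx in groups.items()}
        for t in range(n_iterations):
            test_parts = []
            for c, idx in shuffled.items():
                k = sizes[c]
                if n_iterations * k <= idx.size:
                    test_parts.append(idx[t * k: (t + 1) * k])
                else:
                    test_parts.append(rng.choice(idx, size=k, replace=False))
            test = np.sort(np.concatenate(test_parts))
            train = np.setdiff1d(np.arange(n), test)
            plan.assignments.append((train, test))
    else:
        if n < 2:
            raise ValidationError("need at least 2 samples")
        k = max(1, round(test_fraction * n))
        order = rng.permutation(n)
        for t in range(n_iterations):
            if n_iterations * k <= n:
                test = np.sort(order[t * k: (t + 1) * k])
            else:
                test = np.sort(rng.choice(n, size=k, replace=False))
            train = np.setdiff1d(np.arange(n), test)
            plan.assignments.append((train, test))
    return plan


def make_kfold_splits(labels: Sequence[str], n_folds: int = 3, seed: int = 0) -> SplitPlan:
    """Standard stratified k-fold alternative to the 70/30 iteration plan."""
    labels = np.asarray(labels)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    plan = SplitPlan(n_folds, 1.0 / n_folds, True, seed)
    for train, test in skf.split(np.zeros(labels.size), labels):
        plan.assignments.append((train, test))
    return plan


def train_forest(
    features: np.ndarray,
    labels: Sequence[str],
    n_trees: int = 100,
    seed: int = 0,
) -> RandomForestClassifier:
    """Fit a bagged ensemble of randomized trees (majority vote, sqrt-feature
    subsampling, unlimited depth); deterministic given the seed."""
    if n_trees < 1:
        raise ConfigError(f"n_trees must be >= 1, got {n_trees}")
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValidationError("need at least 2 classes to train a classifier")
    X = np.asarray(features, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValidationError("feature matrix contains non-finite values")
    model = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", random_state=seed, n_jobs=1
    )
    model.fit(X, labels)
    return model


def report_from_predictions(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    class_names: Sequence[str] | None = None,
    n_iterations: int = 1,
    seed: int = 0,
) -> ClassificationReport:
    """Build a pooled report from true/predicted label sequences.

    Metrics are derived from the confusion matrix: accuracy is its trace
    over its total; precision/recall/F1 are macro-averaged over classes
    present in ``y_true`` (classes never predicted get precision 0).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if class_names is None:
        class_names = sorted(set(y_true.tolist()) | set(y_pred.tolist()))
    class_names = list(class_names)
    index = {c: i for i, c in enumerate(class_names)}
    C = len(class_names)
    confusion = np.zeros((C, C), dtype=int)
    for t, p in zip(y_true, y_pred):
        confusion[index[t], index[p]] += 1

    col = confusion.sum(axis=0).astype(float)  # predicted counts
    row = confusion.sum(axis=1).astype(float)  # true counts
    diag = np.diag(confusion).astype(float)
    per_class: dict[str, dict[str, float]] = {}
    precs, recs, f1s = [], [], []
    for i, c in enumerate(class_names):
        if row[i] == 0:
            continue  # class absent from the test pool: excluded from macro average
        prec = diag[i] / col[i] if col[i] > 0 else 0.0
        rec = diag[i] / row[i]
        f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
        per_class[c] = {
            "precision": prec, "recall": rec, "f1": f1, "support": int(row[i])
        }
        precs.append(prec)
        recs.append(rec)
        f1s.append(f1)
    total = confusion.sum()
    return ClassificationReport(
        class_names=class_names,
        confusion=confusion,
        accuracy=float(diag.sum() / total) if total else 0.0,
        macro_precision=float(np.mean(precs)) if precs else 0.0,
        macro_recall=float(np.mean(recs)) if recs else 0.0,
        macro_f1=float(np.mean(f1s)) if f1s else 0.0,
        per_class=per_class,
        n_iterations=n_iterations,
        seed=seed,
    )


def cross_validate(
    features: np.ndarray,
    labels: Sequence[str],
    plan: SplitPlan | None = None,
    n_trees: int = 100,
    seed: int = 0,
) -> ClassificationReport:
    """Train per iteration, predict the held-out block, pool one confusion matrix."""
    labels = np.asarray(labels)
    X = np.asarray(features, dtype=float)
    if plan is None:
        plan = make_splits(labels, seed=seed)
    class_names = sorted(set(labels.tolist()))
    y_true_all: list[str] = []
    y_pred_all: list[str] = []
    for t, (train, test) in enumerate(plan.assignments):
        train_classes = set(labels[train].tolist())
        if train_classes != set(class_names):
            import warnings

            missing = sorted(set(class_names) - train_classes)
            warnings.warn(f"iteration {t}: classes absent from training fold: {missing}")
        model = train_forest(X[train], labels[train], n_trees=n_trees, seed=seed + t)
        y_pred_all.extend(model.predict(X[test]).tolist())
        y_true_all.extend(labels[test].tolist())
    return report_from_predictions(
        y_true_all, y_pred_all, class_names,
        n_iterations=len(plan.assignments), seed=seed,
    )
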