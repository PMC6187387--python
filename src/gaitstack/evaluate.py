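"""Stratified splitting, confusion matrices, and accuracy reporting.

The study protocol splits the feature table 50:50 into train and test within
each gait (stratified, so 2400 rows become 1200/1200 with 300 per gait on
each side) and reports accuracy both overall (trace of the confusion matrix
over the number of test rows) and per class in one-vs-rest form,
(TP + TN) / (TP + TN + FP + FN).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import FeatureMatrix

__all__ = ["EvalReport", "split_5050", "evaluate"]


@dataclass(frozen=True)
class EvalReport:
    """Confusion matrix (rows = truth) with overall and per-class accuracy."""

    class_names: tuple[str, ...]
    confusion: np.ndarray
    per_class: dict[str, dict[str, int]]
    accuracy_overall: float
    per_class_accuracy: dict[str, float]
    n_test: int

    @property
    def accuracy_percent(self) -> float:
        return 100.0 * self.accuracy_overall

    def to_dict(self) -> dict:
        return {
            "class_names": list(self.class_names),
            "confusion": self.confusion.tolist(),
            "per_class": self.per_class,
            "accuracy_overall": self.accuracy_overall,
            "accuracy_percent": self.accuracy_percent,
            "per_class_accuracy": self.per_class_accuracy,
            "n_test": self.n_test,
        }


def split_5050(
    features: FeatureMatrix, seed: int
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Stratified 50:50 split, deterministic given ``seed``.

    Rows are shuffled within each class; the first half goes to train. For
    odd class counts the extra row goes to train. Train and test partition
    the input exactly.
    """
    labels = features.labels
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for name in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == name)
        if len(idx) < 2:
            raise ValueError(f"class {name!r} has fewer than 2 rows")
        idx = rng.permutation(idx)
        half = (len(idx) + 1) // 2  # extra row to train
        train_idx.extend(idx[:half])
        test_idx.extend(idx[half:])
    train_idx = np.sort(np.array(train_idx))
    test_idx = np.sort(np.array(test_idx))

    def take(ix: np.ndarray) -> FeatureMatrix:
        return FeatureMatrix(
            values=features.values[ix],
            labels=labels[ix],
            window_size=features.window_size,
            column_names=features.column_names,
        )

    return take(train_idx), take(test_idx)


def evaluate(
    truth: np.ndarray, predicted: np.ndarray, class_names: tuple[str, ...] | None = None
) -> EvalReport:
    """Build the confusion matrix and accuracy report from label pairs."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape or truth.size == 0:
        raise ValueError("truth and predicted must be equal-length and nonempty")
    if class_names is None:
        class_names = tuple(sorted(set(truth.tolist())))
    index = {name: i for i, name in enumerate(class_names)}
    n_classes = len(class_names)
    confusion = np.zeros((n_classes, n_classes), dtype=int)
    for t, p in zip(truth, predicted):
        if t not in index or p not in index:
            raise ValueError(f"unknown label {t if t not in index else p!r}")
        confusion[index[t], index[p]] += 1
    n_test = int(confusion.sum())

    per_class: dict[str, dict[str, int]] = {}
    per_class_accuracy: dict[str, float] = {}
    for name, i in index.items():
        tp = int(confusion[i, i])
        fn = int(confusion[i].sum() - tp)
        fp = int(confusion[:, i].sum() - tp)
        tn = n_test - tp - fn - fp
        per_class[name] = {"TP": tp, "TN": tn, "FP": fp, "FN": fn}
        per_class_accuracy[name] = (tp + tn) / n_test
    return EvalReport(
        class_names=tuple(class_names),
        confusion=confusion,
        per_class=per_class,
        accuracy_overall=float(np.trace(confusion)) / n_test,
        per_class_accuracy=per_class_accuracy,
        n_test=n_test,
    )
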