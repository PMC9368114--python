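"""Random-forest species classification over the fused informative ions.

The classifier operates on replicate-level rows (each sample contributes
three technical replicates per measurement design) but every reported
figure is sample-level: all replicates of a sample share a
cross-validation fold, and a sample's call is the majority vote over its
replicate predictions (ties broken by the highest mean class-vote
fraction).

Validation follows a 10-times repeated, species-stratified, sample-
grouped 5-fold cross-validation of the training set, plus a single
evaluation on the held-out test samples. Sensitivity (TP/(TP+FN)) and
specificity (TN/(TN+FP)) are computed one-vs-rest per species from the
sample-level confusion matrix, with macro averages as headline figures.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedGroupKFold

from .fusion_stats import FusedMatrix

__all__ = [
    "ClassifierConfig",
    "ClassificationReport",
    "metrics_from_confusion",
    "train_forest",
    "majority_vote",
    "repeated_grouped_cv",
    "evaluate_test",
]


@dataclass
class ClassifierConfig:
    n_trees: int = 500
    max_features: str = "sqrt"
    seed: int = 0
    cv_folds: int = 5
    cv_repeats: int = 10

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.cv_repeats < 1:
            raise ValueError("cv_repeats must be >= 1")


@dataclass
class ClassificationReport:
    """Sample-level confusion matrix with the derived figures of merit."""

    classes: list[str]
    confusion: np.ndarray  # rows = truth, columns = prediction
    per_class: dict[str, dict[str, float]]
    sensitivity: float  # macro average
    specificity: float  # macro average
    accuracy: float
    n_correct: int
    n_total: int
    cv_repeat_accuracies: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "classes": self.classes,
            "confusion": self.confusion.astype(int).tolist(),
            "per_class": self.per_class,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "n_correct": self.n_correct,
            "n_total": self.n_total,
            "cv_repeat_accuracies": self.cv_repeat_accuracies,
        }


def metrics_from_confusion(
    confusion: np.ndarray, classes: list[str] | None = None
) -> ClassificationReport:
    """One-vs-rest TP/TN/FP/FN, sensitivity, specificity and accuracy."""
    M = np.asarray(confusion)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"confusion matrix must be square, got shape {M.shape}")
    if np.any(M < 0):
        raise ValueError("confusion matrix counts must be non-negative")
    k = M.shape[0]
    if classes is None:
        classes = [f"class{i}" for i in range(k)]
    if len(classes) != k:
        raise ValueError("classes length must match matrix size")
    total = int(M.sum())
    per_class: dict[str, dict[str, float]] = {}
    sens, spec = [], []
    for i, c in enumerate(classes):
        tp = int(M[i, i])
        fn = int(M[i].sum() - tp)
        fp = int(M[:, i].sum() - tp)
        tn = total - tp - fn - fp
        sensitivity = tp / (tp + fn) if tp + fn else float("nan")
        specificity = tn / (tn + fp) if tn + fp else float("nan")
        per_class[c] = {
            "TP": tp,
            "TN": tn,
            "FP": fp,
            "FN": fn,
            "sensitivity": sensitivity,
            "specificity": specificity,
        }
        if tp + fn:
            sens.append(sensitivity)
        if tn + fp:
            spec.append(specificity)
    n_correct = int(np.trace(M))
    return ClassificationReport(
        classes=list(classes),
        confusion=M,
        per_class=per_class,
        sensitivity=float(np.mean(sens)) if sens else float("nan"),
        specificity=float(np.mean(spec)) if spec else float("nan"),
        accuracy=n_correct / total if total else float("nan"),
        n_correct=n_correct,
        n_total=total,
    )


def _species_of(fused: FusedMatrix, labels_by_sample: dict[str, str]) -> np.ndarray:
    sids = fused.values.index.get_level_values("sample_id")
    return np.array([labels_by_sample[s] for s in sids])


def train_forest(
    fused_train: FusedMatrix,
    labels_by_sample: dict[str, str],
    config: ClassifierConfig | None = None,
) -> RandomForestClassifier:
    """Fit the seeded random forest on replicate-level rows."""
    import warnings

    cfg = config or ClassifierConfig()
    X = fused_train.values.to_numpy(dtype=float)
    y = _species_of(fused_train, labels_by_sample)
    if len(set(y)) < 2:
        raise ValueError("training data must contain at least 2 classes")
    if X.shape[1] != 18:
        warnings.warn(
            f"expected 18 fused variables, got {X.shape[1]}", stacklevel=2
        )
    model = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        max_features=cfg.max_features,
        random_state=cfg.seed,
    )
    model.fit(X, y)
    return model


def majority_vote(
    model: RandomForestClassifier, fused: FusedMatrix
) -> dict[str, str]:
    """Sample-level calls: majority over replicate predictions.

    Ties are broken by the class with the highest mean vote fraction
    over the sample's replicates, then alphabetically.
    """
    X = fused.values.to_numpy(dtype=float)
    pred = model.predict(X)
    proba = model.predict_proba(X)
    classes = list(model.classes_)
    sids = fused.values.index.get_level_values("sample_id")
    calls: dict[str, str] = {}
    for sid in sids.unique():
        mask = sids == sid
        counts = Counter(pred[mask])
        top = max(counts.values())
        tied = sorted(c for c, n in counts.items() if n == top)
        if len(tied) == 1:
            calls[sid] = tied[0]
        else:
            mean_p = proba[mask].mean(axis=0)
            calls[sid] = max(tied, key=lambda c: (mean_p[classes.index(c)], ), default=tied[0])
    return calls


def _grouped_folds(X, y_rows, sids, n_folds: int, seed: int):
    """Species-stratified, sample-grouped folds.

    Falls back to plain grouped folds (with a logged warning) when some
    class is too small to stratify — e.g. leave-one-sample-out, where
    every fold holds a single sample.
    """
    import logging

    try:
        splitter = StratifiedGroupKFold(
            n_splits=n_folds, shuffle=True, random_state=seed
        )
        yield from splitter.split(X, y_rows, groups=sids)
    except ValueError:
        logging.getLogger("insectprint").warning(
            "classes too small for %d stratified folds; using unstratified "
            "grouped folds", n_folds,
        )
        from sklearn.model_selection import GroupKFold

        splitter = GroupKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        yield from splitter.split(X, y_rows, groups=sids)


def repeated_grouped_cv(
    fused_train: FusedMatrix,
    labels_by_sample: dict[str, str],
    config: ClassifierConfig | None = None,
) -> ClassificationReport:
    """Repeated stratified sample-grouped k-fold CV of the training set.

    Replicates of a sample never straddle a fold boundary. Each repeat
    yields one out-of-fold call per sample; the report carries the
    per-repeat sample-level accuracies and a final confusion matrix
    built from each sample's modal call across repeats.
    """
    cfg = config or ClassifierConfig()
    index = fused_train.values.index
    sids = index.get_level_values("sample_id")
    y_rows = _species_of(fused_train, labels_by_sample)
    sample_ids = list(dict.fromkeys(sids))
    if len(sample_ids) < cfg.cv_folds:
        raise ValueError(
            f"{len(sample_ids)} samples cannot be split into {cfg.cv_folds} folds"
        )
    X = fused_train.values.to_numpy(dtype=float)

    rng = np.random.SeedSequence(cfg.seed)
    repeat_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in rng.spawn(cfg.cv_repeats)]

    calls_per_sample: dict[str, list[str]] = {s: [] for s in sample_ids}
    repeat_acc: list[float] = []
    for rep_seed in repeat_seeds:
        repeat_calls: dict[str, str] = {}
        for train_idx, val_idx in _grouped_folds(X, y_rows, sids, cfg.cv_folds, rep_seed):
            model = RandomForestClassifier(
                n_estimators=cfg.n_trees,
                max_features=cfg.max_features,
                random_state=rep_seed,
            ).fit(X[train_idx], y_rows[train_idx])
            fold = FusedMatrix(values=fused_train.values.iloc[val_idx], level=fused_train.level)
            repeat_calls.update(majority_vote(model, fold))
        correct = sum(repeat_calls[s] == labels_by_sample[s] for s in sample_ids)
        repeat_acc.append(correct / len(sample_ids))
        for s in sample_ids:
            calls_per_sample[s].append(repeat_calls[s])

    classes = sorted(set(labels_by_sample[s] for s in sample_ids))
    cidx = {c: i for i, c in enumerate(classes)}
    M = np.zeros((len(classes), len(classes)), dtype=int)
    for s in sample_ids:
        modal = Counter(calls_per_sample[s]).most_common()
        top = modal[0][1]
        call = sorted(c for c, n in modal if n == top)[0]
        M[cidx[labels_by_sample[s]], cidx[call]] += 1
    report = metrics_from_confusion(M, classes)
    report.cv_repeat_accuracies = repeat_acc
    return report


def evaluate_test(
    model: RandomForestClassifier,
    fused_test: FusedMatrix,
    labels_by_sample: dict[str, str],
    train_sample_ids: set[str] | None = None,
) -> ClassificationReport:
    """Held-out evaluation with sample-level majority-vote calls.

    ``train_sample_ids`` enables the leakage guard: any overlap with the
    test sample ids is an error.
    """
    test_ids = set(fused_test.values.index.get_level_values("sample_id"))
    if train_sample_ids is not None:
        overlap = sorted(test_ids & set(train_sample_ids))
        if overlap:
            raise ValueError(f"test samples overlap the training set: {overlap}")
    calls = majority_vote(model, fused_test)
    classes = sorted(set(labels_by_sample[s] for s in labels_by_sample))
    cidx = {c: i for i, c in enumerate(classes)}
    M = np.zeros((len(classes), len(classes)), dtype=int)
    for sid, call in calls.items():
        M[cidx[labels_by_sample[sid]], cidx[call]] += 1
    return metrics_from_confusion(M, classes)
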