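"""Random-forest classification of cell lines from five-marker profiles.

The protocol: stratified 70/30 train/test split, a forest with 100 trees and
unlimited depth fit on the five integrin weight factors, evaluation by
confusion matrix, per-class precision/recall, per-class F1 and the macro
(unweighted) average F1; the whole split-fit-evaluate cycle is repeated with
independent resplits and the macro-F1 averaged.  A model retrained on the
full labelled set then predicts the composition of a mixed, unlabelled
population.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix

from .synthetic import MARKERS

__all__ = [
    "ClassifierReport",
    "PredictionSummary",
    "RepeatedTrainingResult",
    "split_train_test",
    "train_forest",
    "f1_from_pre_rec",
    "evaluate",
    "report_from_predictions",
    "repeat_training",
    "predict_population",
]


@dataclass
class ClassifierReport:
    """Evaluation of one fitted model on one held-out test set."""

    classes: tuple[str, ...]
    confusion_counts: np.ndarray  # rows = actual, columns = predicted
    confusion_fractions: np.ndarray  # rows normalised to 1 where the class is present
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    macro_f1: float
    accuracy: float
    n_test: int
    seed: int | None = None

    def __post_init__(self) -> None:
        row_sums = self.confusion_counts.sum(axis=1)
        frac_rows = self.confusion_fractions.sum(axis=1)
        for k, total in enumerate(row_sums):
            if total > 0 and abs(frac_rows[k] - 1.0) > 1e-12:
                raise ValueError("confusion fraction rows must sum to 1")


@dataclass
class PredictionSummary:
    """Predicted composition of an unlabelled population."""

    counts: dict[str, int]
    n_total: int
    mean_profiles: pd.DataFrame  # index = predicted class, columns = markers
    predictions: pd.Series = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_total:
            raise ValueError("predicted counts must sum to n_total")


@dataclass
class RepeatedTrainingResult:
    mean_macro_f1: float
    mean_accuracy: float
    reports: list[ClassifierReport]


def split_train_test(
    frame: pd.DataFrame,
    train_fraction: float = 0.7,
    stratified: bool = True,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive train/test partition of a labelled cell table.

    When stratified, per-class proportions are preserved within rounding.
    Reproducible for a fixed seed.
    """
    if not 0.0 < train_fraction <= 1.0:
        raise ValueError("train_fraction must be in (0, 1]")
    if len(frame) == 0:
        raise ValueError("cannot split an empty cell table")
    rng = np.random.default_rng(seed)
    if stratified:
        train_idx = []
        for label, group in frame.groupby("label", sort=True):
            if len(group) == 0:
                raise ValueError(f"empty class {label!r} under stratification")
            perm = rng.permutation(group.index.to_numpy())
            n_train = int(round(train_fraction * len(group)))
            train_idx.extend(perm[:n_train])
        train_mask = frame.index.isin(train_idx)
    else:
        perm = rng.permutation(frame.index.to_numpy())
        n_train = int(round(train_fraction * len(frame)))
        train_mask = frame.index.isin(perm[:n_train])
    train = frame[train_mask].copy()
    test = frame[~train_mask].copy()
    if len(test) == 0:
        warnings.warn("train_fraction leaves an empty test set", stacklevel=2)
    train["split"] = "train"
    test["split"] = "test"
    return train, test


def train_forest(
    train_frame: pd.DataFrame,
    n_trees: int = 100,
    max_depth: int | None = None,
    seed: int | None = None,
) -> RandomForestClassifier:
    """Fit a random forest on the five weight-factor features.

    Defaults (100 trees, unlimited depth) are the scikit-learn defaults the
    original protocol relied on.
    """
    labels = train_frame["label"]
    if labels.nunique() < 2:
        raise ValueError("training set must contain at least 2 classes")
    model = RandomForestClassifier(n_estimators=n_trees, max_depth=max_depth, random_state=seed)
    model.fit(train_frame[list(MARKERS)].to_numpy(), labels.to_numpy())
    return model


def f1_from_pre_rec(pre: float, rec: float) -> float:
    """F1 = 2*PRE*REC / (PRE + REC); 0 when both are 0."""
    if not (0.0 <= pre <= 1.0 and 0.0 <= rec <= 1.0):
        raise ValueError(f"precision/recall must be in [0, 1], got {pre}, {rec}")
    if pre + rec == 0:
        return 0.0
    return 2.0 * pre * rec / (pre + rec)


def report_from_predictions(
    y_true: np.ndarray, y_pred: np.ndarray, classes: tuple[str, ...], seed: int | None = None
) -> ClassifierReport:
    """Build the full evaluation report from actual and predicted labels."""
    counts = confusion_matrix(y_true, y_pred, labels=list(classes)).astype(float)
    row_sums = counts.sum(axis=1, keepdims=True)
    fractions = np.divide(counts, row_sums, out=np.zeros_like(counts), where=row_sums > 0)
    precision, recall, f1 = {}, {}, {}
    for k, cls in enumerate(classes):
        tp = counts[k, k]
        predicted = counts[:, k].sum()
        actual = counts[k, :].sum()
        precision[cls] = tp / predicted if predicted > 0 else 0.0
        recall[cls] = tp / actual if actual > 0 else 0.0
        f1[cls] = f1_from_pre_rec(precision[cls], recall[cls])
    n = int(counts.sum())
    return ClassifierReport(
        classes=classes,
        confusion_counts=counts,
        confusion_fractions=fractions,
        precision=precision,
        recall=recall,
        f1=f1,
        macro_f1=float(np.mean(list(f1.values()))),
        accuracy=float(np.trace(counts) / n) if n else 0.0,
        n_test=n,
        seed=seed,
    )


def evaluate(
    model: RandomForestClassifier, test_frame: pd.DataFrame, seed: int | None = None
) -> ClassifierReport:
    """Confusion matrix, per-class PRE/REC/F1, macro F1 and accuracy on a test set."""
    if len(test_frame) == 0:
        raise ValueError("test set is empty")
    known = set(model.classes_)
    unknown = set(test_frame["label"].unique()) - known
    if unknown:
        raise ValueError(f"test set contains labels the model never saw: {sorted(unknown)}")
    y_pred = model.predict(test_frame[list(MARKERS)].to_numpy())
    return report_from_predictions(
        test_frame["label"].to_numpy(), y_pred, tuple(model.classes_), seed=seed
    )


def repeat_training(
    frame: pd.DataFrame,
    n_iterations: int = 200,
    seed: int | None = None,
    train_fraction: float = 0.7,
    n_trees: int = 100,
    max_depth: int | None = None,
) -> RepeatedTrainingResult:
    """Repeat the stratified split / fit / evaluate cycle and average macro F1.

    Each iteration gets its own derived seeds for the split and the forest, so
    the whole protocol is reproducible from the single top-level seed.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    rng = np.random.default_rng(seed)
    iter_seeds = rng.integers(0, 2**31 - 1, size=(n_iterations, 2))
    reports = []
    for split_seed, fit_seed in iter_seeds:
        train, test = split_train_test(frame, train_fraction, stratified=True, seed=int(split_seed))
        model = train_forest(train, n_trees=n_trees, max_depth=max_depth, seed=int(fit_seed))
        reports.append(evaluate(model, test, seed=int(fit_seed)))
    return RepeatedTrainingResult(
        mean_macro_f1=float(np.mean([r.macro_f1 for r in reports])),
        mean_accuracy=float(np.mean([r.accuracy for r in reports])),
        reports=reports,
    )


def predict_population(
    model: RandomForestClassifier, frame: pd.DataFrame
) -> PredictionSummary:
    """Predict the class of every cell in an unlabelled population.

    Returns per-class counts (summing to the population size) and the mean
    five-marker profile of the cells assigned to each class.
    """
    features = frame[list(MARKERS)]
    if features.shape[1] != model.n_features_in_:
        raise ValueError(
            f"feature dimension mismatch: model expects {model.n_features_in_}, "
            f"got {features.shape[1]}"
        )
    pred = pd.Series(model.predict(features.to_numpy()), index=frame.index, name="predicted")
    counts = {cls: int((pred == cls).sum()) for cls in model.classes_}
    mean_profiles = features.groupby(pred).mean().reindex(model.classes_)
    return PredictionSummary(
        counts=counts, n_total=len(frame), mean_profiles=mean_profiles, predictions=pred
    )
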