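"""KNN classification, cross-validation schemes and confusion metrics.

The classifier is plain k-nearest-neighbor with Euclidean distance and an
unweighted majority vote.  Determinism rules (the original analysis is
silent on both): a tie in the vote goes to the class of the single nearest
neighbor, and ties in distance resolve by record index.

Evaluation schemes:

* leave-one-out CV (:func:`loocv`) — each record predicted from all
  others; fully deterministic, used for the small subject-level cohort;
* stratified k-fold CV (:func:`kfold_cv`) — class proportions preserved
  per fold, fold assignment a deterministic function of the seed; default
  three folds, matching the slice-level analysis.

Metrics use the clinical convention that the *positive* class is injured
(class 0): sensitivity = TP/(TP+FN) is the injured detection rate and
specificity = TN/(TN+FP) the normal detection rate.  Metrics with a zero
denominator are reported as NaN, never silently as 0.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .types import (
    NORMAL_CLASS,
    PATIENT_CLASS,
    ConfusionCounts,
    EvalReport,
    FeatureTable,
)


def knn_predict(
    train_x: np.ndarray, train_y: np.ndarray, query: np.ndarray, k: int
) -> int:
    """Majority class among the k Euclidean-nearest training records."""
    x = np.atleast_2d(np.asarray(train_x, dtype=float))
    y = np.asarray(train_y)
    q = np.asarray(query, dtype=float).ravel()
    if x.shape[1] != q.shape[0]:
        raise DataError(
            f"query dimension {q.shape[0]} does not match training "
            f"dimension {x.shape[1]}"
        )
    if not 1 <= k <= len(y):
        raise ConfigError(f"k={k} outside [1, {len(y)}]")
    d = np.linalg.norm(x - q, axis=1)
    order = np.argsort(d, kind="stable")[:k]  # distance ties: lower index first
    votes = y[order]
    classes, counts = np.unique(votes, return_counts=True)
    winners = classes[counts == counts.max()]
    if len(winners) == 1:
        return int(winners[0])
    return int(votes[0])  # vote tie: class of the single nearest neighbor


def subject_aggregate(slices: FeatureTable) -> FeatureTable:
    """Average each subject's slices into one row; labels propagate.

    Raises if any subject carries mixed class labels.
    """
    frame = slices.frame
    rows = []
    for subject_id, group in frame.groupby("subject_id", sort=True):
        labels = group["class"].unique()
        if len(labels) != 1:
            raise DataError(f"subject {subject_id!r} has mixed class labels")
        row = {"subject_id": subject_id, "slice_id": 0, "class": int(labels[0])}
        for f in slices.feature_names:
            row[f] = float(group[f].mean())
        rows.append(row)
    return FeatureTable(pd.DataFrame(rows), slices.feature_names)


def metrics_from_counts(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity); NaN where a denominator is 0."""
    if counts.total == 0:
        raise DataError("no evaluated records")
    accuracy = (counts.tp + counts.tn) / counts.total
    pos = counts.tp + counts.fn
    neg = counts.tn + counts.fp
    sensitivity = counts.tp / pos if pos else math.nan
    specificity = counts.tn / neg if neg else math.nan
    return accuracy, sensitivity, specificity


def _report_from_predictions(
    table: FeatureTable,
    predicted: np.ndarray,
    scheme: str,
    k: int,
    seed: int | None,
) -> EvalReport:
    truth = table.labels
    tp = int(np.sum((truth == PATIENT_CLASS) & (predicted == PATIENT_CLASS)))
    fn = int(np.sum((truth == PATIENT_CLASS) & (predicted == NORMAL_CLASS)))
    tn = int(np.sum((truth == NORMAL_CLASS) & (predicted == NORMAL_CLASS)))
    fp = int(np.sum((truth == NORMAL_CLASS) & (predicted == PATIENT_CLASS)))
    counts = ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)
    accuracy, sensitivity, specificity = metrics_from_counts(counts)
    preds = pd.DataFrame(
        {
            "subject_id": table.subject_ids,
            "slice_id": table.frame["slice_id"].to_numpy(),
            "truth": truth,
            "predicted": predicted,
        }
    )
    return EvalReport(
        counts=counts,
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        predictions=preds,
        scheme=scheme,
        k=k,
        seed=seed,
        feature_names=list(table.feature_names),
    )


def loocv(table: FeatureTable, k: int = 1) -> EvalReport:
    """Leave-one-out CV: each record predicted from the remaining N-1."""
    n = table.n_records
    if n < 2:
        raise DataError("LOOCV needs at least two records")
    if k > n - 1:
        raise ConfigError(f"k={k} exceeds N-1={n - 1}")
    x = table.values
    y = table.labels
    predicted = np.empty(n, dtype=int)
    for i in range(n):
        keep = np.arange(n) != i
        predicted[i] = knn_predict(x[keep], y[keep], x[i], k)
    return _report_from_predictions(table, predicted, "loocv", k, None)


def stratified_folds(labels: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Fold index per record, class proportions preserved, seed-deterministic."""
    if n_folds < 2:
        raise ConfigError("need at least two folds")
    rng = np.random.default_rng(seed)
    fold = np.empty(len(labels), dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < n_folds:
            raise ConfigError(
                f"class {cls} has {len(idx)} records, fewer than "
                f"{n_folds} folds"
            )
        perm = rng.permutation(idx)
        fold[perm] = np.arange(len(perm)) % n_folds
    return fold


def kfold_cv(
    table: FeatureTable, n_folds: int = 3, k: int = 5, seed: int = 0
) -> EvalReport:
    """Stratified k-fold CV with aggregated held-out confusion counts."""
    x = table.values
    y = table.labels
    fold = stratified_folds(y, n_folds, seed)
    predicted = np.empty(len(y), dtype=int)
    for f in range(n_folds):
        test = fold == f
        train = ~test
        if train.sum() < k:
            raise ConfigError(
                f"fold {f} leaves only {int(train.sum())} training records "
                f"for k={k}"
            )
        for i in np.flatnonzero(test):
            predicted[i] = knn_predict(x[train], y[train], x[i], k)
    return _report_from_predictions(
        table, predicted, f"{n_folds}-fold", k, seed
    )
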