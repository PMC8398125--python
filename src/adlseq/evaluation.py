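"""Evaluation protocol: stratified k-fold CV, one-vs-rest metrics, held-out
and sequential (real-time) evaluation.

All metrics are computed one-vs-rest per class from a confusion matrix whose
rows are true classes and columns predictions.  The matrix may hold raw
counts or row-normalized fractions; in the normalized case every class is
given equal weight (the balanced-design convention), so the same arithmetic
applies to both.  Macro scores are unweighted means over classes.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field, replace as dc_replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .casas_io import ActivityInstance
from .features import Vocabulary, encode_dataset, encode_instance
from .model import Model, ModelSpec, build_model, predict, train_model
from .preprocessing import CLASS_ORDER, Dataset, balance_dataset

__all__ = [
    "EvalReport",
    "stratified_folds",
    "confusion_counts",
    "metrics_from_confusion",
    "cross_validate",
    "evaluate_holdout",
    "evaluate_sequential",
]

_METRIC_COLS = ["precision", "recall", "specificity", "f1", "accuracy", "error"]


@dataclass
class EvalReport:
    """Confusion matrix plus per-class and macro one-vs-rest metrics.

    ``confusion`` is row-normalized (true class in rows); ``counts`` keeps
    the raw tallies when they are known.  ``per_class`` is a DataFrame with
    precision/recall/specificity/f1 in [0, 1] and accuracy/error in percent;
    ``macro`` holds their unweighted means over classes.
    """

    confusion: np.ndarray
    per_class: pd.DataFrame
    macro: dict
    counts: Optional[np.ndarray] = None
    class_order: Sequence[str] = CLASS_ORDER
    n_folds: int = 0
    n_repeats: int = 0

    def to_frame(self) -> pd.DataFrame:
        """Confusion matrix and metrics side by side, one row per class,
        mirroring the usual report layout (confusion columns first, then
        Precision/Recall/Specificity/F1/Accuracy/Error)."""
        conf = pd.DataFrame(
            np.round(self.confusion, 3), index=self.class_order, columns=self.class_order
        )
        return pd.concat([conf, self.per_class.round(3)], axis=1)

    def to_json(self) -> dict:
        return {
            "class_order": list(self.class_order),
            "confusion": self.confusion.tolist(),
            "per_class": self.per_class.to_dict(orient="index"),
            "macro": self.macro,
            "n_folds": self.n_folds,
            "n_repeats": self.n_repeats,
        }


def stratified_folds(labels: Sequence, k: int = 10, seed: int = 0) -> List[np.ndarray]:
    """Partition sample indices into ``k`` disjoint test subsets with equal
    per-class counts in every fold.

    Classes must each have at least ``k`` samples.  When a class count is not
    divisible by ``k`` the remainder is spread over the leading folds.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    folds: List[list] = [[] for _ in range(k)]
    for cls in pd.unique(labels):
        idxs = np.flatnonzero(labels == cls)
        if len(idxs) < k:
            raise ValueError(f"class {cls!r} has {len(idxs)} samples, fewer than k={k}")
        idxs = rng.permutation(idxs)
        for f, chunk in enumerate(np.array_split(idxs, k)):
            folds[f].extend(chunk.tolist())
    return [np.sort(np.asarray(f, dtype=np.int64)) for f in folds]


def confusion_counts(y_true, y_pred, n_classes: int) -> np.ndarray:
    """Raw confusion tallies, rows = true class, columns = predicted."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    out = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(out, (y_true, y_pred), 1)
    return out


def metrics_from_confusion(
    confusion: np.ndarray, class_order: Sequence[str] = CLASS_ORDER
) -> EvalReport:
    """One-vs-rest metric suite from a (counts or row-normalized) confusion
    matrix.

    Per class: precision = TP/(TP+FP), recall = TP/(TP+FN), specificity =
    TN/(TN+FP), F1 the harmonic mean of precision and recall, accuracy =
    (TP+TN)/total in percent and error its complement (so accuracy + error
    is exactly 100).  A class never predicted gets precision (and F1) 0 with
    a warning.  Rows summing to zero (class absent from the data) are left
    out of the macro means.
    """
    M = np.asarray(confusion, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"confusion matrix must be square, got {M.shape}")
    if (M < 0).any():
        raise ValueError("confusion matrix entries must be non-negative")
    if len(class_order) != M.shape[0]:
        raise ValueError("class_order length must match the matrix")
    total = M.sum()
    row = M.sum(axis=1)
    col = M.sum(axis=0)
    tp = np.diag(M)
    fn = row - tp
    fp = col - tp
    tn = total - tp - fn - fp

    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        specificity = np.where(tn + fp > 0, tn / (tn + fp), 0.0)
        f1 = np.where(
            precision + recall > 0,
            2 * precision * recall / (precision + recall),
            0.0,
        )
    if ((tp + fp) == 0).any():
        never = [class_order[j] for j in np.flatnonzero((tp + fp) == 0)]
        warnings.warn(f"classes never predicted (precision set to 0): {never}",
                      stacklevel=2)
    accuracy = (tp + tn) / total * 100.0
    error = 100.0 - accuracy

    per_class = pd.DataFrame(
        np.column_stack([precision, recall, specificity, f1, accuracy, error]),
        index=list(class_order),
        columns=_METRIC_COLS,
    )
    present = row > 0
    if not present.all():
        absent = [class_order[j] for j in np.flatnonzero(~present)]
        warnings.warn(f"classes absent from the data, excluded from macro: {absent}",
                      stacklevel=2)
    macro = {c: float(per_class[c][present].mean()) for c in _METRIC_COLS}
    normalized = np.divide(M, row[:, None], out=np.zeros_like(M), where=row[:, None] > 0)
    counts = M.astype(np.int64) if np.allclose(M, np.round(M)) and total > len(M) else None
    return EvalReport(
        confusion=normalized,
        per_class=per_class,
        macro=macro,
        counts=counts,
        class_order=tuple(class_order),
    )


def _spawn_seeds(seed: int, n: int) -> List[int]:
    rng = np.random.default_rng(seed)
    return rng.integers(0, 2**31 - 1, size=n).tolist()


@dataclass
class CVResult:
    """Cross-validation outcome: the averaged report plus, per repeat, the
    trained fold models and the non-selected (remaining) instances."""

    report: EvalReport
    models: List[List[Model]] = field(default_factory=list)
    remainings: List[Dataset] = field(default_factory=list)


def cross_validate(
    pool: Dataset,
    spec: ModelSpec,
    vocab: Vocabulary,
    n_per_class: Optional[int] = 60,
    k: int = 10,
    repeats: int = 5,
    seed: int = 0,
    keep_models: bool = False,
) -> CVResult:
    """Stratified k-fold cross-validation, repeated on freshly drawn
    balanced sample sets.

    Each repeat draws ``n_per_class`` instances per class from ``pool``
    (``None`` uses the pool as-is, e.g. when it is already balanced), splits
    them into ``k`` stratified folds, trains one model per fold on the other
    k-1 folds and accumulates test confusion counts over every repeat and
    fold.  Everything derives from ``seed``.
    """
    n_classes = spec.n_classes
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    seeds = _spawn_seeds(seed, repeats)
    result = CVResult(report=None)  # type: ignore[arg-type]
    for r in range(repeats):
        rep_seed = seeds[r]
        if n_per_class is not None:
            balanced, remaining = balance_dataset(pool, n_per_class, rep_seed)
        else:
            balanced, remaining = pool, Dataset([], pool.class_order)
        samples = encode_dataset(balanced, vocab, length=spec.sequence_length)
        labels = [s.y for s in samples]
        folds = stratified_folds(labels, k=k, seed=rep_seed)
        fold_seeds = _spawn_seeds(rep_seed, k)
        rep_models = []
        for f, test_idx in enumerate(folds):
            test_mask = np.zeros(len(samples), dtype=bool)
            test_mask[test_idx] = True
            train_samples = [s for s, m in zip(samples, test_mask) if not m]
            test_samples = [s for s, m in zip(samples, test_mask) if m]
            fold_spec = dc_replace(spec, seed=fold_seeds[f])
            model = build_model(fold_spec, vocab_size=len(vocab))
            train_model(model, train_samples)
            y_pred = predict(model, test_samples)
            y_true = [s.y for s in test_samples]
            counts += confusion_counts(y_true, y_pred, n_classes)
            if keep_models:
                rep_models.append(model)
        if keep_models:
            result.models.append(rep_models)
            result.remainings.append(remaining)
    report = metrics_from_confusion(counts, pool.class_order)
    report.counts = counts
    report.n_folds = k
    report.n_repeats = repeats
    result.report = report
    return result


def evaluate_holdout(
    models: Sequence[Model],
    remaining: Dataset,
    vocab: Vocabulary,
) -> EvalReport:
    """Evaluate trained models on the held-out (imbalanced) remainder.

    Confusion counts accumulate over all models and all remaining instances;
    with imbalanced data the headline macro metric is Recall (precision is
    prevalence-sensitive there).  Macro means run over the classes actually
    present.
    """
    if not remaining.instances:
        raise ValueError("remaining dataset is empty")
    if isinstance(models, Model):
        models = [models]
    n_classes = len(remaining.class_order)
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    first_spec = models[0].spec
    samples = encode_dataset(remaining, vocab, length=first_spec.sequence_length)
    y_true = [s.y for s in samples]
    for model in models:
        y_pred = predict(model, samples)
        counts += confusion_counts(y_true, y_pred, n_classes)
    report = metrics_from_confusion(counts, remaining.class_order)
    report.counts = counts
    return report


def _split_periods(
    instances: Sequence[ActivityInstance], period_days: int, anchor_label: str
) -> List[list]:
    """Consecutive windows of at least ``period_days``; each new window opens
    at the first ``anchor_label`` instance at or after the boundary."""
    periods: List[list] = []
    i, n = 0, len(instances)
    while i < n:
        end_ts = instances[i].begin_ts + dt.timedelta(days=period_days)
        j = i + 1
        while j < n and (
            instances[j].begin_ts < end_ts or instances[j].label != anchor_label
        ):
            j += 1
        periods.append(list(instances[i:j]))
        i = j
    return periods


def evaluate_sequential(
    model: Model,
    instances: Sequence[ActivityInstance],
    vocab: Vocabulary,
    class_order: Sequence[str] = CLASS_ORDER,
    period_days: int = 7,
) -> EvalReport:
    """Real-time protocol: the previous-activity feature is the model's own
    previous prediction, not the ground truth.

    The chronological stream is cut into consecutive windows of
    ``period_days``, each re-anchored at the first Sleeping instance after
    the boundary.  Within a window the first instance keeps its ground-truth
    predecessor; every later instance receives the label the model just
    predicted.  Windows with fewer than two instances are skipped with a
    warning.  Recall is the headline macro metric.
    """
    class_order = list(class_order)
    n_classes = len(class_order)
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    for period in _split_periods(instances, period_days, anchor_label="Sleeping"):
        if len(period) < 2:
            warnings.warn(
                f"period starting {period[0].begin_ts} has {len(period)} "
                "instance(s); skipped",
                stacklevel=2,
            )
            continue
        prev_feature = period[0].prev_label
        for inst in period:
            sample = encode_instance(
                dc_replace(inst, prev_label=prev_feature),
                vocab,
                class_order,
                length=model.spec.sequence_length,
            )
            pred = int(predict(model, [sample])[0])
            counts[sample.y, pred] += 1
            prev_feature = class_order[pred]
    report = metrics_from_confusion(counts, class_order)
    report.counts = counts
    return report
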