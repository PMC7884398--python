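"""Cross-validation split enumeration, model selection, and metrics.

Model assessment follows the strict training/validation/testing
discipline: the combined training+validation cohort is explored by
exhaustive leave-k-out enumeration (k = 6 for the 24-subject cohort
gives C(24,6) = 134,596 candidate splits), splits may be restricted to
those balanced between the two tumor classes, and a single finalized
model is then evaluated once on the held-out test cohort.

Metric conventions (positive class = sRCC):

* accuracy = 100 * (TP + TN) / N
* false positive rate = 100 * FP / N
* false negative rate = 100 * FN / N
* PPV = 100 * TP / (TP + FP), NPV = 100 * TN / (TN + FN)

Note the *total-cohort* denominator for FPR and FNR: both rates are
fractions of the whole cohort, not of one class, so
accuracy + FPR + FNR = 100 holds as an identity.  This departs from the
textbook per-class definition and is deliberate — it is the convention
under which the reference confusion tables are self-consistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations, islice
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .activation import ActivationMap
from .errors import StageError
from .lvq import LvqConfig, flatten_map, predict_many, train_lvq

POSITIVE_CLASS = "sRCC"


@dataclass(frozen=True)
class SplitPlan:
    """One leave-k-out split of the combined training+validation cohort."""

    training_ids: tuple[str, ...]
    validation_ids: tuple[str, ...]
    balanced: bool  # equal class counts on both sides


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise StageError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricsRow:
    """Percent metrics under the total-cohort denominator convention."""

    accuracy: float
    fpr: float
    fnr: float
    ppv: float | None  # None when TP + FP = 0
    npv: float | None  # None when TN + FN = 0


def count_leave_k_out(n: int, k: int) -> int:
    """Number of leave-k-out splits, C(n, k), exact integer arithmetic."""
    if not 0 < k < n:
        raise StageError(f"holdout size must satisfy 0 < k < n, got k={k}, n={n}")
    return math.comb(n, k)


def enumerate_leave_k_out(ids: list[str], k: int,
                          labels: Mapping[str, str],
                          max_splits: int | None = None,
                          seed: int = 0) -> Iterator[SplitPlan]:
    """Yield leave-k-out splits in deterministic lexicographic order.

    The held-out ``k`` subjects form the validation side.  Splits are
    enumerated over the sorted id list, so the order is reproducible
    regardless of input order.  When ``max_splits`` is given, a seeded
    uniform subsample of that size is yielded instead (still in
    lexicographic order) — the desk-scale mode, since every split costs
    one LVQ training.
    """
    ids_sorted = sorted(ids)
    n = len(ids_sorted)
    total = count_leave_k_out(n, k)

    selected: set[int] | None = None
    if max_splits is not None and max_splits < total:
        rng = np.random.default_rng(seed)
        selected = set(rng.choice(total, size=max_splits, replace=False).tolist())

    for rank, held_out in enumerate(combinations(ids_sorted, k)):
        if selected is not None and rank not in selected:
            continue
        val = tuple(held_out)
        train = tuple(s for s in ids_sorted if s not in held_out)
        yield SplitPlan(training_ids=train, validation_ids=val,
                        balanced=_balanced(train, labels) and _balanced(val, labels))


def _balanced(side: tuple[str, ...], labels: Mapping[str, str]) -> bool:
    counts: dict[str, int] = {}
    for s in side:
        counts[labels[s]] = counts.get(labels[s], 0) + 1
    return len(set(counts.values())) == 1 and len(counts) > 1


def confusion_metrics(m: ConfusionMatrix) -> MetricsRow:
    """Percent metrics from a confusion matrix (see module docstring)."""
    total = m.total
    if total < 1:
        raise StageError("confusion matrix is empty")
    return MetricsRow(
        accuracy=100.0 * (m.tp + m.tn) / total,
        fpr=100.0 * m.fp / total,
        fnr=100.0 * m.fn / total,
        ppv=None if m.tp + m.fp == 0 else 100.0 * m.tp / (m.tp + m.fp),
        npv=None if m.tn + m.fn == 0 else 100.0 * m.tn / (m.tn + m.fn),
    )


def confusion_from_predictions(true: list[str], pred: list[str],
                               positive: str = POSITIVE_CLASS) -> ConfusionMatrix:
    tp = sum(1 for t, p in zip(true, pred) if t == positive and p == positive)
    fn = sum(1 for t, p in zip(true, pred) if t == positive and p != positive)
    fp = sum(1 for t, p in zip(true, pred) if t != positive and p == positive)
    tn = sum(1 for t, p in zip(true, pred) if t != positive and p != positive)
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def cross_validate(maps: Mapping[str, ActivationMap],
                   labels: Mapping[str, str],
                   lvq_config: LvqConfig,
                   splits: Iterator[SplitPlan] | list[SplitPlan]) -> pd.DataFrame:
    """Train and score an LVQ model on every split.

    Returns a DataFrame with one row per split: the member ids of both
    sides, the balanced flag, and training/validation accuracy in
    percent.  The same LVQ seed is used for every split, so duplicate
    splits produce identical rows.
    """
    rows = []
    for plan in splits:
        for s in (*plan.training_ids, *plan.validation_ids):
            if s not in maps:
                raise StageError(f"subject {s} has no activation map")
            if s not in labels:
                raise StageError(f"subject {s} has no class label")
        x_train = np.asarray([flatten_map(maps[s]) for s in plan.training_ids])
        y_train = [labels[s] for s in plan.training_ids]
        x_val = np.asarray([flatten_map(maps[s]) for s in plan.validation_ids])
        y_val = [labels[s] for s in plan.validation_ids]
        model = train_lvq(x_train, y_train, lvq_config)
        train_acc = 100.0 * float(np.mean(
            np.asarray(predict_many(model, x_train)) == np.asarray(y_train)))
        val_acc = 100.0 * float(np.mean(
            np.asarray(predict_many(model, x_val)) == np.asarray(y_val)))
        rows.append({
            "training_ids": ",".join(plan.training_ids),
            "validation_ids": ",".join(plan.validation_ids),
            "balanced": plan.balanced,
            "train_accuracy": train_acc,
            "val_accuracy": val_acc,
        })
    return pd.DataFrame(rows)


def select_model(cv_table: pd.DataFrame, threshold: float,
                 require_balanced: bool = False) -> list[SplitPlan]:
    """Splits whose training AND validation accuracy reach ``threshold``.

    Optionally restricted to class-balanced splits; ordered by validation
    accuracy, then training accuracy (both descending), then the
    lexicographic split order of the table.  An empty result is allowed.
    """
    if cv_table.empty:
        raise StageError("cross-validation table is empty")
    df = cv_table.reset_index(drop=True)
    keep = (df["train_accuracy"] >= threshold) & (df["val_accuracy"] >= threshold)
    if require_balanced:
        keep &= df["balanced"].astype(bool)
    df = df[keep]
    df = df.sort_values(["val_accuracy", "train_accuracy"],
                        ascending=[False, False], kind="stable")
    return [
        SplitPlan(training_ids=tuple(r.training_ids.split(",")),
                  validation_ids=tuple(r.validation_ids.split(",")),
                  balanced=bool(r.balanced))
        for r in df.itertuples()
    ]


def take(iterator: Iterator, n: int) -> list:
    """First ``n`` items of an iterator (convenience for split streams)."""
    return list(islice(iterator, n))
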