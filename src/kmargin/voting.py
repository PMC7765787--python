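"""Record-level diagnosis by K-majority voting, and evaluation metrics.

The record label is the class with the most one-hot votes among the top-K
most confident segments.  A vote tie breaks toward the tied class that holds
the single most confident segment (smallest margin), then toward catalog
order.  Evaluation reports the confusion matrix, per-class F1 computed as
2·diag / (row sum + column sum), their unweighted (macro) mean — the headline
metric — and conventional macro precision/recall.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .augment import augment_dataset
from .margin import SelectionResult, kmargin_select
from .model import SegmentClassifier, predict_segment_probs
from .types import AugmentationConfig, ClassCatalog, EvalReport, MonitoringRecord

__all__ = [
    "onehot_votes",
    "kmajority_vote",
    "diagnose_record",
    "evaluate",
]


def onehot_votes(selection: SelectionResult, catalog: ClassCatalog) -> np.ndarray:
    """(K, M) binary matrix; row k is the one-hot of the k-th selected label."""
    votes = np.zeros((len(selection), catalog.n_classes), dtype=np.int64)
    for k, lab in enumerate(selection.labels):
        votes[k, catalog.index(lab)] = 1
    return votes


def kmajority_vote(
    votes: np.ndarray, margins: np.ndarray, catalog: ClassCatalog
) -> str:
    """Class with the largest column sum; ties go to the class holding the
    minimum-margin (most confident) segment, then to catalog order."""
    votes = np.atleast_2d(np.asarray(votes))
    margins = np.asarray(margins, dtype=np.float64)
    if votes.shape[0] < 1:
        raise ValueError("need at least one vote")
    sums = votes.sum(axis=0)
    best = sums.max()
    tied = np.flatnonzero(sums == best)
    if len(tied) == 1:
        return catalog.labels[int(tied[0])]
    # per tied class, the best (smallest) margin among its segments
    best_margin = np.array(
        [margins[votes[:, j] == 1].min() if votes[:, j].any() else np.inf for j in tied]
    )
    return catalog.labels[int(tied[int(np.argmin(best_margin))])]


def diagnose_record(
    model: SegmentClassifier,
    record: MonitoringRecord,
    config: AugmentationConfig,
    catalog: ClassCatalog,
    k: int = 3,
) -> tuple[str, SelectionResult]:
    """Full record pipeline: test-mode augmentation -> segment probabilities ->
    top-K margin selection -> one-hot votes -> K-majority vote."""
    if record.length < 1:
        raise ValueError("record has no samples")
    segments = augment_dataset([record], config, catalog, mode="test")
    probs = predict_segment_probs(model, np.stack([s.data for s in segments]))
    selection = kmargin_select(probs, k, catalog)
    label = kmajority_vote(onehot_votes(selection, catalog), selection.margins, catalog)
    return label, selection


def confusion_matrix(
    predictions: Sequence[str], references: Sequence[str], catalog: ClassCatalog
) -> np.ndarray:
    """(M, M) counts; rows = reference class, columns = predicted class."""
    if len(predictions) != len(references):
        raise ValueError("predictions and references must have equal length")
    cm = np.zeros((catalog.n_classes, catalog.n_classes), dtype=np.int64)
    for pred, ref in zip(predictions, references):
        cm[catalog.index(ref), catalog.index(pred)] += 1
    return cm


def evaluate(
    predictions: Sequence[str], references: Sequence[str], catalog: ClassCatalog
) -> EvalReport:
    """Confusion matrix, per-class and macro F1, macro precision/recall.

    A class absent from both predictions and references contributes F1 = 0
    and is still averaged.  Precision uses predicted-class denominators and
    recall reference-class denominators (the conventional definitions); the
    macro F1 is unaffected by that convention.
    """
    cm = confusion_matrix(predictions, references, catalog)
    diag = np.diag(cm).astype(np.float64)
    row = cm.sum(axis=1).astype(np.float64)  # reference counts
    col = cm.sum(axis=0).astype(np.float64)  # predicted counts
    denom = row + col
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(denom > 0, 2.0 * diag / np.where(denom > 0, denom, 1.0), 0.0)
        prec = np.where(col > 0, diag / np.where(col > 0, col, 1.0), 0.0)
        rec = np.where(row > 0, diag / np.where(row > 0, row, 1.0), 0.0)
    return EvalReport(
        labels=catalog.labels,
        confusion=cm,
        per_class_f1=f1,
        macro_f1=float(f1.mean()),
        precision=float(prec.mean()),
        recall=float(rec.mean()),
    )
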