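"""Knowledge-level feature aggregation, the interpretation loss, and the
joint objective.

Fragment-level predictions from the knowledge head are pooled column-wise into
segment-level features, and segment-level features of the *selected* top-K
confident segments into one record-level vector, with a per-feature operation
matched to the attribute's nature: ``max`` for presence flags, ``mean`` for
levels, ``cv`` (population sd / |mean|, the dispersion coefficient) for
regularity.  The interpretation loss is a plain MSE over selected segments and
features; the joint objective is its exact sum with the classification loss.
"""

from __future__ import annotations

import logging

import numpy as np

from .augment import augment_dataset, split_fragments
from .margin import classification_loss, kmargin_select
from .model import KnowledgeHead, SegmentClassifier, predict_segment_probs
from .types import AugmentationConfig, ClassCatalog, KnowledgeSpec, MonitoringRecord

logger = logging.getLogger("kmargin")

__all__ = [
    "aggregate_features",
    "aggregate_record",
    "knowledge_loss",
    "total_loss",
    "interpret_record",
    "record_knowledge_vector",
    "CV_SENTINEL",
]

#: returned by the cv aggregator when the mean is 0 but values differ
CV_SENTINEL = np.nan


def _cv(values: np.ndarray) -> float:
    """Population coefficient of variation; 0 for constant input, NaN sentinel
    (logged) when the mean is zero with unequal values."""
    sd = float(np.std(values))
    if sd == 0.0:
        return 0.0
    mean = float(np.mean(values))
    if mean == 0.0:
        logger.warning("cv aggregator: zero mean with unequal values; sentinel returned")
        return CV_SENTINEL
    return sd / abs(mean)


_AGG = {
    "max": lambda v: float(np.max(v)),
    "mean": lambda v: float(np.mean(v)),
    "cv": _cv,
}


def aggregate_features(
    unit_features: np.ndarray, spec: KnowledgeSpec
) -> np.ndarray:
    """Column-wise pooling of a (n_units, F) feature block into an (F,) vector."""
    feats = np.atleast_2d(np.asarray(unit_features, dtype=np.float64))
    if feats.shape[0] == 0:
        raise ValueError("nothing to aggregate")
    if feats.shape[1] != spec.n_features:
        raise ValueError(f"expected {spec.n_features} feature columns, got {feats.shape[1]}")
    return np.array([_AGG[agg](feats[:, j]) for j, agg in enumerate(spec.aggregators)])


def aggregate_record(
    segment_features: np.ndarray,
    selected_indices: np.ndarray,
    spec: KnowledgeSpec,
) -> np.ndarray:
    """Record-level vector: pool segment features over the selected segments only.

    ``selected_indices`` are 1-based segment indices (the α selection / top-K).
    """
    feats = np.atleast_2d(np.asarray(segment_features, dtype=np.float64))
    idx = np.asarray(selected_indices, dtype=np.int64)
    if idx.size == 0:
        raise ValueError("empty selection")
    if idx.min() < 1 or idx.max() > feats.shape[0]:
        raise ValueError("selection indices outside segment range")
    return aggregate_features(feats[idx - 1], spec)


def knowledge_loss(predicted: np.ndarray, reference: np.ndarray) -> float:
    """MSE over (selected segments or fragments) x features; 0 iff exact match."""
    predicted = np.asarray(predicted, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if predicted.shape != reference.shape:
        raise ValueError(f"shape mismatch {predicted.shape} vs {reference.shape}")
    diff = predicted - reference
    return float(np.mean(diff * diff))


def total_loss(
    probs: np.ndarray,
    target_indices: np.ndarray,
    predicted_z: np.ndarray,
    reference_z: np.ndarray,
) -> float:
    """Joint objective: classification NLL + knowledge MSE, exactly additive."""
    return classification_loss(probs, target_indices) + knowledge_loss(
        predicted_z, reference_z
    )


def record_knowledge_vector(
    classifier: SegmentClassifier,
    head: KnowledgeHead,
    record: MonitoringRecord,
    config: AugmentationConfig,
    catalog: ClassCatalog,
    spec: KnowledgeSpec,
    k: int = 3,
) -> np.ndarray:
    """Record-level knowledge vector via the production path.

    Only the top-K most confident segments are passed through the knowledge
    head (ceil(W/N) fragment forwards each — the method's entire extra
    inference cost per record), pooled per segment and then across the
    selection.
    """
    segments = augment_dataset([record], config, catalog, mode="test")
    probs = predict_segment_probs(classifier, np.stack([s.data for s in segments]))
    selection = kmargin_select(probs, k, catalog)
    seg_feats = []
    for t in selection.indices:
        frags = np.stack(
            [f.data for f in split_fragments(segments[t - 1], config.fragment_len)]
        )
        seg_feats.append(aggregate_features(head.predict(frags), spec))
    return aggregate_features(np.stack(seg_feats), spec)


def interpret_record(
    classifier: SegmentClassifier,
    head: KnowledgeHead,
    record: MonitoringRecord,
    config: AugmentationConfig,
    catalog: ClassCatalog,
    spec: KnowledgeSpec,
    k: int = 3,
) -> dict:
    """Knowledge features at all three levels for one record.

    Returns ``{"fragment": (T, Q, F), "segment": (T, F), "record": (F,),
    "selected": 1-based top-K indices}``.  Fragment predictions come from the
    knowledge head; segment features pool fragments; the record vector pools
    the top-K most confident segments only, so noisy segments do not leak into
    the record-level interpretation.
    """
    if not head.trained:
        raise ValueError("knowledge head has not been trained")
    segments = augment_dataset([record], config, catalog, mode="test")
    probs = predict_segment_probs(classifier, np.stack([s.data for s in segments]))
    selection = kmargin_select(probs, k, catalog)
    frag_feats = []
    for seg in segments:
        frags = np.stack([f.data for f in split_fragments(seg, config.fragment_len)])
        frag_feats.append(head.predict(frags))
    frag_feats = np.stack(frag_feats)  # (T, Q, F)
    seg_feats = np.stack([aggregate_features(ff, spec) for ff in frag_feats])
    rec_feat = aggregate_record(seg_feats, selection.indices, spec)
    return {
        "fragment": frag_feats,
        "segment": seg_feats,
        "record": rec_feat,
        "selected": selection.indices,
    }
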