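"""End-to-end training of the margin-filtered pipeline.

Each epoch, the current model predicts all training segments; per record, the
α gate decides whether the loss is restricted to the top-K most confident
segments (margin filtering) or uses everything; one pass of minibatch
optimization then runs on the selected segments.  The selection is recomputed
from the refreshed model state at the start of every epoch.  With filtering
disabled the pipeline degenerates to the plain train-on-all baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .augment import augment_dataset
from .margin import select_alpha_segments
from .model import (
    Adam,
    KnowledgeHead,
    ModelConfig,
    SegmentClassifier,
    build_model,
    train,
)
from .synth import knowledge_for_segments
from .types import AugmentationConfig, ClassCatalog, MonitoringRecord
from .voting import diagnose_record

__all__ = ["FitResult", "fit_pipeline", "predict_records"]


@dataclass
class FitResult:
    classifier: SegmentClassifier
    head: KnowledgeHead
    loss_trace: list[float]
    n_selected_per_epoch: list[int]
    catalog: ClassCatalog


def fit_pipeline(
    records: list[MonitoringRecord],
    aug_config: AugmentationConfig,
    model_config: ModelConfig,
    catalog: ClassCatalog,
    k: int = 3,
    filter_noisy: bool = True,
    alpha_threshold: float = 0.5,
    truths: dict | None = None,
) -> FitResult:
    """Train the segment classifier (and, given truths, the knowledge head).

    ``truths`` maps record id to analytic ground truth (synthetic data); when
    present, per-fragment knowledge references are standardized and the joint
    classification + interpretation objective is optimized.
    """
    segments = augment_dataset(records, aug_config, catalog, mode="train")
    x = np.stack([s.data for s in segments])
    y = np.array([catalog.index(s.inherited_label) for s in segments], dtype=np.int64)
    rec_of_seg = [s.record_id for s in segments]
    record_ids = [r.id for r in records]
    seg_idx_by_record = {rid: [] for rid in record_ids}
    for i, rid in enumerate(rec_of_seg):
        seg_idx_by_record[rid].append(i)

    classifier, head = build_model(model_config, n_channels=x.shape[1])

    z_std = None
    if truths is not None:
        z_raw = knowledge_for_segments(truths, segments, aug_config)  # (S, Q, F)
        flat = z_raw.reshape(-1, z_raw.shape[-1])
        mean = flat.mean(axis=0)
        scale = flat.std(axis=0)
        scale[scale == 0] = 1.0
        head.set_standardizer(mean, scale)
        z_std = (z_raw - mean) / scale

    params = classifier.parameters()
    if z_std is not None:
        seen = {id(p) for p in params}
        params = params + [p for p in head.parameters() if id(p) not in seen]
    optimizer = Adam(params, model_config.learning_rate)
    rng = np.random.default_rng(model_config.seed)

    trace: list[float] = []
    n_selected: list[int] = []
    for _ in range(model_config.epochs):
        if filter_noisy:
            probs = classifier.predict_proba(x)
            chosen: list[int] = []
            for rid in record_ids:
                idx = seg_idx_by_record[rid]
                if not idx:
                    continue
                local = select_alpha_segments(
                    probs[idx], k, catalog, threshold=alpha_threshold
                )
                chosen.extend(idx[t - 1] for t in local)
            sel = np.array(sorted(chosen), dtype=np.int64)
        else:
            sel = np.arange(x.shape[0])
        n_selected.append(int(sel.size))
        epoch_loss = train(
            classifier,
            x[sel],
            y[sel],
            model_config,
            knowledge_head=head if z_std is not None else None,
            knowledge_targets=z_std[sel] if z_std is not None else None,
            optimizer=optimizer,
            epochs=1,
            rng=rng,
        )
        trace.extend(epoch_loss)
    if z_std is not None:
        head.trained = True
    return FitResult(classifier, head, trace, n_selected, catalog)


def predict_records(
    classifier: SegmentClassifier,
    records: list[MonitoringRecord],
    aug_config: AugmentationConfig,
    catalog: ClassCatalog,
    k: int | None = 3,
) -> list[str]:
    """Record-level labels; ``k=None`` votes over all segments (no filtering)."""
    effective_k = k if k is not None else 10**9  # clamps to T per record
    return [
        diagnose_record(classifier, rec, aug_config, catalog, k=effective_k)[0]
        for rec in records
    ]
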