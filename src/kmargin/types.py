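"""Domain types shared across the package.

A *record* is one long multi-channel monitoring time series carrying a single
reference health-condition label (e.g. a multi-minute single-lead ECG).  A
*segment* is a fixed-width window of ``W`` samples cut from a record — the unit
of classifier prediction.  A *fragment* is an ``N``-sample slice of a segment —
the unit of knowledge-feature regression and the time step of the recurrent
layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ClassCatalog",
    "MonitoringRecord",
    "Segment",
    "Fragment",
    "AugmentationConfig",
    "KnowledgeSpec",
    "EvalReport",
]


@dataclass(frozen=True)
class ClassCatalog:
    """Ordered set of health-condition class names, optionally with training counts.

    ``counts`` (records per class in the training set) drive the dynamic,
    skewness-aware augmentation strides; they are absent at prediction time.
    """

    labels: tuple[str, ...]
    counts: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        object.__setattr__(self, "labels", labels)
        if len(labels) < 2:
            raise ValueError("a class catalog needs at least two classes")
        if len(set(labels)) != len(labels):
            raise ValueError("class labels must be unique")
        if self.counts is not None:
            counts = tuple(int(c) for c in self.counts)
            object.__setattr__(self, "counts", counts)
            if len(counts) != len(labels):
                raise ValueError("counts must have one entry per label")
            if any(c < 0 for c in counts):
                raise ValueError("class counts must be nonnegative")

    @property
    def n_classes(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"label {label!r} not in catalog {self.labels}") from None

    def percentages(self, ndigits: int = 2) -> dict[str, float]:
        """Per-class record percentages rounded to ``ndigits`` decimals.

        Requires counts; raises otherwise.
        """
        if self.counts is None:
            raise ValueError("catalog has no counts")
        total = sum(self.counts)
        if total == 0:
            raise ValueError("all class counts are zero")
        return {
            lab: round(100.0 * c / total, ndigits)
            for lab, c in zip(self.labels, self.counts)
        }


@dataclass
class MonitoringRecord:
    """One labeled (or unlabeled) multi-channel monitoring time series.

    ``signal`` has shape ``(L, length)`` — channels by samples.  ``knowledge``
    optionally holds F record-level domain attributes.
    """

    id: str
    signal: np.ndarray
    sampling_rate: float
    label: str | None = None
    knowledge: np.ndarray | None = None

    def __post_init__(self) -> None:
        sig = np.asarray(self.signal, dtype=np.float64)
        if sig.ndim == 1:
            sig = sig[None, :]
        if sig.ndim != 2 or sig.shape[0] < 1 or sig.shape[1] < 1:
            raise ValueError(
                f"record {self.id!r}: signal must be (channels, samples) with "
                f"at least one of each, got shape {sig.shape}"
            )
        self.signal = sig
        if self.knowledge is not None:
            self.knowledge = np.asarray(self.knowledge, dtype=np.float64)

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def length(self) -> int:
        return self.signal.shape[1]


@dataclass
class Segment:
    """A ``W``-wide window of a record.  ``t`` is 1-based, matching field usage."""

    record_id: str
    t: int
    data: np.ndarray  # (L, W)
    offset: int  # 0-based sample offset of the window start in the record
    inherited_label: str | None = None

    @property
    def width(self) -> int:
        return self.data.shape[1]


@dataclass
class Fragment:
    """An ``N``-wide slice of a segment.  ``q`` is 1-based."""

    record_id: str
    t: int
    q: int
    data: np.ndarray  # (L, N)


@dataclass(frozen=True)
class AugmentationConfig:
    """Sliding-window augmentation parameters.

    window
        Segment width W in samples (default 6000: 30 s at 200 Hz / 20 s at 300 Hz).
    max_stride
        Maximum stride threshold M; the most frequent class slides by exactly M,
        rarer classes proportionally less, oversampling the minority.
    fragment_len
        Fragment width N in samples; each segment yields ceil(W/N) fragments.
    test_stride
        Fixed stride used when labels are unknown (prediction mode).
    """

    window: int = 6000
    max_stride: int = 500
    fragment_len: int = 300
    test_stride: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.window >= self.fragment_len >= 1):
            raise ValueError("need window >= fragment_len >= 1")
        if self.max_stride < 1 or self.test_stride < 1:
            raise ValueError("strides must be >= 1")

    @property
    def fragments_per_segment(self) -> int:
        return math.ceil(self.window / self.fragment_len)


_AGGREGATORS = ("max", "mean", "cv")


@dataclass(frozen=True)
class KnowledgeSpec:
    """Names and per-feature aggregators for knowledge-level attributes.

    Each feature is pooled over fragments (then over selected segments) with an
    operation matched to its nature: ``max`` for presence-style flags (did a
    morphological event occur anywhere), ``mean`` for level-style attributes,
    ``cv`` (population sd / |mean|, the dispersion coefficient) for
    regularity-style attributes.
    """

    names: tuple[str, ...]
    aggregators: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "aggregators", tuple(self.aggregators))
        if len(self.names) != len(self.aggregators):
            raise ValueError("one aggregator per feature required")
        bad = [a for a in self.aggregators if a not in _AGGREGATORS]
        if bad:
            raise ValueError(f"unknown aggregators {bad}; choose from {_AGGREGATORS}")

    @property
    def n_features(self) -> int:
        return len(self.names)


@dataclass
class EvalReport:
    """Confusion matrix (rows = reference, cols = predicted) and F1 summary."""

    labels: tuple[str, ...]
    confusion: np.ndarray  # (M, M) ints
    per_class_f1: np.ndarray  # (M,)
    macro_f1: float
    precision: float
    recall: float

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "confusion": self.confusion.tolist(),
            "per_class_f1": {
                lab: float(f) for lab, f in zip(self.labels, self.per_class_f1)
            },
            "macro_f1": float(self.macro_f1),
            "precision": float(self.precision),
            "recall": float(self.recall),
        }
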