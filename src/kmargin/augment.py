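"""Skewness-aware sliding-window augmentation.

Long records are cut into fixed-width segments with a per-class *dynamic
stride*: the most frequent class slides by the maximum stride threshold M,
rarer classes by proportionally less, so minority-class records yield more
segments and the augmented training set is closer to balanced.  Records
shorter than the window are zero-padded at the end.  Segments are further
sliced into ceil(W/N) fragments of width N for the recurrent layer and the
knowledge head.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .types import AugmentationConfig, ClassCatalog, Fragment, MonitoringRecord, Segment

__all__ = [
    "StrideTable",
    "compute_dynamic_strides",
    "zero_pad",
    "slide_windows",
    "split_fragments",
    "augment_dataset",
]


@dataclass(frozen=True)
class StrideTable:
    """Per-class dynamic strides, in samples."""

    strides: dict[str, int]

    def __getitem__(self, label: str) -> int:
        return self.strides[label]


def compute_dynamic_strides(catalog: ClassCatalog, max_stride: int) -> StrideTable:
    """Dynamic stride per class: ``ceil(max_stride * count_c / max_count)``.

    Classes with zero training records get the maximum stride (they generate
    no segments anyway, and a zero stride would be degenerate).
    """
    if catalog.counts is None:
        raise ValueError("catalog must carry training counts")
    counts = np.asarray(catalog.counts)
    if counts.max() == 0:
        raise ValueError("all class counts are zero")
    top = int(counts.max())
    strides = {}
    for lab, c in zip(catalog.labels, catalog.counts):
        strides[lab] = math.ceil(max_stride * c / top) if c > 0 else max_stride
    return StrideTable(strides)


def zero_pad(data: np.ndarray, width: int) -> np.ndarray:
    """Right-pad an (L, n) array with zeros to width ``width`` (n <= width)."""
    data = np.atleast_2d(np.asarray(data, dtype=np.float64))
    n = data.shape[1]
    if n > width:
        raise ValueError(f"cannot pad length {n} down to {width}")
    if n == width:
        return data
    out = np.zeros((data.shape[0], width), dtype=data.dtype)
    out[:, :n] = data
    return out


def slide_windows(record: MonitoringRecord, window: int, stride: int) -> list[Segment]:
    """Cut a record into ``window``-wide segments at the given stride.

    A record shorter than the window yields a single zero-padded segment.
    Windows never overhang the record end: offsets are 0, stride, 2*stride, ...
    while ``offset + window <= length``.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if record.length < window:
        data = zero_pad(record.signal, window)
        return [Segment(record.id, 1, data, 0, record.label)]
    n_segments = (record.length - window) // stride + 1
    return [
        Segment(
            record.id,
            t + 1,
            record.signal[:, t * stride : t * stride + window].copy(),
            t * stride,
            record.label,
        )
        for t in range(n_segments)
    ]


def split_fragments(segment: Segment, fragment_len: int) -> list[Fragment]:
    """Slice a segment into ceil(W/N) fragments of width N (last one zero-padded)."""
    width = segment.width
    if fragment_len > width:
        raise ValueError("fragment_len exceeds segment width")
    n_fragments = math.ceil(width / fragment_len)
    fragments = []
    for q in range(n_fragments):
        chunk = segment.data[:, q * fragment_len : (q + 1) * fragment_len]
        if chunk.shape[1] < fragment_len:
            chunk = zero_pad(chunk, fragment_len)
        fragments.append(Fragment(segment.record_id, segment.t, q + 1, chunk))
    return fragments


def augment_dataset(
    records: Sequence[MonitoringRecord],
    config: AugmentationConfig,
    catalog: ClassCatalog,
    mode: Literal["train", "test"] = "train",
) -> list[Segment]:
    """Augment all records; training mode uses per-class dynamic strides.

    In training mode every record must carry a label and slides with its
    class's dynamic stride; in test mode all records slide with the fixed
    ``config.test_stride`` (labels are not needed).
    """
    if mode == "train":
        table = compute_dynamic_strides(catalog, config.max_stride)
    segments: list[Segment] = []
    for rec in records:
        if mode == "train":
            if rec.label is None:
                raise ValueError(f"record {rec.id!r} is unlabeled in training mode")
            stride = table[rec.label]
        else:
            stride = config.test_stride
        segments.extend(slide_windows(rec, config.window, stride))
    return segments
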