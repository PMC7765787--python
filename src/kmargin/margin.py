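"""Uncertainty margins, top-K confident-segment selection, and the α gate.

The *uncertainty margin* of a segment is the second-highest minus the highest
class probability: it lies in [-1, 0] and is more negative the more decisively
the classifier separates its top two candidate classes.  Iteratively removing
the current most-confident segment K times yields the top-K selection used
both to restrict the training loss to trustworthy segments and to vote the
record-level label.  The α gate only applies the restriction once the mean
top-1 probability over all of a record's segments exceeds a threshold
(default 0.5) — an unreliable early model still trains on everything.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import ClassCatalog

__all__ = [
    "MarginScore",
    "SelectionResult",
    "uncertainty_margin",
    "margins_of",
    "most_confident",
    "kmargin_select",
    "mean_top1_probability",
    "select_alpha_segments",
    "classification_loss",
]

_PROB_EPS = 1e-12


def _check_probs(probs: np.ndarray) -> np.ndarray:
    probs = np.atleast_2d(np.asarray(probs, dtype=np.float64))
    if probs.shape[1] < 2:
        raise ValueError("need at least two classes")
    return probs


def uncertainty_margin(p: np.ndarray) -> float:
    """second_max(p) - max(p); 0 iff the two largest probabilities tie."""
    p = np.asarray(p, dtype=np.float64)
    if p.size < 2:
        raise ValueError("need at least two classes")
    top2 = np.partition(p, -2)[-2:]
    return float(top2[0] - top2[1])


def margins_of(probs_per_segment: np.ndarray) -> np.ndarray:
    """Vectorised margins for a (T, M) probability table."""
    probs = _check_probs(probs_per_segment)
    top2 = np.partition(probs, -2, axis=1)[:, -2:]
    return top2[:, 0] - top2[:, 1]


@dataclass(frozen=True)
class MarginScore:
    value: float

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-9 <= self.value <= 1e-9):
            raise ValueError("margin must lie in [-1, 0]")


@dataclass
class SelectionResult:
    """Top-K most confident segments of one record.

    ``indices`` are 1-based segment indices t in selection order (margins
    nondecreasing, i.e. most confident first); ``labels`` the corresponding
    predicted classes, ``margins`` the margin values.
    """

    indices: np.ndarray  # (K,) ints, 1-based
    labels: list[str]
    margins: np.ndarray  # (K,) floats, nondecreasing

    def __len__(self) -> int:
        return len(self.indices)


def most_confident(
    probs_per_segment: np.ndarray, catalog: ClassCatalog
) -> tuple[int, str]:
    """1-based index of the minimum-margin segment and its top-probability class.

    Margin ties break toward the lowest segment index.
    """
    probs = _check_probs(probs_per_segment)
    if probs.shape[0] == 0:
        raise ValueError("no segments")
    m = margins_of(probs)
    t = int(np.argmin(m))  # argmin takes the first minimum: lowest-index tie-break
    return t + 1, catalog.labels[int(np.argmax(probs[t]))]


def kmargin_select(
    probs_per_segment: np.ndarray, k: int, catalog: ClassCatalog
) -> SelectionResult:
    """Iteratively extract the min(K, T) most confident segments.

    Equivalent to a stable sort of segments by (margin, index) ascending; K
    larger than the number of segments clamps (short records legitimately
    produce few segments).
    """
    if k < 1:
        raise ValueError("K must be >= 1")
    probs = _check_probs(probs_per_segment)
    t_total = probs.shape[0]
    if t_total == 0:
        raise ValueError("no segments")
    m = margins_of(probs)
    order = np.argsort(m, kind="stable")[: min(k, t_total)]
    labels = [catalog.labels[int(np.argmax(probs[t]))] for t in order]
    return SelectionResult(
        indices=order + 1, labels=labels, margins=m[order]
    )


def mean_top1_probability(probs_per_segment: np.ndarray) -> float:
    """α: arithmetic mean of each segment's maximum class probability."""
    probs = _check_probs(probs_per_segment)
    if probs.shape[0] == 0:
        raise ValueError("no segments")
    return float(probs.max(axis=1).mean())


def select_alpha_segments(
    probs_per_segment: np.ndarray,
    k: int,
    catalog: ClassCatalog,
    threshold: float = 0.5,
) -> np.ndarray:
    """Xα: top-K 1-based indices when α > threshold (strict), else all T."""
    probs = _check_probs(probs_per_segment)
    if mean_top1_probability(probs) > threshold:
        return kmargin_select(probs, k, catalog).indices
    return np.arange(1, probs.shape[0] + 1)


def classification_loss(
    probs: np.ndarray, target_indices: np.ndarray
) -> float:
    """Mean negative log-likelihood over selected segments (pooled).

    ``probs`` is the (S, M) table of the selected segments across records and
    ``target_indices`` their reference class indices.  Zero probabilities are
    clipped at a small epsilon.  The loss is >= 0 and 0 iff every selected
    segment puts probability 1 on its target.
    """
    probs = _check_probs(probs)
    target_indices = np.asarray(target_indices, dtype=np.int64)
    if probs.shape[0] != target_indices.shape[0]:
        raise ValueError("one target per selected segment required")
    if probs.shape[0] == 0:
        raise ValueError("no selected segments")
    p = np.clip(probs[np.arange(probs.shape[0]), target_indices], _PROB_EPS, 1.0)
    return float(-np.log(p).mean())
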