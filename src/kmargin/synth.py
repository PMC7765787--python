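"""Seeded generator of synthetic monitoring records.

Emulates the statistical structure the method assumes, at desk scale:

* quasi-periodic waveforms with class-discriminative morphology — a
  ``regular`` rhythm class with a fixed inter-beat interval and a small
  secondary deflection before every main pulse (the "P-wave" analog), an
  ``irregular`` class with strongly jittered intervals and no deflection, and
  a ``noise`` class of broadband noise with no beats;
* configurable class-frequency skew;
* additive baseline noise and sporadic noise bursts;
* contiguous mislabeled spans: a fraction rho of a record's duration carries a
  *different* class's morphology while the record keeps its own label — the
  segment-level label-noise phenomenon the margin filter is built for.

Knowledge-feature ground truth (secondary-deflection presence, inter-beat
interval dispersion, main-pulse amplitude) is computed analytically from the
generation parameters, never estimated from the waveform, so interpretation
tests have exact references.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .io import write_records
from .types import (
    AugmentationConfig,
    ClassCatalog,
    KnowledgeSpec,
    MonitoringRecord,
    Segment,
)

__all__ = [
    "SynthConfig",
    "RecordTruth",
    "SyntheticDataset",
    "default_knowledge_spec",
    "class_counts_from_weights",
    "generate_record",
    "generate_dataset",
    "fragment_truth",
    "knowledge_for_segments",
    "oracle_classify_segment",
]

CLASSES = ("regular", "irregular", "noise")


@dataclass(frozen=True)
class SynthConfig:
    """Generation parameters (times in seconds, amplitudes in arbitrary units)."""

    n_records: int = 200
    class_weights: dict = field(
        default_factory=lambda: {"regular": 0.6, "irregular": 0.3, "noise": 0.1}
    )
    record_length_range: tuple[int, int] = (3000, 4500)  # samples
    sampling_rate: float = 100.0
    beat_period_mean: dict = field(
        default_factory=lambda: {"regular": 0.5, "irregular": 0.5}
    )
    beat_period_sd: dict = field(
        default_factory=lambda: {"regular": 0.005, "irregular": 0.2}
    )
    secondary_deflection_prob: dict = field(
        default_factory=lambda: {"regular": 1.0, "irregular": 0.0}
    )
    main_amp_mean: float = 1.0
    main_amp_sd: float = 0.1
    main_width: float = 0.02
    deflection_amp: float = 0.3
    deflection_width: float = 0.02
    deflection_offset: float = 0.12
    baseline_noise_sd: float = 0.05
    noise_class_sd: float = 0.4
    noise_burst_rate: float = 0.01  # bursts per second
    noise_burst_amp: float = 1.0
    noise_burst_len: float = 0.3
    noisy_span_fraction: float = 0.0  # rho
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.noisy_span_fraction <= 0.5):
            raise ValueError("rho must lie in [0, 0.5]")
        for p in self.secondary_deflection_prob.values():
            if not (0.0 <= p <= 1.0):
                raise ValueError("deflection probabilities must lie in [0, 1]")
        if not all(0.0 <= w for w in self.class_weights.values()):
            raise ValueError("class weights must be nonnegative")


def default_knowledge_spec() -> KnowledgeSpec:
    return KnowledgeSpec(
        names=("deflection_present", "interval_cv", "pulse_amplitude"),
        aggregators=("max", "mean", "mean"),
    )


@dataclass
class RecordTruth:
    """Analytic ground truth of one generated record."""

    length: int
    beat_times: np.ndarray  # sample index of each main pulse center
    beat_amps: np.ndarray
    deflection_times: np.ndarray  # centers of actually-placed deflections
    spans: list[tuple[int, int, str]]  # (start, end, morphology class)


def class_counts_from_weights(weights: dict, n: int) -> dict[str, int]:
    """Deterministic largest-remainder apportionment of n records to classes."""
    labels = list(weights)
    total_w = sum(weights.values())
    exact = {lab: n * weights[lab] / total_w for lab in labels}
    counts = {lab: math.floor(exact[lab]) for lab in labels}
    leftover = n - sum(counts.values())
    by_frac = sorted(labels, key=lambda lab: (-(exact[lab] - counts[lab]), labels.index(lab)))
    for lab in by_frac[:leftover]:
        counts[lab] += 1
    return counts


def _add_pulse(wave: np.ndarray, center: int, amp: float, width_samples: float) -> None:
    half = int(math.ceil(3 * width_samples))
    lo = max(0, center - half)
    hi = min(len(wave), center + half + 1)
    if lo >= hi:
        return
    t = np.arange(lo, hi) - center
    wave[lo:hi] += amp * np.exp(-0.5 * (t / width_samples) ** 2)


def _fill_span(
    wave: np.ndarray,
    start: int,
    end: int,
    morph: str,
    cfg: SynthConfig,
    rng: np.random.Generator,
    truth_beats: list,
    truth_defl: list,
) -> None:
    fs = cfg.sampling_rate
    if morph == "noise":
        wave[start:end] += rng.normal(0.0, cfg.noise_class_sd, size=end - start)
        return
    period = cfg.beat_period_mean[morph]
    sd = cfg.beat_period_sd[morph]
    min_gap = 0.3 * period
    t = start + rng.uniform(0.0, period) * fs
    while t < end:
        center = int(round(t))
        amp = max(0.2, rng.normal(cfg.main_amp_mean, cfg.main_amp_sd))
        _add_pulse(wave, center, amp, cfg.main_width * fs)
        truth_beats.append((center, amp))
        if rng.random() < cfg.secondary_deflection_prob.get(morph, 0.0):
            d_center = center - int(round(cfg.deflection_offset * fs))
            if d_center >= start:
                _add_pulse(wave, d_center, cfg.deflection_amp, cfg.deflection_width * fs)
                truth_defl.append(d_center)
        t += max(min_gap, rng.normal(period, sd)) * fs


def generate_record(
    label: str,
    cfg: SynthConfig,
    rng: np.random.Generator,
    record_id: str = "r0",
) -> tuple[MonitoringRecord, RecordTruth]:
    """One labeled record plus its analytic ground truth.

    With rho > 0, a contiguous span of rho x length is replaced by the
    morphology of a different (randomly chosen) class while the record label is
    unchanged — the injected noisy-label span.
    """
    if label not in CLASSES:
        raise KeyError(f"unknown class {label!r}")
    lo, hi = cfg.record_length_range
    length = int(rng.integers(lo, hi + 1))
    wave = np.zeros(length)
    spans: list[tuple[int, int, str]] = []
    rho = cfg.noisy_span_fraction
    if rho > 0.0:
        span_len = int(round(rho * length))
        span_start = int(rng.integers(0, length - span_len + 1))
        other = str(rng.choice([c for c in CLASSES if c != label]))
        pieces = []
        if span_start > 0:
            pieces.append((0, span_start, label))
        pieces.append((span_start, span_start + span_len, other))
        if span_start + span_len < length:
            pieces.append((span_start + span_len, length, label))
        spans = pieces
    else:
        spans = [(0, length, label)]

    beats: list[tuple[int, float]] = []
    defl: list[int] = []
    for start, end, morph in spans:
        _fill_span(wave, start, end, morph, cfg, rng, beats, defl)

    wave += rng.normal(0.0, cfg.baseline_noise_sd, size=length)
    duration = length / cfg.sampling_rate
    for _ in range(rng.poisson(cfg.noise_burst_rate * duration)):
        b_len = int(cfg.noise_burst_len * cfg.sampling_rate)
        b_start = int(rng.integers(0, max(1, length - b_len)))
        wave[b_start : b_start + b_len] += rng.normal(
            0.0, cfg.noise_burst_amp, size=min(b_len, length - b_start)
        )

    beats.sort()
    truth = RecordTruth(
        length=length,
        beat_times=np.array([b[0] for b in beats], dtype=np.int64),
        beat_amps=np.array([b[1] for b in beats]),
        deflection_times=np.array(sorted(defl), dtype=np.int64),
        spans=spans,
    )
    record = MonitoringRecord(
        id=record_id, signal=wave[None, :], sampling_rate=cfg.sampling_rate, label=label
    )
    return record, truth


@dataclass
class SyntheticDataset:
    records: list[MonitoringRecord]
    truths: dict[str, RecordTruth]
    catalog: ClassCatalog
    config: SynthConfig

    def write(self, out_dir: str | Path) -> Path:
        """Write manifest + CSV signals + a record-level knowledge TSV."""
        out_dir = Path(out_dir)
        manifest = write_records(self.records, out_dir)
        with open(out_dir / "knowledge.tsv", "w") as fh:
            fh.write("id\tdeflection_present\tinterval_cv\tpulse_amplitude\n")
            for rec in self.records:
                t = self.truths[rec.id]
                vals = fragment_truth(t, 0, t.length)
                fh.write(f"{rec.id}\t{vals[0]:.6g}\t{vals[1]:.6g}\t{vals[2]:.6g}\n")
        return manifest


def generate_dataset(cfg: SynthConfig) -> SyntheticDataset:
    """Generate records with class counts following the weights exactly
    (deterministic largest-remainder rounding); fully seeded."""
    rng = np.random.default_rng(cfg.seed)
    counts = class_counts_from_weights(cfg.class_weights, cfg.n_records)
    labels_in_order = [lab for lab in cfg.class_weights for _ in range(counts[lab])]
    records, truths = [], {}
    for i, lab in enumerate(labels_in_order):
        rec, truth = generate_record(lab, cfg, rng, record_id=f"rec{i:04d}")
        records.append(rec)
        truths[rec.id] = truth
    catalog = ClassCatalog(
        labels=tuple(cfg.class_weights),
        counts=tuple(counts[lab] for lab in cfg.class_weights),
    )
    return SyntheticDataset(records, truths, catalog, cfg)


# ---- analytic knowledge ground truth -------------------------------------

def fragment_truth(truth: RecordTruth, start: int, end: int) -> np.ndarray:
    """(deflection_present, interval_cv, pulse_amplitude) for samples [start, end).

    Deflection presence is 1 if any secondary-deflection center lies in the
    window; the interval cv is the population coefficient of variation of
    inter-beat intervals whose endpoints both lie in the window (0 with fewer
    than two intervals); the amplitude is the mean main-pulse amplitude of
    beats in the window (0 with none).
    """
    bt = truth.beat_times
    in_win = (bt >= start) & (bt < end)
    defl = float(np.any((truth.deflection_times >= start) & (truth.deflection_times < end)))
    amps = truth.beat_amps[in_win]
    amp = float(amps.mean()) if amps.size else 0.0
    times = bt[in_win]
    if times.size >= 3:
        intervals = np.diff(times).astype(np.float64)
        mean = intervals.mean()
        cv = float(intervals.std() / mean) if mean > 0 else 0.0
    else:
        cv = 0.0
    return np.array([defl, cv, amp])


def knowledge_for_segments(
    truths: dict[str, RecordTruth],
    segments: Sequence[Segment],
    aug: AugmentationConfig,
) -> np.ndarray:
    """(n_segments, Q, 3) fragment-level ground truth aligned with augmentation.

    Fragment q of a segment at record offset o covers record samples
    [o + (q-1)N, o + qN); windows past the record end are zero-padded signal
    and get all-zero truth.
    """
    q_total = aug.fragments_per_segment
    out = np.zeros((len(segments), q_total, 3))
    for s_i, seg in enumerate(segments):
        truth = truths[seg.record_id]
        for q in range(q_total):
            start = seg.offset + q * aug.fragment_len
            end = min(seg.offset + (q + 1) * aug.fragment_len, truth.length)
            if start < truth.length:
                out[s_i, q] = fragment_truth(truth, start, end)
    return out


# ---- independent morphology oracle ----------------------------------------

def oracle_classify_segment(data: np.ndarray, cfg: SynthConfig) -> str:
    """Rule-based segment classifier used to certify task separability.

    Independent of the learned model: broadband-noise segments are flagged by
    waveform roughness (mean absolute first difference relative to the spread);
    beat segments are classified by detecting main pulses and testing for the
    secondary deflection in the expected pre-beat window.
    """
    x = np.asarray(data, dtype=np.float64)
    if x.ndim == 2:
        x = x[0]
    fs = cfg.sampling_rate
    spread = x.std() + 1e-12
    roughness = np.abs(np.diff(x)).mean() / spread
    if roughness > 0.8:
        return "noise"
    period = cfg.beat_period_mean["regular"]
    peaks, _ = find_peaks(x, height=0.5, distance=int(0.35 * period * fs))
    if len(peaks) < 2:
        return "noise"
    off = int(round(cfg.deflection_offset * fs))
    half = int(round(0.05 * fs))
    hits = 0
    checked = 0
    for p in peaks:
        lo, hi = p - off - half, p - off + half + 1
        if lo < 0:
            continue
        checked += 1
        if x[lo:hi].max() > cfg.deflection_amp / 2:
            hits += 1
    if checked and hits / checked > 0.5:
        return "regular"
    return "irregular"
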