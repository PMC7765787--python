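"""Readers and writers for signals, manifests, predictions and configs.

Signals are plain delimited matrices (one row per time step, one column per
channel); a JSON manifest maps record ids to their file, sampling rate and
optional label / knowledge attributes.  Predictions go to TSV.  Everything is
human-inspectable text.
"""

from __future__ import annotations

import json
import logging
import os
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .types import ClassCatalog, MonitoringRecord

logger = logging.getLogger("kmargin")

__all__ = [
    "read_records",
    "write_records",
    "write_predictions",
    "read_predictions",
    "load_config",
    "log_run",
]


class FormatError(ValueError):
    """Malformed input file (ragged rows, bad manifest, ...)."""


def _read_signal(path: Path) -> np.ndarray:
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric value") from exc
    if not rows:
        raise FormatError(f"{path}: empty signal file")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise FormatError(f"{path}: rows of unequal width")
    # file is time x channels; in memory we keep channels x time
    return np.asarray(rows, dtype=np.float64).T


def read_records(
    signal_dir: str | os.PathLike,
    manifest_path: str | os.PathLike,
    catalog: ClassCatalog | None = None,
) -> list[MonitoringRecord]:
    """Load all records named by a JSON manifest, in manifest order.

    The manifest maps ``id -> {"file": ..., "sampling_rate": ..., "label"?: ...,
    "knowledge"?: [...]}``.  Labels may be absent (prediction mode); when a
    catalog is given, present labels are validated against it.
    """
    signal_dir = Path(signal_dir)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    if not isinstance(manifest, dict):
        raise FormatError(f"{manifest_path}: manifest must be a JSON object")
    records = []
    for rec_id, entry in manifest.items():
        label = entry.get("label")
        if label is not None and catalog is not None and label not in catalog.labels:
            raise KeyError(
                f"record {rec_id!r}: label {label!r} not in catalog {catalog.labels}"
            )
        knowledge = entry.get("knowledge")
        records.append(
            MonitoringRecord(
                id=rec_id,
                signal=_read_signal(signal_dir / entry["file"]),
                sampling_rate=float(entry.get("sampling_rate", 1.0)),
                label=label,
                knowledge=None if knowledge is None else np.asarray(knowledge, float),
            )
        )
    return records


def write_records(
    records: Sequence[MonitoringRecord],
    out_dir: str | os.PathLike,
    manifest_name: str = "manifest.json",
) -> Path:
    """Write records as CSV signal files plus a JSON manifest; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict] = {}
    for rec in records:
        fname = f"{rec.id}.csv"
        np.savetxt(out_dir / fname, rec.signal.T, delimiter=",", fmt="%.8g")
        entry: dict = {"file": fname, "sampling_rate": rec.sampling_rate}
        if rec.label is not None:
            entry["label"] = rec.label
        if rec.knowledge is not None:
            entry["knowledge"] = [float(v) for v in np.atleast_1d(rec.knowledge)]
        manifest[rec.id] = entry
    manifest_path = out_dir / manifest_name
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest_path


def write_predictions(
    record_ids: Sequence[str],
    labels: Sequence[str],
    path: str | os.PathLike,
    knowledge_out: np.ndarray | None = None,
    feature_names: Sequence[str] | None = None,
) -> None:
    """Write per-record predictions as TSV: id, predicted_label[, F feature columns]."""
    if len(record_ids) != len(labels):
        raise ValueError("one predicted label per record required")
    data: dict = {"id": list(record_ids), "predicted_label": list(labels)}
    if knowledge_out is not None:
        ko = np.atleast_2d(np.asarray(knowledge_out, dtype=np.float64))
        if ko.shape[0] != len(record_ids):
            raise ValueError("knowledge_out must have one row per record")
        names = (
            list(feature_names)
            if feature_names is not None
            else [f"feature_{j + 1}" for j in range(ko.shape[1])]
        )
        for j, name in enumerate(names):
            data[name] = ko[:, j]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_predictions(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"id": str})


def load_config(path: str | os.PathLike) -> dict:
    """Load a flat keys-per-module YAML config; returns {} for an empty file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def log_run(config: dict, seed: int | None = None) -> None:
    """Log the resolved configuration and seed of a run (one line per key)."""
    if seed is not None:
        logger.info("seed = %d", seed)
    for section, values in config.items():
        logger.info("config %s: %s", section, values)
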