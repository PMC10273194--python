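"""Tabular survival I/O and report serialization.

Datasets travel as delimited text (TSV by default, CSV by extension) with a
``time`` column, a binary ``status`` column and numeric feature columns,
plus an optional JSON sidecar manifest recording the generating
configuration, seed and true-signal indices.  Every written artifact embeds
a schema version and the seed for reproducibility.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .metrics import EvaluationReport
from .selection import SelectionResult
from .simdata import SimulationConfig, SurvivalDataset, config_from_dict, \
    config_to_dict

__all__ = [
    "SCHEMA_VERSION",
    "read_survival_table",
    "write_dataset",
    "read_dataset",
    "write_report",
    "write_selection",
]

SCHEMA_VERSION = "1.0"


def _delimiter(path: Path, delimiter: Optional[str]) -> str:
    if delimiter:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_survival_table(
    path,
    time_col: str = "time",
    event_col: str = "status",
    delimiter: Optional[str] = None,
) -> SurvivalDataset:
    """Parse a delimited survival table into a :class:`SurvivalDataset`.

    All columns other than ``time_col`` and ``event_col`` become features.
    Times must be strictly positive, events coded 0/1 and features numeric;
    violations raise with the offending column (and row, where applicable).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter(path, delimiter),
                     float_precision="round_trip")
    for col in (time_col, event_col):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    time = pd.to_numeric(df[time_col], errors="coerce")
    if time.isna().any() or (time <= 0).any():
        bad = int(np.flatnonzero(time.isna() | (time <= 0))[0])
        raise ValueError(
            f"column {time_col!r}: non-positive or non-numeric time at row {bad}"
        )
    event = pd.to_numeric(df[event_col], errors="coerce")
    if event.isna().any() or ~event.isin([0, 1]).all():
        bad = int(np.flatnonzero(event.isna() | ~event.isin([0, 1]))[0])
        raise ValueError(
            f"column {event_col!r}: event indicator not in {{0,1}} at row {bad}"
        )
    feature_cols = [c for c in df.columns if c not in (time_col, event_col)]
    X = np.empty((len(df), len(feature_cols)))
    for j, col in enumerate(feature_cols):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = int(np.flatnonzero(vals.isna())[0])
            raise ValueError(f"column {col!r}: non-numeric value at row {bad}")
        X[:, j] = vals.to_numpy()

    ds = SurvivalDataset(
        X=X,
        time=time.to_numpy(dtype=float),
        event=event.to_numpy(dtype=int),
        feature_names=feature_cols,
    )
    manifest = _manifest_path(path)
    if manifest.exists():
        meta = json.loads(manifest.read_text())
        if "true_signal_indices" in meta:
            ds.true_signals = np.asarray(meta["true_signal_indices"], dtype=int)
        if meta.get("config"):
            ds.config = config_from_dict(meta["config"])
        if meta.get("risk_group") is not None:
            ds.risk_group = np.asarray(meta["risk_group"], dtype=int)
    ds.validate()
    return ds


def _manifest_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".manifest.json")


def write_dataset(ds: SurvivalDataset, path, delimiter: Optional[str] = None) -> Path:
    """Write a dataset as a delimited table plus a JSON sidecar manifest."""
    path = Path(path)
    sep = _delimiter(path, delimiter)
    df = pd.DataFrame(ds.X, columns=ds.feature_names)
    df.insert(0, "status", ds.event)
    df.insert(0, "time", ds.time)
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "n": ds.n,
        "p": ds.p,
        "feature_names": ds.feature_names,
        "true_signal_indices": [int(i) for i in ds.true_signals],
        "config": config_to_dict(ds.config) if ds.config else None,
        "seed": ds.config.seed if ds.config else None,
        "risk_group": (None if ds.risk_group is None
                       else [int(g) for g in ds.risk_group]),
    }
    _manifest_path(path).write_text(json.dumps(manifest, indent=1))
    return path


def read_dataset(path, delimiter: Optional[str] = None) -> SurvivalDataset:
    """Inverse of :func:`write_dataset` (manifest-aware)."""
    return read_survival_table(path, delimiter=delimiter)


def write_report(report: EvaluationReport, path, seed: Optional[int] = None,
                 config: Optional[dict] = None) -> Path:
    """Evaluation report as JSON, with a flat TSV twin for aggregation."""
    path = Path(path)
    payload = {
        "schema_version": SCHEMA_VERSION,
        "seed": seed,
        "config": config or {},
        "report": report.to_dict(),
    }
    path.write_text(json.dumps(payload, indent=1))
    tsv = path.with_suffix(".tsv")
    pd.DataFrame([report.to_dict()]).to_csv(tsv, sep="\t", index=False)
    return path


def write_selection(result: SelectionResult, path,
                    feature_names: Optional[list[str]] = None,
                    seed: Optional[int] = None,
                    config: Optional[dict] = None) -> Path:
    """Selection result as JSON plus a per-feature TSV (one row per feature)."""
    path = Path(path)
    payload = {
        "schema_version": SCHEMA_VERSION,
        "seed": seed,
        "config": config or {},
        **result.to_dict(feature_names),
    }
    path.write_text(json.dumps(payload, indent=1))
    p = len(result.scores)
    names = feature_names or [f"f{j + 1}" for j in range(p)]
    selected = np.zeros(p, dtype=int)
    selected[result.selected] = 1
    tsv = path.with_suffix(".tsv")
    pd.DataFrame({"feature": names, "score": result.scores,
                  "selected": selected}).to_csv(tsv, sep="\t", index=False)
    return path
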