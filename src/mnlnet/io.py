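"""Reading and writing EEG records, segment tables, and evaluation reports.

Two on-disk layouts are supported:

* Bonn-style raw ASCII records — one sample value per line, one file per
  record, organized in one subdirectory per set (A-E).
* UCI-style segment CSV — one row per fixed-length segment with a trailing
  integer label column ``y`` in 1..5 (1 = seizure set E ... 5 = set A).

Evaluation reports are written as a CSV table (one row per task/metric with
columns k1..k10 and the fold mean) plus a JSON sidecar at full precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SET_IDS", "UCI_LABEL_TO_SET", "SET_TO_UCI_LABEL",
    "EEGRecord", "SegmentTable", "EvalReport", "FormatError",
    "read_bonn_record", "read_bonn_dir", "read_uci_csv",
    "write_report", "read_report",
]

SET_IDS = ("A", "B", "C", "D", "E")

# The UCI "Epileptic Seizure Recognition" distribution codes seizure as 1
# and eyes-open healthy as 5; internally everything is in A-E vocabulary.
UCI_LABEL_TO_SET = {1: "E", 2: "D", 3: "C", 4: "B", 5: "A"}
SET_TO_UCI_LABEL = {v: k for k, v in UCI_LABEL_TO_SET.items()}

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "precision", "f1")


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


@dataclass
class EEGRecord:
    """One raw single-channel EEG signal."""

    samples: np.ndarray
    set_id: str
    record_index: int
    sampling_rate_hz: float = 173.61

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise ValueError("record has no samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("record contains non-finite samples")
        if self.set_id not in SET_IDS:
            raise ValueError(f"unknown set id {self.set_id!r}")
        if self.record_index < 0:
            raise ValueError("record_index must be >= 0")

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class SegmentTable:
    """Fixed-length segments with integer task labels and provenance."""

    segments: np.ndarray                  # (n, segment_length)
    labels: np.ndarray                    # (n,) ints, consecutive from 0
    set_ids: np.ndarray                   # (n,) 'A'..'E'
    record_index: np.ndarray              # (n,)
    chunk_index: np.ndarray               # (n,)

    def __post_init__(self):
        self.segments = np.atleast_2d(np.asarray(self.segments, dtype=float))
        if self.segments.size == 0:
            self.segments = self.segments.reshape(0, 0)
        self.labels = np.asarray(self.labels, dtype=int)
        self.set_ids = np.asarray(self.set_ids, dtype="U1")
        self.record_index = np.asarray(self.record_index, dtype=int)
        self.chunk_index = np.asarray(self.chunk_index, dtype=int)
        n = self.segments.shape[0]
        for name, arr in (("labels", self.labels), ("set_ids", self.set_ids),
                          ("record_index", self.record_index),
                          ("chunk_index", self.chunk_index)):
            if arr.shape[0] != n:
                raise ValueError(f"{name} has length {arr.shape[0]}, expected {n}")

    def __len__(self) -> int:
        return self.segments.shape[0]

    @property
    def segment_length(self) -> int:
        return self.segments.shape[1]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1 if len(self) else 0

    def subset(self, idx) -> "SegmentTable":
        return SegmentTable(self.segments[idx], self.labels[idx],
                            self.set_ids[idx], self.record_index[idx],
                            self.chunk_index[idx])

    @staticmethod
    def concatenate(tables: list["SegmentTable"]) -> "SegmentTable":
        tables = [t for t in tables if len(t)]
        return SegmentTable(
            np.concatenate([t.segments for t in tables]),
            np.concatenate([t.labels for t in tables]),
            np.concatenate([t.set_ids for t in tables]),
            np.concatenate([t.record_index for t in tables]),
            np.concatenate([t.chunk_index for t in tables]),
        )


@dataclass
class EvalReport:
    """Per-fold and mean metrics for one task, in the k1..k10 + Mean layout."""

    scheme: str
    k: int = 10
    fold_metrics: dict = field(default_factory=dict)  # metric -> list of k values

    def add_fold(self, metrics: dict[str, float]) -> None:
        for name, value in metrics.items():
            self.fold_metrics.setdefault(name, []).append(float(value))

    def validate(self) -> None:
        if not self.fold_metrics:
            raise ValueError("report has no metrics")
        for name, vals in self.fold_metrics.items():
            if len(vals) != self.k:
                raise ValueError(
                    f"metric {name!r} has {len(vals)} folds, expected {self.k}")

    def mean(self, metric: str) -> float:
        return float(np.mean(self.fold_metrics[metric]))

    def to_dict(self) -> dict:
        self.validate()
        return {
            "scheme": self.scheme,
            "k": self.k,
            "metrics": {m: {"folds": vals, "mean": self.mean(m)}
                        for m, vals in self.fold_metrics.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EvalReport":
        rep = cls(scheme=d["scheme"], k=d["k"])
        for m, entry in d["metrics"].items():
            rep.fold_metrics[m] = [float(v) for v in entry["folds"]]
        rep.validate()
        return rep


# ---------------------------------------------------------------------------
# Bonn-style ASCII records


def read_bonn_record(path, set_id: str, record_index: int,
                     sampling_rate_hz: float = 173.61) -> EEGRecord:
    """Read one raw ASCII record: one sample per line, blanks skipped."""
    path = Path(path)
    samples = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                continue
            try:
                samples.append(float(text))
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: not a number: {text!r}") from None
    if not samples:
        raise FormatError(f"{path}: empty record file")
    return EEGRecord(np.array(samples), set_id=set_id,
                     record_index=record_index,
                     sampling_rate_hz=sampling_rate_hz)


def read_bonn_dir(root) -> list[EEGRecord]:
    """Read a Bonn-style tree: one subdirectory per set, one file per record."""
    root = Path(root)
    records = []
    for set_id in SET_IDS:
        set_dir = root / set_id
        if not set_dir.is_dir():
            continue
        for i, path in enumerate(sorted(set_dir.iterdir())):
            if path.is_file():
                records.append(read_bonn_record(path, set_id, i))
    if not records:
        raise FormatError(f"{root}: no set subdirectories with record files")
    return records


def write_bonn_record(record: EEGRecord, path) -> None:
    with open(path, "w") as fh:
        for v in record.samples:
            fh.write(f"{float(v)!r}\n")


# ---------------------------------------------------------------------------
# UCI-style segment CSV


def read_uci_csv(path) -> SegmentTable:
    """Read a UCI-layout CSV: header, optional leading id column, numeric
    segment values, trailing integer label column ``y`` in 1..5."""
    path = Path(path)
    df = pd.read_csv(path)
    if "y" not in df.columns:
        if df.columns[-1].lower() != "y":
            raise FormatError(f"{path}: expected final label column 'y'")
    label_col = "y" if "y" in df.columns else df.columns[-1]
    id_col = None
    first = df.columns[0]
    if df[first].dtype == object or str(first).lower() in ("id", "unnamed: 0"):
        id_col = first
    value_cols = [c for c in df.columns if c not in (label_col, id_col)]
    if df.empty:
        return SegmentTable(np.zeros((0, len(value_cols))), [], [], [], [])
    try:
        segments = df[value_cols].to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric segment value: {exc}") from None
    if not np.all(np.isfinite(segments)):
        raise FormatError(f"{path}: rows with missing or non-finite values "
                          "(possible arity mismatch)")
    y = df[label_col].to_numpy()
    if not np.all(np.isin(y, list(UCI_LABEL_TO_SET))):
        bad = sorted(set(y) - set(UCI_LABEL_TO_SET))
        raise FormatError(f"{path}: labels outside 1..5: {bad}")
    set_ids = np.array([UCI_LABEL_TO_SET[int(v)] for v in y])
    labels = np.array([SET_IDS.index(s) for s in set_ids])
    n = len(df)
    if id_col is not None:
        rec_idx, chunk_idx = _parse_provenance(df[id_col].astype(str).tolist())
    else:
        rec_idx, chunk_idx = _synthesize_provenance(set_ids)
    return SegmentTable(segments, labels, set_ids, rec_idx, chunk_idx)


def _parse_provenance(ids: list[str]) -> tuple[np.ndarray, np.ndarray]:
    rec, chunk = [], []
    for s in ids:
        parts = s.split(".")
        if len(parts) == 3 and parts[1].isdigit() and parts[2].isdigit():
            rec.append(int(parts[1]))
            chunk.append(int(parts[2]))
        else:
            rec, chunk = [], []
            break
    if rec:
        return np.array(rec), np.array(chunk)
    return _synthesize_provenance(np.array([""] * len(ids)))


def _synthesize_provenance(set_ids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # Without an id column, number segments within each set consecutively.
    rec = np.zeros(len(set_ids), dtype=int)
    chunk = np.zeros(len(set_ids), dtype=int)
    counters: dict[str, int] = {}
    for i, s in enumerate(set_ids):
        k = counters.get(s, 0)
        rec[i], chunk[i] = divmod(k, 23)
        counters[s] = k + 1
    return rec, chunk


def write_uci_csv(table: SegmentTable, path) -> None:
    """Write a SegmentTable in the UCI CSV dialect (id column + y label)."""
    path = Path(path)
    n, m = table.segments.shape
    cols = {"id": [f"{s}.{r}.{c}" for s, r, c in
                   zip(table.set_ids, table.record_index, table.chunk_index)]}
    for j in range(m):
        cols[f"X{j + 1}"] = table.segments[:, j]
    cols["y"] = [SET_TO_UCI_LABEL[s] for s in table.set_ids]
    pd.DataFrame(cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Reports


def write_report(report: EvalReport, path) -> None:
    """Write CSV (task,metric,k1..k10,mean) plus a full-precision JSON sidecar."""
    report.validate()
    path = Path(path)
    rows = []
    for metric, vals in report.fold_metrics.items():
        row = {"task": report.scheme, "metric": metric}
        row.update({f"k{i + 1}": v for i, v in enumerate(vals)})
        row["mean"] = report.mean(metric)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    path.with_suffix(".json").write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n")


def read_report(path) -> EvalReport:
    """Read a report back from the JSON sidecar (lossless round-trip)."""
    path = Path(path)
    if path.suffix != ".json":
        path = path.with_suffix(".json")
    return EvalReport.from_dict(json.loads(path.read_text()))
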