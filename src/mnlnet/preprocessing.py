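"""Signal normalization, record segmentation, and task assembly.

Each raw record is split into 23 contiguous non-overlapping chunks
(4,097 samples -> 23 x 178, the trailing 3 samples discarded), and each
chunk is z-scored independently before entering the network.  Task
datasets are built from class-combination schemes such as ``"AB-E"``:
hyphen-separated groups of set letters, each group one classifier class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import SET_IDS, EEGRecord, SegmentTable

__all__ = ["NormalizationStats", "TaskScheme", "zscore_normalize",
           "segment_record", "segment_records", "parse_scheme",
           "build_task_dataset", "DOUBLE_SCHEMES", "MULTI_SCHEMES"]

# The published experimental grid of class combinations.
DOUBLE_SCHEMES = ("A-E", "B-E", "C-E", "D-E", "AB-E", "AC-E", "AD-E", "BC-E",
                  "BD-E", "CD-E", "ABC-E", "ABD-E", "BCD-E", "ABCD-E")
MULTI_SCHEMES = ("A-C-E", "A-D-E", "B-C-E", "B-D-E", "AB-CD-E", "A-B-C-D-E")


@dataclass(frozen=True)
class NormalizationStats:
    mu: float
    theta: float  # population standard deviation, >= 0


class SchemeError(ValueError):
    """A class-combination string does not parse."""


@dataclass(frozen=True)
class TaskScheme:
    scheme_string: str
    groups: tuple[frozenset, ...]

    @property
    def n_classes(self) -> int:
        return len(self.groups)

    @property
    def used_sets(self) -> frozenset:
        return frozenset().union(*self.groups)

    def class_of(self, set_id: str) -> int | None:
        for i, g in enumerate(self.groups):
            if set_id in g:
                return i
        return None


def zscore_normalize(s: np.ndarray) -> tuple[np.ndarray, NormalizationStats]:
    """Center and scale: s* = (s - mu)/theta with the population SD.

    A constant signal (theta = 0) maps to the zero vector.
    """
    s = np.asarray(s, dtype=float)
    if s.size == 0:
        raise ValueError("cannot normalize an empty signal")
    if not np.all(np.isfinite(s)):
        raise ValueError("signal contains non-finite values")
    mu = float(s.mean())
    theta = float(s.std())  # population estimator (divide by n)
    if theta > 0:
        s_star = (s - mu) / theta
    else:
        s_star = np.zeros_like(s)
    return s_star, NormalizationStats(mu=mu, theta=theta)


def segment_record(record: EEGRecord, n_chunks: int = 23) -> SegmentTable:
    """Split a record into n_chunks contiguous equal-length segments.

    chunk_length = floor(len(record)/n_chunks); trailing remainder samples
    are discarded.
    """
    n = len(record)
    if n < n_chunks:
        raise ValueError(f"record length {n} shorter than n_chunks {n_chunks}")
    chunk_len = n // n_chunks
    used = chunk_len * n_chunks
    segments = record.samples[:used].reshape(n_chunks, chunk_len)
    label = SET_IDS.index(record.set_id)
    return SegmentTable(
        segments=segments,
        labels=np.full(n_chunks, label),
        set_ids=np.full(n_chunks, record.set_id),
        record_index=np.full(n_chunks, record.record_index),
        chunk_index=np.arange(n_chunks),
    )


def segment_records(records: list[EEGRecord], n_chunks: int = 23) -> SegmentTable:
    return SegmentTable.concatenate([segment_record(r, n_chunks) for r in records])


def parse_scheme(scheme_string: str) -> TaskScheme:
    """Parse a class-combination string like "AB-E" or "A-B-C-D-E"."""
    parts = scheme_string.strip().upper().split("-")
    if len(parts) < 2:
        raise SchemeError(f"{scheme_string!r}: need at least 2 groups")
    groups = []
    seen = set()
    for part in parts:
        if not part:
            raise SchemeError(f"{scheme_string!r}: empty group")
        for letter in part:
            if letter not in SET_IDS:
                raise SchemeError(f"{scheme_string!r}: unknown set {letter!r}")
            if letter in seen:
                raise SchemeError(
                    f"{scheme_string!r}: set {letter!r} appears more than once")
            seen.add(letter)
        groups.append(frozenset(part))
    return TaskScheme(scheme_string="-".join(parts), groups=tuple(groups))


def build_task_dataset(segments: SegmentTable, scheme: TaskScheme | str,
                       normalize: bool = True) -> SegmentTable:
    """Select and relabel segments for a task scheme.

    Segments whose set is not referenced are dropped; retained segments get
    the index of their group as label and are (by default) z-scored
    independently.
    """
    if isinstance(scheme, str):
        scheme = parse_scheme(scheme)
    present = set(segments.set_ids)
    for g in scheme.groups:
        if not (g & present):
            raise ValueError(f"scheme group {sorted(g)} matches no segments")
    new_labels = np.array([scheme.class_of(s) if scheme.class_of(s) is not None
                           else -1 for s in segments.set_ids])
    keep = new_labels >= 0
    out = segments.subset(keep)
    out.labels = new_labels[keep]
    if normalize:
        data = np.empty_like(out.segments)
        for i in range(len(out)):
            data[i], _ = zscore_normalize(out.segments[i])
        out.segments = data
    return out
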