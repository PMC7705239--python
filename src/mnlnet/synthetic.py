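"""Synthetic surrogate EEG with class-dependent spectral structure.

Generates five sets (A-E) of single-channel records emulating the layout of
the Bonn corpus: by default 100 records per set, 4,097 samples each at
173.61 Hz.  Every record is 1/f-shaped Gaussian background noise plus a
set-dependent component whose amplitude scales linearly with the
``separability`` knob:

* sets A, B — a sustained ~10 Hz alpha-band rhythm (eyes closed/open
  surrogates differ in rhythm frequency and amplitude),
* sets C, D — sparse random interictal-like transient spikes,
* set E  — a high-amplitude ~3 Hz spike-and-wave train (ictal surrogate).

At ``separability = 0`` every set-dependent amplitude vanishes, so all five
sets are drawn from the identical background distribution; large values
make the seizure class trivially separable.  One global seed spawns an
independent stream per (set, record), so any subset is reproducible
regardless of generation order.  This is a test surrogate, not a
physiological EEG simulator.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import SET_IDS, EEGRecord, write_bonn_record, write_uci_csv
from .preprocessing import segment_records

__all__ = ["SyntheticSpec", "generate_bonn_like", "write_synthetic"]


@dataclass(frozen=True)
class SyntheticSpec:
    n_records_per_set: int = 100
    record_length: int = 4097
    sampling_rate_hz: float = 173.61
    seed: int = 0
    separability: float = 1.0
    noise_sd: float = 1.0
    clip: float = 50.0

    def __post_init__(self):
        if self.n_records_per_set < 1 or self.record_length < 1:
            raise ValueError("counts must be positive")
        if self.separability < 0:
            raise ValueError("separability must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


# Per-set component amplitudes, in units of noise_sd, at separability = 1.
_ALPHA_AMP = {"A": 0.9, "B": 0.7}
_ALPHA_FREQ = {"A": 10.0, "B": 9.0}
_SPIKE_AMP = {"C": 2.0, "D": 2.5}
_SPIKE_RATE_HZ = {"C": 0.6, "D": 1.0}   # expected transients per second
_SW_AMP = 3.0                           # set E spike-wave amplitude
_SW_FREQ = 3.0


def _pink_noise(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    """Gaussian noise with ~1/f power spectrum (spectral exponent 1)."""
    freqs = np.fft.rfftfreq(n, d=1.0)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = 1.0 / np.sqrt(freqs[nz])
    shape[0] = 0.0
    spec = shape * (rng.standard_normal(len(freqs))
                    + 1j * rng.standard_normal(len(freqs)))
    x = np.fft.irfft(spec, n=n)
    x *= sd / x.std()
    return x


def _record_signal(rng: np.random.Generator, set_id: str,
                   spec: SyntheticSpec) -> np.ndarray:
    n = spec.record_length
    fs = spec.sampling_rate_hz
    t = np.arange(n) / fs
    x = _pink_noise(rng, n, spec.noise_sd)
    s = spec.separability * spec.noise_sd
    if set_id in _ALPHA_AMP:
        phase = rng.uniform(0, 2 * np.pi)
        freq = _ALPHA_FREQ[set_id] * (1 + 0.02 * rng.standard_normal())
        x += _ALPHA_AMP[set_id] * s * np.sin(2 * np.pi * freq * t + phase)
    elif set_id in _SPIKE_AMP:
        n_spikes = rng.poisson(_SPIKE_RATE_HZ[set_id] * n / fs)
        width = 0.03  # seconds
        for _ in range(n_spikes):
            t0 = rng.uniform(0, t[-1])
            sign = rng.choice([-1.0, 1.0])
            x += sign * _SPIKE_AMP[set_id] * s * np.exp(-0.5 * ((t - t0) / width) ** 2)
    elif set_id == "E":
        phase = rng.uniform(0, 2 * np.pi)
        # spike-and-wave: slow wave plus a sharp transient once per cycle
        cycle = np.mod(2 * np.pi * _SW_FREQ * t + phase, 2 * np.pi)
        wave = np.sin(cycle)
        spikes = np.exp(-0.5 * ((cycle - np.pi) / 0.25) ** 2)
        x += _SW_AMP * s * (wave + 2.0 * spikes)
    return np.clip(x, -spec.clip, spec.clip)


def generate_bonn_like(spec: SyntheticSpec) -> list[EEGRecord]:
    """Five sets of surrogate records; deterministic given ``spec.seed``."""
    records = []
    for si, set_id in enumerate(SET_IDS):
        for ri in range(spec.n_records_per_set):
            rng = np.random.default_rng(
                np.random.SeedSequence(spec.seed, spawn_key=(si, ri)))
            records.append(EEGRecord(
                _record_signal(rng, set_id, spec),
                set_id=set_id, record_index=ri,
                sampling_rate_hz=spec.sampling_rate_hz))
    return records


def write_synthetic(records: list[EEGRecord], out_dir,
                    layout: str = "bonn_ascii") -> Path:
    """Write records in a supported on-disk layout; returns the path written.

    ``bonn_ascii``: one subdirectory per set, one ASCII file per record.
    ``uci_csv``: segments all records (23 chunks each) into a single CSV.
    """
    if not records:
        raise ValueError("no records to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if layout == "bonn_ascii":
        for rec in records:
            set_dir = out_dir / rec.set_id
            set_dir.mkdir(exist_ok=True)
            write_bonn_record(rec, set_dir / f"{rec.set_id}{rec.record_index:03d}.txt")
        return out_dir
    if layout == "uci_csv":
        table = segment_records(records)
        path = out_dir / "segments.csv"
        write_uci_csv(table, path)
        return path
    raise ValueError(f"unknown layout {layout!r}")
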