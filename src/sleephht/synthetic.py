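"""Synthetic labelled EEG epochs with stage-dependent spectral content.

Generates 30-s, 100 Hz epochs whose band structure follows textbook EEG:
posterior alpha dominates relaxed wakefulness, slow delta dominates deep
sleep, stage 2 carries spindle-band activity, and REM is mixed-frequency.
Each band component is a sinusoid with random phase, random frequency
within the band, and slow random amplitude modulation (so the signal is
non-stationary and decomposes into several IMFs), plus Gaussian noise.

Also writes minimal EDF+ fixture files (16-bit signal + annotation stream
in the Sleep-EDFx "Sleep stage X" dialect) to exercise the ingestion
module without external recordings.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StageSpec",
    "SyntheticDatasetSpec",
    "EpochRecord",
    "DEFAULT_STAGE_SPECS",
    "generate_epoch",
    "generate_dataset",
    "write_edf_fixture",
]


@dataclass
class EpochRecord:
    """One labelled 30-s EEG segment (3000 samples at 100 Hz)."""

    samples: np.ndarray
    label: str
    fs: float = 100.0
    subject_id: str = "synthetic"
    epoch_index: int = 0


@dataclass(frozen=True)
class StageSpec:
    """Spectral recipe for one sleep stage.

    ``band_components`` are (center frequency Hz, bandwidth Hz, amplitude uV)
    triples; ``noise_sigma`` is the Gaussian noise level in uV.
    """

    stage_label: str
    band_components: tuple[tuple[float, float, float], ...]
    noise_sigma: float = 6.0
    baseline_amplitude: float = 0.0

    def validate(self, fs: float) -> None:
        if self.stage_label not in {"W", "1", "2", "3", "4", "R"}:
            raise ValueError(f"unknown stage label {self.stage_label!r}")
        if not self.band_components:
            raise ValueError("at least one band component is required")
        for f0, bw, amp in self.band_components:
            if not 0 < f0 < fs / 2:
                raise ValueError(f"center frequency {f0} outside (0, fs/2)")
            if bw < 0 or amp < 0:
                raise ValueError("bandwidth and amplitude must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


# Band amplitudes in uV, loosely scaled to adult scalp EEG at Pz-Oz.
# Alpha dominates wake; delta grows through stages 3-4; stage 2 carries a
# spindle component; REM is low-amplitude mixed frequency.
DEFAULT_STAGE_SPECS: dict[str, StageSpec] = {
    "W": StageSpec("W", ((10.0, 2.0, 30.0), (20.0, 4.0, 8.0), (1.5, 1.0, 6.0))),
    "1": StageSpec("1", ((5.0, 2.0, 20.0), (9.0, 1.5, 10.0), (1.5, 1.0, 8.0))),
    "2": StageSpec("2", ((13.0, 1.5, 18.0), (5.0, 2.0, 15.0), (1.5, 1.0, 12.0))),
    "3": StageSpec("3", ((1.5, 1.0, 35.0), (5.0, 2.0, 10.0))),
    "4": StageSpec("4", ((0.8, 0.6, 45.0), (4.0, 1.5, 6.0)), noise_sigma=5.0),
    "R": StageSpec("R", ((6.0, 2.5, 15.0), (18.0, 4.0, 8.0), (2.5, 1.0, 7.0)),
                   noise_sigma=7.0),
}


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """A balanced multi-stage dataset recipe."""

    n_per_class: int
    stages: tuple[str, ...] = ("W", "1", "2", "3", "4", "R")
    fs: float = 100.0
    epoch_seconds: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class <= 0:
            raise ValueError("n_per_class must be > 0")
        n = self.fs * self.epoch_seconds
        if abs(n - round(n)) > 1e-9:
            raise ValueError("fs * epoch_seconds must be an integer")


def generate_epoch(
    spec: StageSpec, fs: float = 100.0, epoch_seconds: float = 30.0, seed: int = 0
) -> EpochRecord:
    """One synthetic epoch: sum of amplitude-modulated band sinusoids with
    random phase plus Gaussian noise. Deterministic for a given seed."""
    if fs <= 0 or epoch_seconds <= 0:
        raise ValueError("fs and epoch_seconds must be > 0")
    n = fs * epoch_seconds
    if abs(n - round(n)) > 1e-9:
        raise ValueError("fs * epoch_seconds must be an integer")
    spec.validate(fs)
    n = int(round(n))
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    x = np.full(n, spec.baseline_amplitude, dtype=float)
    for f0, bw, amp in spec.band_components:
        f = rng.uniform(f0 - bw / 2, f0 + bw / 2)
        f = min(max(f, 0.1), fs / 2 - 0.1)
        phase = rng.uniform(0, 2 * np.pi)
        # slow AM (0.05-0.3 Hz) keeps the component band-limited but
        # non-stationary, which EMD needs to separate modes.
        f_am = rng.uniform(0.05, 0.3)
        depth = rng.uniform(0.2, 0.5)
        am = 1.0 + depth * np.sin(2 * np.pi * f_am * t + rng.uniform(0, 2 * np.pi))
        x += amp * am * np.sin(2 * np.pi * f * t + phase)
    x += rng.normal(0.0, spec.noise_sigma, n)
    return EpochRecord(samples=x, label=spec.stage_label, fs=fs)


def generate_dataset(
    spec: SyntheticDatasetSpec,
    stage_specs: dict[str, StageSpec] | None = None,
) -> list[EpochRecord]:
    """``n_per_class`` epochs per stage; per-epoch seeds are spawned
    deterministically from the master seed."""
    specs = stage_specs or DEFAULT_STAGE_SPECS
    for s in spec.stages:
        if s not in specs:
            raise ValueError(f"no StageSpec for stage {s!r}")
    # one independent child seed per epoch, stable across runs
    n_total = spec.n_per_class * len(spec.stages)
    child_seeds = np.random.SeedSequence(spec.seed).generate_state(n_total)
    epochs: list[EpochRecord] = []
    k = 0
    for stage in spec.stages:
        for i in range(spec.n_per_class):
            ep = generate_epoch(
                specs[stage], spec.fs, spec.epoch_seconds, seed=int(child_seeds[k])
            )
            ep.epoch_index = len(epochs)
            epochs.append(ep)
            k += 1
    return epochs


# ---------------------------------------------------------------------------
# Minimal EDF+ fixture writer (16-bit). Field layout per the EDF standard:
# 256-byte fixed header, 256 bytes per signal, then 2-byte little-endian
# integer samples per data record. The annotation file is an EDF+ file whose
# single "EDF Annotations" signal carries the TAL-coded hypnogram.
# ---------------------------------------------------------------------------


def _field(s: str, n: int) -> bytes:
    b = s.encode("ascii")
    if len(b) > n:
        raise ValueError(f"EDF header field too long: {s!r}")
    return b + b" " * (n - len(b))


def _fixed_header(reserved: str, n_records: int, record_seconds: float) -> bytes:
    return b"".join(
        [
            _field("0", 8),
            _field("X X X X", 80),
            _field("Startdate 01-JAN-2000 X X X", 80),
            _field("01.01.00", 8),
            _field("00.00.00", 8),
            _field(str(256 * 2), 8),
            _field(reserved, 44),
            _field(str(n_records), 8),
            _field(f"{record_seconds:g}", 8),
            _field("1", 4),
        ]
    )


def _signal_header(
    label: str, dim: str, pmin: float, pmax: float, dmin: int, dmax: int, spr: int
) -> bytes:
    return b"".join(
        [
            _field(label, 16),
            _field("", 80),
            _field(dim, 8),
            _field(f"{pmin:g}", 8),
            _field(f"{pmax:g}", 8),
            _field(str(dmin), 8),
            _field(str(dmax), 8),
            _field("", 80),
            _field(str(spr), 8),
            _field("", 32),
        ]
    )


def write_edf_fixture(
    epochs: list[EpochRecord],
    psg_path: str | os.PathLike,
    hypnogram_path: str | os.PathLike | None = None,
    channel_name: str = "EEG Pz-Oz",
) -> tuple[str, str]:
    """Write epochs as an EDF signal file plus an EDF+ annotation file with
    one "Sleep stage X" annotation per 30-s epoch. Returns both paths."""
    if not epochs:
        raise ValueError("no epochs to write")
    fs = epochs[0].fs
    if any(ep.fs != fs for ep in epochs):
        raise ValueError("all epochs must share the sampling rate")
    psg_path = os.fspath(psg_path)
    if hypnogram_path is None:
        root, _ = os.path.splitext(psg_path)
        hypnogram_path = root + "-Hypnogram.edf"
    hypnogram_path = os.fspath(hypnogram_path)

    samples = np.concatenate([ep.samples for ep in epochs])
    epoch_seconds = len(epochs[0].samples) / fs
    spr = len(epochs[0].samples)
    pmax = max(float(np.max(np.abs(samples))) * 1.05, 1.0)
    pmin = -pmax
    dmin, dmax = -32768, 32767
    dig = np.round(
        (np.clip(samples, pmin, pmax) - pmin) / (pmax - pmin) * (dmax - dmin) + dmin
    ).astype("<i2")

    with open(psg_path, "wb") as f:
        f.write(_fixed_header("", len(epochs), epoch_seconds))
        f.write(_signal_header(channel_name, "uV", pmin, pmax, dmin, dmax, spr))
        f.write(dig.tobytes())

    tals = b"+0\x14\x14\x00"
    for i, ep in enumerate(epochs):
        onset = i * epoch_seconds
        text = f"Sleep stage {ep.label}"
        tals += f"+{onset:g}\x15{epoch_seconds:g}\x14{text}\x14\x00".encode("ascii")
    if len(tals) % 2:
        tals += b"\x00"
    with open(hypnogram_path, "wb") as f:
        f.write(_fixed_header("EDF+C", 1, 0))
        f.write(_signal_header("EDF Annotations", "", 0, 1, dmin, dmax, len(tals) // 2))
        f.write(tals)
    return psg_path, hypnogram_path
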