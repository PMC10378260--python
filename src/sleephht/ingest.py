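"""EDF ingestion: channel extraction, hypnogram parsing, epoching,
label merging and class balancing.

Recordings are scored in 30-s epochs. For the binary task the five sleep
stages (1-4 and REM) merge into a single "sleep" class against "wake";
movement-time (M) and unscored (?) epochs are discarded, and the majority
class is randomly under-sampled so both classes have equal counts.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np

from .synthetic import EpochRecord

__all__ = [
    "SampledSignal",
    "StageAnnotation",
    "ChannelNotFoundError",
    "STAGE_LABELS",
    "read_psg_channel",
    "read_hypnogram",
    "segment_epochs",
    "map_labels_binary",
    "balance_classes",
    "cap_class",
]

logger = logging.getLogger(__name__)

STAGE_LABELS = ("W", "1", "2", "3", "4", "R", "M", "?")

#: Sleep-EDFx annotation texts -> single-character stage codes.
_ANNOTATION_MAP = {
    "Sleep stage W": "W",
    "Sleep stage 1": "1",
    "Sleep stage 2": "2",
    "Sleep stage 3": "3",
    "Sleep stage 4": "4",
    "Sleep stage R": "R",
    "Movement time": "M",
    "Sleep stage ?": "?",
}


class ChannelNotFoundError(KeyError):
    pass


@dataclass
class SampledSignal:
    samples: np.ndarray
    fs: float
    channel_name: str
    start_time: float = 0.0


@dataclass(frozen=True)
class StageAnnotation:
    onset: float
    duration: float
    stage: str


def read_psg_channel(edf_path: str | os.PathLike, channel_name: str) -> SampledSignal:
    """Full-night signal of one channel from an EDF/EDF+ file, in uV."""
    import mne

    raw = mne.io.read_raw_edf(os.fspath(edf_path), preload=False, verbose="error")
    if channel_name not in raw.ch_names:
        raise ChannelNotFoundError(
            f"channel {channel_name!r} not in {raw.ch_names}"
        )
    data = raw.get_data(picks=[channel_name], units="uV")[0]
    return SampledSignal(
        samples=np.asarray(data, dtype=float),
        fs=float(raw.info["sfreq"]),
        channel_name=channel_name,
    )


def read_hypnogram(annotation_path: str | os.PathLike) -> list[StageAnnotation]:
    """Stage annotations ordered by onset; unknown texts map to '?'."""
    import mne

    ann = mne.read_annotations(os.fspath(annotation_path))
    out = [
        StageAnnotation(
            onset=float(a["onset"]),
            duration=float(a["duration"]),
            stage=_ANNOTATION_MAP.get(a["description"].strip(), "?"),
        )
        for a in ann
    ]
    return sorted(out, key=lambda a: a.onset)


def segment_epochs(
    signal: SampledSignal,
    annotations: list[StageAnnotation],
    epoch_seconds: float = 30.0,
    subject_id: str = "",
) -> list[EpochRecord]:
    """Expand each annotation into consecutive non-overlapping 30-s epochs
    carrying its stage. Windows are half-open [onset, onset + 30); trailing
    partial windows are dropped; annotations running past the signal end
    are truncated with a warning."""
    n_win = signal.fs * epoch_seconds
    if abs(n_win - round(n_win)) > 1e-9:
        raise ValueError("fs * epoch_seconds must be an integer")
    n_win = int(round(n_win))
    epochs: list[EpochRecord] = []
    for ann in annotations:
        if ann.onset < 0 or ann.duration <= 0:
            raise ValueError("annotations need onset >= 0 and duration > 0")
        start = int(round(ann.onset * signal.fs))
        n_epochs = int(ann.duration // epoch_seconds)
        avail = (signal.samples.size - start) // n_win
        if avail < n_epochs:
            logger.warning(
                "annotation at %gs (%gs, stage %s) extends past the signal end; "
                "truncated from %d to %d epochs",
                ann.onset, ann.duration, ann.stage, n_epochs, max(avail, 0),
            )
            n_epochs = max(avail, 0)
        for k in range(n_epochs):
            lo = start + k * n_win
            epochs.append(
                EpochRecord(
                    samples=signal.samples[lo : lo + n_win].copy(),
                    label=ann.stage,
                    fs=signal.fs,
                    subject_id=subject_id,
                    epoch_index=len(epochs),
                )
            )
    return epochs


def map_labels_binary(epochs: list[EpochRecord]) -> list[EpochRecord]:
    """Stages 1-4 and R -> 'sleep', W -> 'wake'; M and ? epochs dropped."""
    out: list[EpochRecord] = []
    n_dropped = 0
    for ep in epochs:
        if ep.label == "W" or ep.label == "wake":
            label = "wake"
        elif ep.label in {"1", "2", "3", "4", "R"} or ep.label == "sleep":
            label = "sleep"
        elif ep.label in {"M", "?"}:
            n_dropped += 1
            continue
        else:
            raise ValueError(f"unknown stage label {ep.label!r}")
        out.append(
            EpochRecord(ep.samples, label, ep.fs, ep.subject_id, ep.epoch_index)
        )
    if n_dropped:
        logger.info("dropped %d movement-time/unscored epochs", n_dropped)
    return out


def balance_classes(epochs: list[EpochRecord], seed: int = 0) -> list[EpochRecord]:
    """Randomly under-sample the majority class so both binary classes have
    min(count_sleep, count_wake) members; retained order is preserved."""
    labels = np.array([ep.label for ep in epochs])
    classes = set(labels)
    if classes != {"sleep", "wake"}:
        raise ValueError(
            f"need both binary classes present, got {sorted(classes)}"
        )
    n_sleep = int(np.sum(labels == "sleep"))
    n_wake = int(np.sum(labels == "wake"))
    target = min(n_sleep, n_wake)
    majority = "sleep" if n_sleep > n_wake else "wake"
    if n_sleep == n_wake:
        return list(epochs)
    maj_idx = np.flatnonzero(labels == majority)
    rng = np.random.default_rng(seed)
    keep_maj = set(rng.choice(maj_idx, size=target, replace=False).tolist())
    return [
        ep
        for i, ep in enumerate(epochs)
        if labels[i] != majority or i in keep_maj
    ]


def cap_class(
    epochs: list[EpochRecord], stage: str, max_count: int, seed: int = 0
) -> list[EpochRecord]:
    """Down-sample one class uniformly at random to at most ``max_count``
    members, leaving the others untouched."""
    if max_count <= 0:
        raise ValueError("max_count must be > 0")
    idx = np.flatnonzero(np.array([ep.label == stage for ep in epochs]))
    if idx.size <= max_count:
        return list(epochs)
    rng = np.random.default_rng(seed)
    keep = set(rng.choice(idx, size=max_count, replace=False).tolist())
    return [ep for i, ep in enumerate(epochs) if ep.label != stage or i in keep]
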