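"""Statistical features of IMF sequences for the dense (tabular) branch.

Sixteen waveform statistics are computed per IMF: extremes, moments
(population-normalized standard deviation, kurtosis, skewness; sample
variance), energy-like quantities (RMS, energy, power) and the
peak-normalized "spikiness" factors (crest, shape, impulse, clearance,
peak-to-RMS), plus the range. The peak is max|y_i| throughout so that the
peak-based factors are consistent under sign flips.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.preprocessing import StandardScaler

from .emd import IMFDecomposition

__all__ = [
    "FEATURE_NAMES",
    "FeatureVector",
    "compute_statistics",
    "featurize_epoch",
    "standardize_features",
]

FEATURE_NAMES: tuple[str, ...] = (
    "minimum",
    "maximum",
    "mean",
    "standard_deviation",
    "kurtosis",
    "skewness",
    "rms",
    "crest_factor",
    "shape_factor",
    "impulse_factor",
    "clearance_factor",
    "variance",
    "energy",
    "power",
    "peak_to_rms",
    "range",
)


@dataclass
class FeatureVector:
    """Concatenated per-IMF statistics for one epoch.

    ``values`` has length ``16 * n_imfs_used`` ordered IMF-major; blocks
    for IMFs beyond the decomposition's count are zero with
    ``padded = True``; ``degenerate`` flags any IMF whose ratio or moment
    features were undefined and reported as 0.
    """

    values: np.ndarray
    feature_names: list[str]
    n_imfs_used: int
    padded: bool = False
    degenerate: bool = False


def compute_statistics(y: np.ndarray) -> tuple[dict[str, float], bool]:
    """The 16 named statistics of a sequence; returns (values, degenerate).

    Degenerate inputs never produce non-finite values: a constant sequence
    (sigma = 0) reports kurtosis and skewness as 0, and an all-zero
    sequence reports every ratio feature as 0; both set the flag.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    mu = float(np.mean(y))
    dev = y - mu
    sigma = float(np.sqrt(np.mean(dev**2)))  # population
    rms = float(np.sqrt(np.mean(y**2)))
    peak = float(np.max(np.abs(y)))
    mean_abs = float(np.mean(np.abs(y)))
    mean_sqrt_abs = float(np.mean(np.sqrt(np.abs(y))))

    degenerate = False
    if sigma > 0:
        kurtosis = float(np.mean(dev**4) / sigma**4)
        skewness = float(np.mean(dev**3) / sigma**3)
    else:
        kurtosis = skewness = 0.0
        degenerate = True
    if rms > 0:
        crest = peak / rms
        peak_to_rms = peak / rms
        shape = rms / mean_abs
        impulse = peak / mean_abs
        clearance = peak / mean_sqrt_abs**2
    else:
        crest = peak_to_rms = shape = impulse = clearance = 0.0
        degenerate = True

    values = {
        "minimum": float(np.min(y)),
        "maximum": float(np.max(y)),
        "mean": mu,
        "standard_deviation": sigma,
        "kurtosis": kurtosis,
        "skewness": skewness,
        "rms": rms,
        "crest_factor": crest,
        "shape_factor": shape,
        "impulse_factor": impulse,
        "clearance_factor": clearance,
        "variance": float(np.sum(dev**2) / (n - 1)),
        "energy": float(np.sum(y**2)),
        "power": float(np.mean(y**2)),
        "peak_to_rms": peak_to_rms,
        "range": float(np.max(y) - np.min(y)),
    }
    return values, degenerate


def featurize_epoch(
    decomposition: IMFDecomposition, n_imfs_used: int = 4
) -> FeatureVector:
    """Statistics of the first ``n_imfs_used`` IMFs, concatenated in IMF
    order. Missing IMFs yield zero-padded blocks with ``padded`` set."""
    if n_imfs_used < 1:
        raise ValueError("n_imfs_used must be >= 1")
    if decomposition.original.size == 0:
        raise ValueError("empty decomposition")
    blocks: list[np.ndarray] = []
    names: list[str] = []
    padded = False
    degenerate = False
    for k in range(n_imfs_used):
        names.extend(f"imf{k + 1}_{f}" for f in FEATURE_NAMES)
        if k < decomposition.n_imfs:
            vals, degen = compute_statistics(decomposition.imfs[k])
            degenerate |= degen
            blocks.append(np.array([vals[f] for f in FEATURE_NAMES]))
        else:
            padded = True
            blocks.append(np.zeros(len(FEATURE_NAMES)))
    return FeatureVector(
        values=np.concatenate(blocks),
        feature_names=names,
        n_imfs_used=n_imfs_used,
        padded=padded,
        degenerate=degenerate,
    )


def standardize_features(
    train: np.ndarray, *others: np.ndarray
) -> tuple[list[np.ndarray], StandardScaler]:
    """Zero-mean unit-variance scaling fit on the training matrix only and
    applied to every split (constant columns map to 0). Returns the scaled
    matrices in input order plus the fitted scaler."""
    train = np.asarray(train, dtype=float)
    if train.size == 0:
        raise ValueError("empty training matrix")
    scaler = StandardScaler().fit(train)
    out = [scaler.transform(train)]
    out.extend(scaler.transform(np.asarray(m, dtype=float)) for m in others)
    return out, scaler
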