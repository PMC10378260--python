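"""Hilbert spectrum images from an EMD decomposition.

Each IMF is converted to instantaneous amplitude and frequency via the
analytic signal; amplitude is then accumulated on a time x frequency grid
along the instantaneous-frequency trajectory of every IMF. The grid,
normalized to [0, 1], is the image input of the convolutional branch of
the classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert
from skimage.transform import resize as _sk_resize

from .emd import IMFDecomposition

__all__ = [
    "SpectrumGrid",
    "SpectrumImage",
    "analytic_signal",
    "instantaneous_frequency",
    "hilbert_spectrum",
    "render_image",
]

#: Floor (relative to the per-image maximum) applied before log scaling.
LOG_FLOOR = 1e-6


@dataclass(frozen=True)
class SpectrumGrid:
    """Time x frequency binning of the Hilbert spectrum.

    Defaults: 64 x 64 bins, 0-50 Hz (the full band at fs = 100 Hz),
    log amplitude scaling.
    """

    n_time_bins: int = 64
    n_freq_bins: int = 64
    freq_min: float = 0.0
    freq_max: float = 50.0
    amplitude_scale: str = "log"

    def __post_init__(self) -> None:
        if self.n_time_bins < 8 or self.n_freq_bins < 8:
            raise ValueError("grid must have at least 8 bins per axis")
        if not self.freq_max > self.freq_min >= 0:
            raise ValueError("need freq_max > freq_min >= 0")
        if self.amplitude_scale not in ("linear", "log"):
            raise ValueError("amplitude_scale must be 'linear' or 'log'")


@dataclass
class SpectrumImage:
    """Normalized Hilbert spectrum raster (frequency rows x time columns)."""

    pixels: np.ndarray
    grid: SpectrumGrid
    epoch_id: str = ""


def analytic_signal(imf: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous amplitude and unwrapped phase of an IMF.

    The analytic extension is computed with the FFT-based Hilbert
    transform; amplitude is its modulus, phase its unwrapped argument.
    """
    x = np.asarray(imf, dtype=float)
    if x.size == 0:
        raise ValueError("empty IMF")
    z = hilbert(x)
    return np.abs(z), np.unwrap(np.angle(z))


def instantaneous_frequency(phase: np.ndarray, fs: float) -> np.ndarray:
    """f(t) = (1/2pi) dphi/dt in Hz, central differences, clipped at 0."""
    phi = np.asarray(phase, dtype=float)
    if fs <= 0:
        raise ValueError("fs must be > 0")
    freq = np.gradient(phi) * fs / (2.0 * np.pi)
    return np.clip(freq, 0.0, None)


def _normalize(acc: np.ndarray, scale: str) -> np.ndarray:
    peak = acc.max()
    if peak <= 0:
        return np.zeros_like(acc)
    if scale == "linear":
        return acc / peak
    floored = np.clip(acc, LOG_FLOOR * peak, None)
    logged = np.log10(floored) - np.log10(LOG_FLOOR * peak)
    return logged / -np.log10(LOG_FLOOR)


def hilbert_spectrum(
    decomposition: IMFDecomposition,
    grid: SpectrumGrid | None = None,
    fs: float = 100.0,
    epoch_id: str = "",
) -> SpectrumImage:
    """Accumulate per-IMF instantaneous amplitude into the time x frequency
    grid. Samples whose instantaneous frequency falls outside
    [freq_min, freq_max) are dropped; the result is normalized to [0, 1]
    per the grid's amplitude scale."""
    g = grid or SpectrumGrid()
    acc = np.zeros((g.n_freq_bins, g.n_time_bins), dtype=float)
    if decomposition.n_imfs == 0:
        warnings.warn("decomposition has no IMFs; returning an all-zero image")
        return SpectrumImage(pixels=acc, grid=g, epoch_id=epoch_id)

    n = decomposition.original.size
    t_bins = np.minimum(
        (np.arange(n) * g.n_time_bins) // n, g.n_time_bins - 1
    ).astype(int)
    f_span = g.freq_max - g.freq_min
    for imf in decomposition.imfs:
        amp, phase = analytic_signal(imf)
        freq = instantaneous_frequency(phase, fs)
        f_bins = np.floor((freq - g.freq_min) / f_span * g.n_freq_bins).astype(int)
        ok = (f_bins >= 0) & (f_bins < g.n_freq_bins)
        np.add.at(acc, (f_bins[ok], t_bins[ok]), amp[ok])
    return SpectrumImage(pixels=_normalize(acc, g.amplitude_scale), grid=g, epoch_id=epoch_id)


def render_image(
    spectrum: SpectrumImage, out_size: tuple[int, int] | None = None, channels: int = 1
) -> np.ndarray:
    """Resample a spectrum to ``out_size`` (H, W) with values in [0, 1].

    channels=1 keeps the normalized amplitude (H x W); channels=3 applies
    the viridis colormap (H x W x 3). Rendering at the native size with
    channels=1 is the identity.
    """
    if channels not in (1, 3):
        raise ValueError("channels must be 1 or 3")
    px = spectrum.pixels
    if out_size is not None:
        h, w = out_size
        if h < 1 or w < 1:
            raise ValueError("invalid output size")
        if (h, w) != px.shape:
            px = _sk_resize(px, (h, w), order=1, anti_aliasing=False)
            peak = px.max()
            if peak > 0:
                px = np.clip(px / peak, 0.0, 1.0)
    if channels == 3:
        from matplotlib import cm

        px = cm.viridis(px)[..., :3]
    return px
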