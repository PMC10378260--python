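"""Empirical mode decomposition by envelope-mean sifting.

A signal ``x(t)`` is decomposed into intrinsic mode functions (IMFs)
``h_i(t)`` and a residue ``r_n(t)`` so that ``x = sum_i h_i + r_n``.
Each sifting pass interpolates the local maxima and minima with cubic
splines, subtracts the mean envelope, and repeats until the candidate
satisfies the two IMF conditions:

(a) the number of extrema and the number of zero-crossings are equal or
    differ by at most one, and
(b) the envelope mean is locally zero (tested as envelope-mean RMS below
    a fraction of the signal RMS).

Because condition (b) needs a numeric threshold and pure monotonicity of
the sifting remainder never occurs for oscillatory modes, sifting also
stops on the standard Cauchy-style SD criterion or an iteration cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "EMDConfig",
    "IMFDecomposition",
    "InsufficientExtremaError",
    "find_extrema",
    "spline_envelope",
    "sift_once",
    "is_imf",
    "extract_imf",
    "decompose",
]


class InsufficientExtremaError(ValueError):
    """Signal has too few extrema to build an envelope (monotone residue)."""


@dataclass(frozen=True)
class EMDConfig:
    """Sifting controls.

    Parameters
    ----------
    max_imfs : int
        Upper bound on the number of IMFs extracted.
    max_sift_iterations : int
        Hard cap on sifting passes per IMF.
    sd_threshold : float
        Normalized squared difference between successive sifting
        candidates below which sifting stops (Huang's SD criterion).
    envelope_mean_tolerance : float
        IMF condition (b): RMS of the envelope mean must be below this
        fraction of the candidate's RMS.
    boundary_extension : int
        Number of extrema mirrored about each signal end before spline
        fitting, to suppress envelope end swings.
    """

    max_imfs: int = 10
    max_sift_iterations: int = 50
    sd_threshold: float = 0.2
    envelope_mean_tolerance: float = 0.05
    boundary_extension: int = 2

    def __post_init__(self) -> None:
        if self.max_imfs < 1:
            raise ValueError("max_imfs must be >= 1")
        if self.max_sift_iterations < 1:
            raise ValueError("max_sift_iterations must be >= 1")
        if self.sd_threshold <= 0:
            raise ValueError("sd_threshold must be > 0")


@dataclass
class IMFDecomposition:
    """Ordered IMFs plus residue for one signal.

    Invariant: ``original == sum(imfs) + residue`` to numerical tolerance,
    and all sequences share the original's length.
    """

    imfs: list[np.ndarray]
    residue: np.ndarray
    original: np.ndarray

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruction_error(self) -> float:
        """max |x - (sum h_i + r)| / max |x| (0 for an all-zero signal)."""
        recon = self.residue + (np.sum(self.imfs, axis=0) if self.imfs else 0.0)
        denom = np.max(np.abs(self.original))
        if denom == 0:
            return float(np.max(np.abs(self.original - recon)))
        return float(np.max(np.abs(self.original - recon)) / denom)


def find_extrema(signal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict interior local maxima and minima.

    Runs of equal values (plateaus) are collapsed to a single extremum at
    the plateau midpoint (rounded down). Endpoints are never extrema.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("signal must be 1-D with at least 3 samples")

    # Collapse plateaus: representatives of runs of equal consecutive values.
    change = np.flatnonzero(np.diff(x) != 0)
    if change.size == 0:  # constant signal
        empty = np.array([], dtype=int)
        return empty, empty
    run_starts = np.concatenate(([0], change + 1))
    run_ends = np.concatenate((change, [x.size - 1]))  # inclusive
    if run_starts.size < 3:
        empty = np.array([], dtype=int)
        return empty, empty
    # between consecutive runs the direction is strictly up or down
    up = np.diff(x[run_starts]) > 0
    mids = (run_starts[1:-1] + run_ends[1:-1]) // 2
    is_max = up[:-1] & ~up[1:]
    is_min = ~up[:-1] & up[1:]
    return mids[is_max], mids[is_min]


def _mirrored_knots(
    signal: np.ndarray, idx: np.ndarray, n_mirror: int
) -> tuple[np.ndarray, np.ndarray]:
    """Extend extrema by mirroring up to ``n_mirror`` of them about each end."""
    n = signal.size
    pos = idx.astype(float)
    val = signal[idx]
    k = min(n_mirror, idx.size)
    if k > 0:
        left_pos = -pos[:k][::-1]
        left_val = val[:k][::-1]
        right_pos = 2 * (n - 1) - pos[-k:][::-1]
        right_val = val[-k:][::-1]
        pos = np.concatenate([left_pos, pos, right_pos])
        val = np.concatenate([left_val, val, right_val])
    # Guard against coincident knots (extremum exactly at an end).
    keep = np.concatenate(([True], np.diff(pos) > 0))
    return pos[keep], val[keep]


def spline_envelope(
    signal: np.ndarray,
    extrema_indices: np.ndarray,
    which: str = "upper",
    boundary_extension: int = 2,
) -> np.ndarray:
    """Cubic-spline envelope through the given extrema.

    ``which`` is informational ("upper" or "lower"); the same interpolation
    applies to both. Raises :class:`InsufficientExtremaError` with fewer
    than 2 extrema (after boundary extension the knot count only grows).
    """
    if which not in ("upper", "lower"):
        raise ValueError("which must be 'upper' or 'lower'")
    x = np.asarray(signal, dtype=float)
    idx = np.asarray(extrema_indices, dtype=int)
    if idx.size < 2:
        raise InsufficientExtremaError(
            f"need >= 2 extrema for the {which} envelope, got {idx.size}"
        )
    pos, val = _mirrored_knots(x, idx, boundary_extension)
    t = np.arange(x.size, dtype=float)
    if pos.size >= 4:
        return CubicSpline(pos, val)(t)
    if pos.size == 3:
        return CubicSpline(pos, val, bc_type="natural")(t)
    return np.interp(t, pos, val)


def sift_once(
    signal: np.ndarray, boundary_extension: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """One sifting pass: returns (candidate d(t), mean envelope m(t)).

    m(t) = (u(t) + l(t)) / 2 and d(t) = signal - m(t), where u and l are
    the cubic-spline envelopes of the maxima and minima.
    """
    x = np.asarray(signal, dtype=float)
    maxima, minima = find_extrema(x)
    upper = spline_envelope(x, maxima, "upper", boundary_extension)
    lower = spline_envelope(x, minima, "lower", boundary_extension)
    mean_env = 0.5 * (upper + lower)
    return x - mean_env, mean_env


def _zero_crossings(x: np.ndarray) -> int:
    """Sign changes, ignoring exact zeros between samples of equal sign."""
    s = np.sign(x)
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.count_nonzero(np.diff(s)))


def is_imf(signal: np.ndarray, config: EMDConfig | None = None) -> tuple[bool, dict]:
    """Test the two IMF conditions; returns (verdict, diagnostics).

    Diagnostics report the extrema count, the zero-crossing count, and the
    envelope-mean RMS ratio.
    """
    cfg = config or EMDConfig()
    x = np.asarray(signal, dtype=float)
    diag: dict = {"n_extrema": 0, "n_zero_crossings": 0, "envelope_mean_ratio": np.inf}
    if x.size == 0:
        raise ValueError("empty signal")
    rms = float(np.sqrt(np.mean(x**2)))
    if rms == 0 or x.size < 3:
        diag["degenerate"] = True
        return False, diag
    maxima, minima = find_extrema(x)
    n_ext = maxima.size + minima.size
    n_zc = _zero_crossings(x)
    diag["n_extrema"] = n_ext
    diag["n_zero_crossings"] = n_zc
    counts_ok = abs(n_ext - n_zc) <= 1
    try:
        _, mean_env = sift_once(x, cfg.boundary_extension)
    except InsufficientExtremaError:
        diag["degenerate"] = True
        return False, diag
    ratio = float(np.sqrt(np.mean(mean_env**2)) / rms)
    diag["envelope_mean_ratio"] = ratio
    return counts_ok and ratio < cfg.envelope_mean_tolerance, diag


def extract_imf(signal: np.ndarray, config: EMDConfig | None = None) -> np.ndarray:
    """Sift one IMF out of ``signal``.

    Iterates until the candidate passes the IMF test, the SD criterion
    between successive candidates drops below ``sd_threshold``, or
    ``max_sift_iterations`` is reached. Raises
    :class:`InsufficientExtremaError` if the input has too few extrema to
    sift at all (the caller then treats it as the monotone residue).
    """
    cfg = config or EMDConfig()
    h = np.asarray(signal, dtype=float)
    prev = None
    for it in range(cfg.max_sift_iterations):
        try:
            d, mean_env = sift_once(h, cfg.boundary_extension)
        except InsufficientExtremaError:
            if it == 0:
                raise
            return h  # cannot sift further; caller vets the candidate
        # IMF conditions for the current candidate h, reusing its envelope
        # mean (this is exactly the is_imf test).
        rms = float(np.sqrt(np.mean(h**2)))
        if rms > 0:
            maxima, minima = find_extrema(h)
            counts_ok = abs(maxima.size + minima.size - _zero_crossings(h)) <= 1
            ratio = float(np.sqrt(np.mean(mean_env**2)) / rms)
            if counts_ok and ratio < cfg.envelope_mean_tolerance:
                return h
        # Huang-style SD between successive candidates: a sum of pointwise
        # squared relative differences (scale-invariant, eps-guarded).
        if prev is not None:
            guard = 1e-12 * float(np.max(prev**2)) + 1e-300
            sd = float(np.sum((prev - h) ** 2 / (prev**2 + guard)))
            if sd < cfg.sd_threshold:
                return h
        prev = h
        h = d
    return h


def decompose(signal: np.ndarray, config: EMDConfig | None = None) -> IMFDecomposition:
    """Full EMD: extract IMFs until the residue has <= 1 interior extremum
    or ``max_imfs`` is reached. The reconstruction identity holds by
    construction."""
    cfg = config or EMDConfig()
    x = np.asarray(signal, dtype=float)
    if x.size < 3:
        raise ValueError("signal must have at least 3 samples")
    residue = x.copy()
    imfs: list[np.ndarray] = []
    while len(imfs) < cfg.max_imfs:
        maxima, minima = find_extrema(residue)
        if maxima.size + minima.size <= 1:
            break
        try:
            h = extract_imf(residue, cfg)
        except InsufficientExtremaError:
            break
        h_max, h_min = find_extrema(h)
        if h_max.size < 2 or h_min.size < 2:
            # too few oscillations to qualify (or even test) as an IMF;
            # leave this near-monotone wobble in the residue
            break
        imfs.append(h)
        residue = residue - h
    return IMFDecomposition(imfs=imfs, residue=residue, original=x)
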