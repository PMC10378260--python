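import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sleephht import (
    EMDConfig,
    InsufficientExtremaError,
    decompose,
    extract_imf,
    find_extrema,
    is_imf,
    sift_once,
    spline_envelope,
)
from sleephht.hht import analytic_signal, instantaneous_frequency


# ---------------------------------------------------------------- extrema


def _brute_extrema(x):
    """Exhaustive run-compressed scan (independent of the implementation)."""
    x = np.asarray(x, float)
    ch = np.flatnonzero(np.diff(x) != 0)
    if ch.size == 0:
        return [], []
    rs = np.concatenate(([0], ch + 1))
    re = np.concatenate((ch, [len(x) - 1]))
    v = x[rs]
    ma, mi = [], []
    for k in range(1, len(rs) - 1):
        mid = (rs[k] + re[k]) // 2
        if v[k] > v[k - 1] and v[k] > v[k + 1]:
            ma.append(mid)
        elif v[k] < v[k - 1] and v[k] < v[k + 1]:
            mi.append(mid)
    return ma, mi


@pytest.mark.parametrize(
    "x,exp_max,exp_min",
    [
        ([0, 1, 0, -1, 0], [1], [3]),
        ([0, 1, 2, 3, 4], [], []),  # monotone ramp: no interior extrema
        ([0, 2, 2, 0], [1], []),  # plateau midpoint, rounded down
        ([0, 2, 2, 2, 0], [2], []),
        ([3, 1, 1, 3], [], [1]),
    ],
)
def test_find_extrema_examples(x, exp_max, exp_min):
    ma, mi = find_extrema(np.asarray(x, float))
    assert ma.tolist() == exp_max
    assert mi.tolist() == exp_min


def test_find_extrema_rejects_short_signal():
    with pytest.raises(ValueError):
        find_extrema(np.array([1.0, 2.0]))


@settings(deadline=None, max_examples=200)
@given(
    st.lists(st.integers(min_value=-4, max_value=4), min_size=3, max_size=50)
)
def test_find_extrema_matches_brute_scan(values):
    x = np.asarray(values, float)
    ma, mi = find_extrema(x)
    bma, bmi = _brute_extrema(x)
    assert ma.tolist() == bma
    assert mi.tolist() == bmi


# ---------------------------------------------------------------- envelope


def test_upper_envelope_of_sinusoid_is_flat(t_epoch):
    x = 2.5 * np.sin(2 * np.pi * 5 * t_epoch)
    ma, mi = find_extrema(x)
    upper = spline_envelope(x, ma, "upper")
    lower = spline_envelope(x, mi, "lower")
    sl = slice(300, 2700)  # away from edges
    assert np.allclose(upper[sl], 2.5, rtol=0.05)
    assert np.allclose(lower[sl], -2.5, rtol=0.05)


def test_envelope_through_equal_knots_is_constant():
    x = np.zeros(100)
    x[[10, 40, 70]] = 3.0
    env = spline_envelope(x, np.array([10, 40, 70]), "upper")
    assert np.allclose(env, 3.0)


def test_envelope_requires_two_extrema():
    x = np.sin(np.linspace(0, np.pi, 50))
    with pytest.raises(InsufficientExtremaError):
        spline_envelope(x, np.array([25]), "upper")


# ---------------------------------------------------------------- sifting


def test_sift_once_identity_and_offset(t_epoch):
    x = np.sin(2 * np.pi * 4 * t_epoch)
    d, m = sift_once(x)
    sl = slice(300, 2700)
    assert np.max(np.abs(m[sl])) < 0.05
    assert np.allclose(d[sl], x[sl], atol=0.05)
    # constant offset moves the envelope mean by the offset
    d2, m2 = sift_once(x + 7.0)
    assert np.allclose(m2[sl], 7.0, atol=0.1)
    # identity d + m == signal holds exactly
    assert np.allclose(d2 + m2, x + 7.0, rtol=0, atol=1e-12)


def test_is_imf_accepts_sinusoid_rejects_offset(t_epoch):
    x = np.sin(2 * np.pi * 10 * t_epoch[:1000])
    ok, diag = is_imf(x)
    assert ok
    assert abs(diag["n_extrema"] - diag["n_zero_crossings"]) <= 1
    ok_off, diag_off = is_imf(x + 10.0)
    assert not ok_off
    assert diag_off["n_zero_crossings"] == 0
    ok_zero, diag_zero = is_imf(np.zeros(100))
    assert not ok_zero and diag_zero.get("degenerate")


def test_extract_imf_recovers_pure_tone(t_epoch):
    x = np.sin(2 * np.pi * 10 * t_epoch)
    h = extract_imf(x)
    assert np.corrcoef(h, x)[0, 1] > 0.99


def test_first_imf_is_fast_tone_of_two_tone_mixture(t_epoch):
    x = np.sin(2 * np.pi * 10 * t_epoch) + np.sin(2 * np.pi * 1 * t_epoch)
    dec = decompose(x)
    sl = slice(300, 2700)  # central 80%
    tone = np.sin(2 * np.pi * 10 * t_epoch)
    assert np.corrcoef(dec.imfs[0][sl], tone[sl])[0, 1] > 0.95


# ---------------------------------------------------------------- decompose


def test_monotone_ramp_yields_no_imfs():
    x = np.linspace(0.0, 5.0, 500)
    dec = decompose(x)
    assert dec.n_imfs == 0
    assert np.array_equal(dec.residue, x)


def test_decompose_respects_max_imfs(t_epoch):
    rng = np.random.default_rng(3)
    x = rng.normal(size=3000)
    dec = decompose(x, EMDConfig(max_imfs=3))
    assert dec.n_imfs <= 3
    assert dec.reconstruction_error() < 1e-8


def test_imf_frequency_ordering(hundred_decompositions, fs):
    """Mean instantaneous frequency must not increase from first IMF to last."""
    for _ep, dec in hundred_decompositions[:10]:
        freqs = []
        for h in dec.imfs:
            _a, phase = analytic_signal(h)
            freqs.append(float(np.mean(instantaneous_frequency(phase, fs))))
        assert all(f1 >= f2 - 0.5 for f1, f2 in zip(freqs, freqs[1:]))
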