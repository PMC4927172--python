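"""Pyramid-transform identities: energy, reconstruction, shift structure."""

import warnings

import numpy as np
import pytest

from waveconn.filters import make_filter
from waveconn.transforms import (
    decompose_matrix,
    dwt,
    inverse_dwt,
    inverse_modwt,
    modwt,
    mra_details,
    scale_to_band,
)

FILTERS = [("D", 2), ("D", 8), ("LA", 8), ("LA", 20), ("C", 6), ("C", 24)]


def _mk(fam, L):
    return make_filter(fam, L)


@pytest.mark.parametrize("family,length", FILTERS)
@pytest.mark.parametrize("n", [64, 100, 177])
def test_modwt_energy_and_reconstruction(family, length, n, rng):
    x = rng.standard_normal(n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        d = modwt(x, _mk(family, length), 4)
    assert abs(d.energy() - x @ x) <= 1e-8 * (x @ x)
    np.testing.assert_allclose(inverse_modwt(d), x, atol=1e-10)


@pytest.mark.parametrize("family,length", FILTERS)
@pytest.mark.parametrize("n", [64, 100, 177])
def test_dwt_reconstruction_and_energy(family, length, n, rng):
    x = rng.standard_normal(n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        d = dwt(x, _mk(family, length), 4)
    np.testing.assert_allclose(inverse_dwt(d), x, atol=1e-10)
    assert abs(d.energy() - x @ x) <= 1e-8 * (x @ x)


def test_constant_series_has_zero_wavelet_coefficients(rng):
    c = 3.7
    d = modwt(np.full(96, c), _mk("LA", 8), 4)
    for w in d.coeffs_per_scale:
        np.testing.assert_allclose(w, 0.0, atol=c * 1e-12)


def test_constant_dwt_smooth_is_scaled_mean():
    d = dwt(np.ones(8), _mk("D", 2), 3)
    for w in d.coeffs_per_scale:
        np.testing.assert_allclose(w, 0.0, atol=1e-12)
    np.testing.assert_allclose(d.smooth, [2.0 * np.sqrt(2.0)], atol=1e-12)


def test_impulse_haar_modwt():
    """Circular Haar MODWT of a unit impulse: two entries of magnitude 1/2."""
    x = np.zeros(16)
    x[0] = 1.0
    d = modwt(x, _mk("D", 2), 1)
    w = d.coeffs_per_scale[0]
    nz = w[np.abs(w) > 1e-14]
    assert nz.size == 2
    np.testing.assert_allclose(np.abs(nz), 0.5, atol=1e-14)


def test_modwt_circular_shift_equivariance(rng):
    x = rng.standard_normal(128)
    f = _mk("D", 8)
    d = modwt(x, f, 4)
    k = 17
    d_shift = modwt(np.roll(x, k), f, 4)
    for w, ws in zip(d.coeffs_per_scale, d_shift.coeffs_per_scale):
        np.testing.assert_array_equal(np.roll(w, k), ws)
    np.testing.assert_array_equal(np.roll(d.smooth, k), d_shift.smooth)


@pytest.mark.parametrize("family,length", FILTERS)
def test_dwt_equals_subsampled_rescaled_modwt(family, length, rng):
    """For N a power of 2: W^D_j[t] = 2^(j/2) W^M_j[2^j (t+1) - 1]."""
    n = 128
    x = rng.standard_normal(n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dm = modwt(x, _mk(family, length), 4)
        dd = dwt(x, _mk(family, length), 4)
    for j in range(1, 5):
        t = np.arange(dd.coeffs_per_scale[j - 1].size)
        sub = dm.coeffs_per_scale[j - 1][(2**j * (t + 1) - 1) % n]
        np.testing.assert_allclose(
            2.0 ** (j / 2.0) * sub, dd.coeffs_per_scale[j - 1], atol=1e-10)


@pytest.mark.parametrize("family,length,wname", [
    ("D", 2, "haar"), ("D", 8, "db4"), ("LA", 8, "sym4"),
    ("LA", 20, "sym10"), ("C", 6, "coif1"), ("C", 24, "coif4"),
])
def test_modwt_matches_reference_library(family, length, wname, rng):
    """Independent-library equivalence with the documented convention map.

    The reference stationary transform is this MODWT conjugated by time
    reversal with a per-level circular advance of (2^j - 1)(L/2 - 1).
    """
    pywt = pytest.importorskip("pywt")
    n = 128
    x = rng.standard_normal(n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        d = modwt(x[::-1], _mk(family, length), 4)
    sw = pywt.swt(x, wname, level=4, norm=True, trim_approx=True)
    for j in range(1, 5):
        shift = (2**j - 1) * (length // 2 - 1) % n
        ours = np.roll(d.coeffs_per_scale[j - 1][::-1], shift)
        np.testing.assert_allclose(ours, sw[-j], atol=1e-8)
    shift = (2**4 - 1) * (length // 2 - 1) % n
    np.testing.assert_allclose(np.roll(d.smooth[::-1], shift), sw[0],
                               atol=1e-8)


def test_dwt_study_length_carry_rule():
    """N = 177 decomposes to depth 4 with the odd-length carry counts."""
    rng = np.random.default_rng(0)
    x = rng.standard_normal(177)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        d = dwt(x, _mk("LA", 8), 4)
    assert [w.size for w in d.coeffs_per_scale] == [88, 44, 22, 11]
    assert d.smooth.size == 12
    assert d.carries == [True, True, True, True]
    np.testing.assert_allclose(inverse_dwt(d), x, atol=1e-10)


def test_mra_details_additivity(rng):
    x = rng.standard_normal(100)
    d = modwt(x, _mk("D", 8), 4)
    details, smooth = mra_details(d)
    assert all(det.size == 100 for det in details)
    np.testing.assert_allclose(sum(details) + smooth, x, atol=1e-10)


def test_mra_details_of_constant_vanish():
    x = np.full(64, 2.5)
    details, smooth = mra_details(modwt(x, _mk("C", 6), 3))
    for det in details:
        np.testing.assert_allclose(det, 0.0, atol=1e-10)
    np.testing.assert_allclose(smooth, x, atol=1e-10)


def test_mra_rejects_dwt_input(rng):
    d = dwt(rng.standard_normal(64), _mk("D", 4), 2)
    with pytest.raises(ValueError):
        mra_details(d)


def test_inverse_method_mismatch(rng):
    d = dwt(rng.standard_normal(64), _mk("D", 4), 2)
    with pytest.raises(ValueError):
        inverse_modwt(d)


def test_variance_decomposition(rng):
    """Mean squared coefficients across scales sum to the second moment."""
    x = rng.standard_normal(256)
    d = modwt(x, _mk("LA", 8), 4)
    total = sum(np.mean(w**2) for w in d.coeffs_per_scale) + np.mean(
        d.smooth**2)
    np.testing.assert_allclose(total, np.mean(x**2), rtol=1e-10)


@pytest.mark.parametrize("tr,scale,low,high", [
    (2.0, 1, 0.125, 0.25),
    (2.0, 2, 0.0625, 0.125),
    (2.0, 3, 0.03125, 0.0625),
    (2.0, 4, 0.015625, 0.03125),
    (1.0, 1, 0.25, 0.5),
])
def test_scale_to_band(tr, scale, low, high):
    band = scale_to_band(tr, scale)
    assert band.low_hz == pytest.approx(low)
    assert band.high_hz == pytest.approx(high)
    assert band.low_hz < band.high_hz


def test_scale_to_band_rejects_bad_input():
    with pytest.raises(ValueError):
        scale_to_band(-1.0, 1)
    with pytest.raises(ValueError):
        scale_to_band(2.0, 0)


def test_input_validation(rng):
    f = _mk("D", 4)
    with pytest.raises(ValueError):
        modwt(np.array([1.0]), f, 1)
    with pytest.raises(ValueError):
        modwt(rng.standard_normal((4, 4)), f, 1)
    with pytest.raises(ValueError):
        modwt(rng.standard_normal(32), f, 0)


def test_decompose_matrix_matches_per_column(rng):
    ts = rng.standard_normal((96, 5))
    ds = decompose_matrix(ts, _mk("LA", 8), "MODWT", 4)
    assert len(ds) == 5
    ref = modwt(ts[:, 3], _mk("LA", 8), 4)
    np.testing.assert_array_equal(ds[3].coeffs_per_scale[1],
                                  ref.coeffs_per_scale[1])
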