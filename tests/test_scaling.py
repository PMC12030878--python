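import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mwcam.scaling import (
    CalibratedMaps,
    apply_contour_prior,
    minmax_complex,
    reconstruct_maps,
    rescale_properties,
    spectrum_normalize,
    water_calibrate,
)


def test_minmax_examples():
    img = np.array([[-2.0, 0.0, 2.0]]) + 1j * np.array([[1.0, 3.0, 5.0]])
    scaled, rec = minmax_complex(img)
    assert np.allclose(scaled.real, [[0.0, 0.5, 1.0]])
    assert np.allclose(scaled.imag, [[0.0, 0.5, 1.0]])
    assert (rec.re_min, rec.re_max, rec.im_min, rec.im_max) == (-2.0, 2.0, 1.0, 5.0)
    # exact 0 and 1 in each part; idempotent on an already-spanning image
    again, _ = minmax_complex(scaled)
    assert np.array_equal(again, scaled)
    assert scaled.real.min() == 0.0 and scaled.real.max() == 1.0


def test_minmax_rejects_constant_component():
    img = np.ones((4, 4)) + 1j * np.arange(16).reshape(4, 4)
    with pytest.raises(ValueError):
        minmax_complex(img)


@settings(max_examples=25, deadline=None)
@given(seed=st.integers(min_value=0, max_value=10**6))
def test_minmax_bounds_property(seed):
    rng = np.random.default_rng(seed)
    img = rng.standard_normal((8, 8)) * 5 + 1j * rng.standard_normal((8, 8))
    scaled, _ = minmax_complex(img)
    for part in (scaled.real, scaled.imag):
        assert part.min() == 0.0 and part.max() == 1.0


def test_spectrum_normalize_bounds_and_phase(sgrid):
    rng = np.random.default_rng(7)
    img = rng.random((64, 64)) + 1j * rng.random((64, 64))
    spec = spectrum_normalize(img, sgrid)
    mags = np.abs(spec.values[spec.mask])
    assert np.isclose(mags.max(), 1.0)
    assert spec.values.real.min() >= -1.0 and spec.values.real.max() <= 1.0
    assert spec.values.imag.min() >= -1.0 and spec.values.imag.max() <= 1.0
    # renormalizing a normalized spectrum is the identity on the mask
    # (the spectral image of the normalized spectrum is already scaled)
    # and normalization preserves phase: compare against the unnormalized
    # filtered spectrum
    from mwcam.spectral import crop_box, field_spectrum, visible_filter

    raw = crop_box(visible_filter(field_spectrum(img, sgrid.geometry), sgrid, 0.5))
    nz = spec.mask & (np.abs(raw.values) > 0)
    assert np.allclose(np.angle(spec.values[nz]), np.angle(raw.values[nz]))


def test_water_calibration_fixed_points(geometry):
    rng = np.random.default_rng(8)
    img = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
    contour = np.zeros((16, 16), dtype=bool)
    contour[4:12, 4:12] = True
    maps = water_calibrate(img, contour, geometry)
    # a pixel whose real part equals the water mean maps to eps_water exactly
    probe = img.copy()
    probe[0, 0] = maps.m_re + 1j * maps.m_im
    maps2 = water_calibrate(probe, contour, geometry)
    outside_mean_re = probe.real[~contour].mean()
    assert np.isclose(
        maps2.eps_cal[0, 0], probe.real[0, 0] / outside_mean_re * 73.0
    )
    # water region maps to (73, 1) on average
    assert np.isclose(maps.eps_cal[~contour].mean(), 73.0)
    assert np.isclose(maps.sigma_cal[~contour].mean(), 1.0)


def test_water_calibration_scale_invariance(geometry):
    rng = np.random.default_rng(9)
    img = rng.standard_normal((8, 8)) + 1j * rng.standard_normal((8, 8))
    contour = np.zeros((8, 8), dtype=bool)
    contour[2:5, 2:5] = True
    a = water_calibrate(img, contour, geometry)
    b = water_calibrate(2.0 * img, contour, geometry)
    assert np.allclose(a.eps_cal, b.eps_cal)
    assert np.allclose(a.sigma_cal, b.sigma_cal)


def test_water_calibration_errors(geometry):
    img = np.ones((4, 4), complex)
    with pytest.raises(ValueError):
        water_calibrate(img, np.ones((4, 4), bool), geometry)


def test_rescale_positive_and_toy_values(geometry):
    """Hand evaluation of the second min-max pass on a 3-pixel map."""
    eps_cal = np.array([[-2.0, 1.0, 4.0]])
    sigma_cal = np.array([[-1.0, 0.5, 2.0]])
    maps = rescale_properties(CalibratedMaps(eps_cal, sigma_cal, 1.0, 1.0))
    # eps: spans [min|.|, max|.|] = [1, 4] affinely over [-2, 4]
    assert np.allclose(maps.eps_net, [[1.0, 2.5, 4.0]])
    # sigma: mirrored structure: max|.| + (min|.|-max|.|)*(x-min)/(max-min)
    # = 2 + (0.5-2)*(x+1)/3
    assert np.allclose(maps.sigma_net, [[2.0, 1.25, 0.5]])
    assert maps.eps_net.min() >= 0 and maps.sigma_net.min() >= 0


def test_rescale_identity_when_positive_spanning():
    eps_cal = np.array([[1.0, 2.0, 4.0]])
    maps = rescale_properties(CalibratedMaps(eps_cal, eps_cal.copy(), 1.0, 1.0))
    assert np.allclose(maps.eps_net, eps_cal)


@settings(max_examples=25, deadline=None)
@given(seed=st.integers(min_value=0, max_value=10**6))
def test_rescale_always_nonnegative(seed):
    rng = np.random.default_rng(seed)
    m = rng.standard_normal((5, 5)) * 10
    maps = rescale_properties(CalibratedMaps(m, m.copy(), 1.0, 1.0))
    assert maps.eps_net.min() >= 0
    assert maps.sigma_net.min() >= 0


def test_contour_prior(geometry):
    rng = np.random.default_rng(10)
    eps = rng.random((8, 8)) + 1
    sig = rng.random((8, 8))
    contour = np.zeros((8, 8), dtype=bool)
    contour[3:6, 3:6] = True
    maps = CalibratedMaps(eps, sig, 1.0, 1.0, eps.copy(), sig.copy())
    out = apply_contour_prior(maps, contour, geometry)
    assert np.all(out.eps_net[~contour] == 73.0)
    assert np.all(out.sigma_net[~contour] == 1.0)
    assert np.array_equal(out.eps_net[contour], eps[contour])
    # idempotent
    again = apply_contour_prior(out, contour, geometry)
    assert np.array_equal(again.eps_net, out.eps_net)
    # all-water mask gives the constant background maps
    allwater = apply_contour_prior(
        CalibratedMaps(eps, sig, 1.0, 1.0, eps.copy(), sig.copy()),
        np.zeros((8, 8), bool),
        geometry,
    )
    assert np.all(allwater.eps_net == 73.0) and np.all(allwater.sigma_net == 1.0)


def test_perfect_network_roundtrip(small_samples, sgrid):
    """Feeding the reference spectrum through the denormalization chain
    recovers water exactly outside the contour and a map that tracks the
    true permittivity inside (up to half-visible spectral truncation)."""
    for sample in small_samples[:3]:
        maps = reconstruct_maps(sample.pair.c_norm, sample.contour, sgrid)
        assert np.all(maps.eps_net[~sample.contour] == 73.0)
        assert np.all(maps.sigma_net[~sample.contour] == 1.0)
        truth = sample.contrast.real + 73.0
        inside = sample.contour
        corr = np.corrcoef(maps.eps_net[inside], truth[inside])[0, 1]
        assert corr > 0.5
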