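import numpy as np
import pytest

from mwcam.spectral import (
    CROP_HALF,
    CurrentSpectrum,
    backproject,
    crop_box,
    diffraction_map,
    differential_image,
    embed,
    field_spectrum,
    inverse_field_spectrum,
    nsd,
    visible_filter,
)


def test_spectral_constants(geometry):
    assert round(geometry.k_water) == 438
    assert np.isclose(geometry.spectral_step * 16, geometry.k_water)
    assert np.isclose(geometry.spacing, geometry.wavelength / 4)


def test_visible_mask_counts(sgrid):
    assert sgrid.visible_mask(0.5).sum() == 197
    # natural inclusive-lattice count of the full visible disk on this grid
    assert sgrid.visible_mask(1.0).sum() == 797


def test_half_visible_fits_17x17(sgrid):
    mask = sgrid.visible_mask(0.5)
    rows = np.where(mask.any(axis=1))[0]
    cols = np.where(mask.any(axis=0))[0]
    assert rows.max() - rows.min() + 1 == 17
    assert cols.max() - cols.min() + 1 == 17


def test_gamma_real_exactly_on_visible(sgrid, geometry):
    gamma = sgrid.gamma()
    vis = sgrid.visible_mask(1.0)
    assert np.all(gamma.imag[vis] == 0)
    assert np.all(gamma.real[~vis] == 0)
    # unit-modulus propagator on the visible disk
    assert np.allclose(
        np.abs(np.exp(1j * gamma[vis] * geometry.distance)), 1.0
    )


def test_filter_idempotent_and_validates(sgrid):
    rng = np.random.default_rng(0)
    spec = rng.standard_normal((64, 64)) + 1j * rng.standard_normal((64, 64))
    once = visible_filter(spec, sgrid, fraction=0.5)
    twice = visible_filter(once.values, sgrid, fraction=0.5)
    assert np.array_equal(once.values, twice.values)
    assert np.all(once.values[~once.mask] == 0)
    with pytest.raises(ValueError):
        visible_filter(spec, sgrid, fraction=0.3)


def test_all_ones_filter_sum_is_197(sgrid):
    filtered = visible_filter(np.ones((64, 64), complex), sgrid, fraction=0.5)
    assert filtered.values.sum() == 197


def test_crop_embed_roundtrip(sgrid):
    rng = np.random.default_rng(1)
    spec = rng.standard_normal((64, 64)) + 1j * rng.standard_normal((64, 64))
    filtered = visible_filter(spec, sgrid, fraction=0.5)
    cropped = crop_box(filtered)
    assert cropped.values.shape == (17, 17)
    assert cropped.mask.sum() == 197
    back = embed(cropped)
    assert np.array_equal(back.values, filtered.values)
    # DC maps to the crop center
    assert cropped.offset == 24
    delta = np.zeros((64, 64), complex)
    delta[32, 32] = 1.0
    c = crop_box(visible_filter(delta, sgrid, fraction=0.5))
    assert c.values[CROP_HALF, CROP_HALF] == 1.0


def test_crop_rejects_energy_outside_window(sgrid):
    full = visible_filter(np.ones((64, 64), complex), sgrid, fraction=1.0)
    with pytest.raises(ValueError):
        crop_box(full)


def test_field_spectrum_basics(geometry):
    n = geometry.n_retina
    const = np.full((n, n), 2.0 + 0j)
    spec = field_spectrum(const, geometry)
    dc = spec[n // 2, n // 2]
    assert np.isclose(dc, 2.0 * geometry.spacing**2 * n * n)
    off = spec.copy()
    off[n // 2, n // 2] = 0
    assert np.abs(off).max() < 1e-9 * abs(dc)
    # single off-center delta -> flat magnitude
    delta = np.zeros((n, n), complex)
    delta[30, 35] = 1.0
    spec = field_spectrum(delta, geometry)
    assert np.allclose(np.abs(spec), geometry.spacing**2)
    # round trip
    rng = np.random.default_rng(2)
    f = rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
    assert np.allclose(inverse_field_spectrum(field_spectrum(f, geometry), geometry), f)
    with pytest.raises(ValueError):
        field_spectrum(np.zeros((32, 32)), geometry)


def test_diffraction_map_zero_and_inverse(sgrid, geometry):
    zero = diffraction_map(np.zeros((64, 64), complex), sgrid)
    assert np.all(zero.values == 0)
    # applying the forward relation then the inverse is the identity on the
    # interior of the visible disk (the gamma=0 rim is zeroed by the 2*gamma
    # factor and carries no recoverable current)
    rng = np.random.default_rng(3)
    j_true = rng.standard_normal((64, 64)) + 1j * rng.standard_normal((64, 64))
    gamma = sgrid.gamma().real
    vis = sgrid.visible_mask(1.0)
    kernel = np.zeros((64, 64), complex)
    nz = vis & (gamma > 0)
    kernel[nz] = (-1j / (2 * gamma[nz])) * np.exp(-1j * gamma[nz] * geometry.distance)
    e_hat = j_true * kernel
    rec = diffraction_map(e_hat, sgrid)
    assert np.allclose(rec.values[nz], j_true[nz], rtol=1e-12, atol=1e-12)
    assert np.all(rec.values[~vis] == 0)


def test_backproject_zero_and_parseval(sgrid, geometry):
    rng = np.random.default_rng(4)
    spec = rng.standard_normal((64, 64)) + 1j * rng.standard_normal((64, 64))
    filtered = visible_filter(spec, sgrid, fraction=0.5)
    img = backproject(filtered)
    assert img.shape == (64, 64)
    # Parseval for the chosen transform pair
    lhs = np.sum(np.abs(img) ** 2)
    rhs = np.sum(np.abs(filtered.values) ** 2) / (64**2 * geometry.spacing**4)
    assert np.isclose(lhs, rhs)
    zero = visible_filter(np.zeros((64, 64), complex), sgrid, fraction=0.5)
    assert np.all(backproject(zero) == 0)


def test_nsd_normalization(sgrid):
    values = np.zeros((64, 64), complex)
    values[32, 32] = 4.0
    values[32, 33] = 0.4
    cs = CurrentSpectrum(values, sgrid.visible_mask(0.5), sgrid)
    db = nsd(cs)
    assert db[32, 32] == 0.0
    assert np.isclose(db[32, 33], -20.0)
    # invariant under global complex scaling
    cs2 = CurrentSpectrum(values * (3 - 2j), cs.mask, sgrid)
    assert np.allclose(nsd(cs2), db)
    with pytest.raises(ValueError):
        nsd(CurrentSpectrum(np.zeros((64, 64), complex), cs.mask, sgrid))


def test_differential_image():
    rng = np.random.default_rng(5)
    a = rng.standard_normal((64, 64)) + 1j * rng.standard_normal((64, 64))
    assert np.all(differential_image(a, a) == 0)
    b = a + 1j
    assert np.all(differential_image(a, b) >= 0)
    with pytest.raises(ValueError):
        differential_image(a, a[:10])
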