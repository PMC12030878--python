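import numpy as np
import pytest

from mwcam.forward import add_awgn, born_forward, incident_field
from mwcam.phantoms import GridSpec, PhantomConfig, TissueDielectrics, build_phantom
from mwcam.spectral import diffraction_map, field_spectrum

from .oracles import weyl_point_source_field, y_integrated_current_spectrum


def water_phantom(grid, geometry, nominal):
    ph = build_phantom(PhantomConfig(1, 1), nominal, grid, geometry)
    ph.eps[:] = geometry.eps_water_complex
    ph.labels[:] = 0
    return ph


def test_incident_field_plane_wave(geometry):
    y = np.array([0.0, 0.05, geometry.wavelength])
    e = incident_field(geometry, y)
    assert e[0] == 1.0 + 0.0j
    assert np.allclose(np.abs(e), 1.0)
    # phase advance over one wavelength is a full turn
    assert np.isclose(np.angle(e[2] / e[0]) % (2 * np.pi), 0.0, atol=1e-9)


def test_zero_contrast_scatters_nothing(grid, geometry, nominal):
    ph = water_phantom(grid, geometry, nominal)
    rf = born_forward(ph, geometry)
    assert np.all(rf.field == 0)


def test_born_linearity(grid, geometry, nominal):
    """Under the first Born approximation the retina field is linear in
    the contrast."""
    ph1 = water_phantom(grid, geometry, nominal)
    ph2 = water_phantom(grid, geometry, nominal)
    ph1.eps[30, 13, 34] = geometry.eps_water_complex + (2.0 - 0.5j)
    ph2.eps[30, 13, 34] = geometry.eps_water_complex + 3.0 * (2.0 - 0.5j)
    f1 = born_forward(ph1, geometry).field
    f2 = born_forward(ph2, geometry).field
    assert np.allclose(f2, 3.0 * f1, rtol=1e-12)


def test_scattered_power_quadratic_in_contrast(grid, geometry, nominal):
    ph1 = water_phantom(grid, geometry, nominal)
    ph2 = water_phantom(grid, geometry, nominal)
    ph1.eps[30, 13, 34] = geometry.eps_water_complex + 1.0
    ph2.eps[30, 13, 34] = geometry.eps_water_complex + 2.0
    p1 = np.sum(np.abs(born_forward(ph1, geometry).field) ** 2)
    p2 = np.sum(np.abs(born_forward(ph2, geometry).field) ** 2)
    assert np.isclose(p2 / p1, 4.0, rtol=1e-10)


def test_forward_inverse_adjoint_consistency(grid, geometry, nominal, sgrid):
    """Recovered current spectrum equals the transverse transform of the
    y-integrated Born currents on the propagative interior, to round-off."""
    cfg = PhantomConfig(2, 3, tumor_case=4, rotation=3, mirror=True, jitter_seed=5)
    ph = build_phantom(cfg, nominal, grid, geometry)
    rf = born_forward(ph, geometry)
    rec = diffraction_map(field_spectrum(rf.field, geometry), sgrid)
    oracle = y_integrated_current_spectrum(
        ph, geometry, sgrid.axis(), sgrid.gamma().real
    )
    interior = sgrid.visible_mask(1.0) & (sgrid.gamma().real > 0)
    err = np.linalg.norm((rec.values - oracle)[interior]) / np.linalg.norm(
        oracle[interior]
    )
    assert err < 1e-9


def test_single_voxel_matches_weyl_quadrature(grid, geometry, nominal):
    """With the physical (attenuating) water kernel, the oversampled
    angular-spectrum field of one voxel matches a fine quadrature of the
    Weyl integral."""
    ph = water_phantom(grid, geometry, nominal)
    ix, iy, iz = 34, 13, 30
    ph.eps[ix, iy, iz] = nominal.complex_permittivity("tumor", geometry)
    rf = born_forward(ph, geometry, medium="lossy", oversample=4)
    x = geometry.retina_coords()
    y = ph.grid.y_coords()
    kw2 = geometry.k0**2 * geometry.eps_water_complex
    j_val = (geometry.k0**2 * ph.eps[ix, iy, iz] - kw2) * np.exp(
        -1j * geometry.k_water_complex * y[iy]
    )
    sub = np.arange(0, 64, 8)
    oracle = weyl_point_source_field(
        geometry,
        (x[ix], y[iy], x[iz]),
        j_val,
        geometry.spacing**2 * ph.grid.spacing,
        x[sub],
        x[sub],
        n_nodes=1200,
    )
    mine = rf.field[np.ix_(sub, sub)]
    assert np.linalg.norm(mine - oracle) / np.linalg.norm(oracle) < 1e-3


def test_forward_validates_grid(geometry, nominal):
    bad = GridSpec(n_transverse=32, ny=5)
    ph = build_phantom(PhantomConfig(1, 1), nominal, bad, geometry)
    with pytest.raises(ValueError):
        born_forward(ph, geometry)


def test_awgn_properties(grid, geometry, nominal):
    ph = water_phantom(grid, geometry, nominal)
    ph.eps[30, 13, 30] = geometry.eps_water_complex + 5.0
    rf = born_forward(ph, geometry)
    # infinite SNR leaves the field untouched
    same = add_awgn(rf, np.inf, 0)
    assert np.array_equal(same.field, rf.field)
    # determinism
    a = add_awgn(rf, 10.0, 123)
    b = add_awgn(rf, 10.0, 123)
    assert np.array_equal(a.field, b.field)
    # empirical SNR over 100 draws at 10 dB
    sig = np.mean(np.abs(rf.field) ** 2)
    ratios = []
    for s in range(100):
        noisy = add_awgn(rf, 10.0, s)
        ratios.append(sig / np.mean(np.abs(noisy.field - rf.field) ** 2))
    snr = 10 * np.log10(np.mean(ratios))
    assert abs(snr - 10.0) < 0.5
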