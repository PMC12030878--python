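"""Independent reference computations used by the test suite.

Everything here deliberately avoids the package's FFT-based code paths:
transforms are explicit DFT matrix products, the Weyl integral is a fine
Riemann quadrature, the cylinder field is a cylindrical-harmonics series,
and SSIM is a direct implementation of the windowed formula.
"""

from __future__ import annotations

import numpy as np
from scipy.special import jv, yv


def y_integrated_current_spectrum(phantom, geometry, grid_k, gamma):
    """Transverse DFT of the y-integrated first-Born currents.

    Evaluates sum_y FT2D{j_z(., y, .)} * exp(+i gamma y) * dy with explicit
    exponential matrices (no FFT); this is the quantity the diffraction
    theorem recovers from the scattered-field spectrum.
    """
    x = geometry.retina_coords()
    y = phantom.grid.y_coords()
    fx = np.exp(-1j * np.outer(grid_k, x))
    kw2 = geometry.k0**2 * geometry.eps_water_complex
    dy = phantom.grid.spacing
    out = np.zeros((len(grid_k), len(grid_k)), dtype=complex)
    for iy, y_val in enumerate(y):
        j_slab = (geometry.k0**2 * phantom.eps[:, iy, :] - kw2) * np.exp(
            -1j * geometry.k_water * y_val
        )
        j_hat = fx @ j_slab @ fx.T * geometry.spacing**2
        out += j_hat * np.exp(1j * gamma * y_val) * dy
    return out


def weyl_point_source_field(
    geometry, source_xyz, j_value, volume, obs_x, obs_z, n_nodes=1400, k_margin=2.5
):
    """Fine Riemann quadrature of the Weyl integral for one point current.

    Uses the lossy water wavenumber so the integrand decays and the
    quadrature converges; returns the field at the retina points
    (obs_x x obs_z) at y = d.
    """
    from mwcam.spectral import branch_gamma

    kc = geometry.k_water_complex
    xs, ys, zs = source_xyz
    d = geometry.distance
    kmax = k_margin * geometry.k_water
    kk = np.linspace(-kmax, kmax, n_nodes, endpoint=False)
    kk = kk + (kk[1] - kk[0]) / 2.0
    dk = kk[1] - kk[0]
    kx, kz = np.meshgrid(kk, kk, indexing="ij")
    gamma = branch_gamma(kc, kx, kz)
    core = (-1j / (8.0 * np.pi**2 * gamma)) * np.exp(-1j * gamma * (d - ys))
    ex = np.exp(-1j * np.outer(np.asarray(obs_x) - xs, kk))
    ez = np.exp(-1j * np.outer(np.asarray(obs_z) - zs, kk))
    return (
        j_value
        * volume
        * np.einsum("am,mn,bn->ab", ex, core, ez, optimize=True)
        * dk
        * dk
    )


def _h2(n, z):
    z = np.asarray(z, dtype=complex)
    return jv(n, z) - 1j * yv(n, z)


def cylinder_total_field(geometry, k_background, eps_cyl, radius, X, Y, n_terms=30):
    """Cylindrical-harmonics series for a z-polarized plane wave on a
    homogeneous cylinder (exp(+i w t), incident exp(-i k y))."""
    k1 = complex(k_background)
    k2 = geometry.k0 * np.sqrt(complex(eps_cyl))
    x1, x2 = k1 * radius, k2 * radius

    def jp(n, z):
        return 0.5 * (jv(n - 1, z) - jv(n + 1, z))

    def h2p(n, z):
        return 0.5 * (_h2(n - 1, z) - _h2(n + 1, z))

    rho = np.hypot(X, Y)
    phi = np.arctan2(Y, X)
    inside = rho <= radius
    total = np.zeros(X.shape, dtype=complex)
    for n in range(-n_terms, n_terms + 1):
        a_n = (k2 * jp(n, x2) * jv(n, x1) - k1 * jv(n, x2) * jp(n, x1)) / (
            k1 * jv(n, x2) * h2p(n, x1) - k2 * jp(n, x2) * _h2(n, x1)
        )
        c_n = (jv(n, x1) + a_n * _h2(n, x1)) / jv(n, x2)
        term = np.where(
            inside,
            c_n * jv(n, k2 * rho),
            jv(n, k1 * rho) + a_n * _h2(n, k1 * rho),
        )
        total += term * np.exp(-1j * n * phi)
    return total


def direct_ssim(a, b, data_range, win=11, sigma=1.5, k1=0.01, k2=0.03):
    """Direct windowed-SSIM evaluation (valid windows, Gaussian weights)."""
    half = win // 2
    ax = np.arange(win) - half
    g = np.exp(-(ax**2) / (2 * sigma**2))
    w = np.outer(g, g)
    w /= w.sum()
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    h, wd = a.shape
    vals = []
    for i in range(half, h - half):
        for j in range(half, wd - half):
            pa = a[i - half : i + half + 1, j - half : j + half + 1]
            pb = b[i - half : i + half + 1, j - half : j + half + 1]
            mu_a = (w * pa).sum()
            mu_b = (w * pb).sum()
            va = (w * (pa - mu_a) ** 2).sum()
            vb = (w * (pb - mu_b) ** 2).sum()
            cov = (w * (pa - mu_a) * (pb - mu_b)).sum()
            vals.append(
                ((2 * mu_a * mu_b + c1) * (2 * cov + c2))
                / ((mu_a**2 + mu_b**2 + c1) * (va + vb + c2))
            )
    return float(np.mean(vals))
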