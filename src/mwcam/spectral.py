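"""Fourier-diffraction-theorem machinery.

Conventions (fixed once, used everywhere):

* time dependence ``exp(+i w t)``, spatial kernels ``exp(-i k.r)``;
* centered ("shifted") spectral layout with DC at index (n//2, n//2);
* continuous-transform normalization: the field spectrum is ``spacing**2``
  times the centered DFT (a Riemann sum of the continuous transform), so the
  diffraction relation E_hat = (-i/2 gamma) j_hat exp(-i gamma d) holds with
  physical units;
* longitudinal wavenumber ``gamma = sqrt(k_water^2 - kx^2 - kz^2)``, real and
  non-negative on the visible disk kx^2 + kz^2 <= k_water^2, and equal to
  ``-i sqrt(kx^2 + kz^2 - k_water^2)`` outside so that evanescent components
  decay under ``exp(-i gamma d)``.

On the 64 x 64 grid the spectral step is exactly k_water/16; the half-visible
disk (radius k_water/2, inclusive boundary) retains 197 pixels inside a
17 x 17 bounding box.  The inclusive-lattice count of the full visible disk
is 797 on this grid.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .geometry import CameraGeometry

CROP_HALF = 8  #: half-width of the symmetric crop window around DC
CROP_SIZE = 2 * CROP_HALF + 1


def cfft2(arr: np.ndarray) -> np.ndarray:
    """Centered 2D DFT (DC at the middle of the shifted layout)."""
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(arr)))


def icfft2(arr: np.ndarray) -> np.ndarray:
    """Inverse of :func:`cfft2`."""
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(arr)))


def branch_gamma(k: complex, kx: np.ndarray, kz: np.ndarray) -> np.ndarray:
    """Longitudinal wavenumber with the decaying branch.

    The principal square root is flipped wherever its imaginary part is
    positive, so ``exp(-i gamma y)`` never grows with propagation distance;
    for a real ``k`` this reduces to real gamma inside the visible disk and
    ``-i|gamma|`` outside.
    """
    g = np.sqrt(k * k - kx * kx - kz * kz + 0j)
    return np.where(g.imag > 0, -g, g)


@dataclass(frozen=True)
class SpectralGrid:
    """Centered (kx, kz) grid attached to a camera geometry."""

    geometry: CameraGeometry

    @property
    def n(self) -> int:
        return self.geometry.n_retina

    @property
    def step(self) -> float:
        return self.geometry.spectral_step

    def axis(self) -> np.ndarray:
        n = self.n
        return (np.arange(n) - n // 2) * self.step

    def mesh(self):
        k = self.axis()
        return np.meshgrid(k, k, indexing="ij")

    def gamma(self) -> np.ndarray:
        kx, kz = self.mesh()
        return branch_gamma(complex(self.geometry.k_water), kx, kz)

    def visible_mask(self, fraction: float = 1.0) -> np.ndarray:
        """Inclusive-boundary disk kx^2 + kz^2 <= (fraction * k_water)^2."""
        kx, kz = self.mesh()
        radius = fraction * self.geometry.k_water
        return kx * kx + kz * kz <= radius * radius * (1 + 1e-12)


@dataclass
class CurrentSpectrum:
    """Complex spectrum samples plus the active mask.

    ``values`` and ``mask`` are either full 64 x 64 maps or the 17 x 17 crop
    (``offset`` records the crop corner in the full grid; ``None`` when
    uncropped).  Values outside the active mask are exactly zero.
    """

    values: np.ndarray
    mask: np.ndarray
    grid: SpectralGrid
    offset: Optional[int] = None

    @property
    def cropped(self) -> bool:
        return self.offset is not None


def field_spectrum(field: np.ndarray, geometry: CameraGeometry) -> np.ndarray:
    """Spectrum of a retina field: spacing^2 times the centered DFT."""
    n = geometry.n_retina
    if field.shape != (n, n):
        raise ValueError(f"expected a {n}x{n} field, got {field.shape}")
    return cfft2(field) * geometry.spacing**2


def inverse_field_spectrum(spectrum: np.ndarray, geometry: CameraGeometry) -> np.ndarray:
    """Inverse of :func:`field_spectrum`."""
    return icfft2(spectrum) / geometry.spacing**2


def diffraction_map(e_hat: np.ndarray, grid: SpectralGrid) -> CurrentSpectrum:
    """Invert the Fourier diffraction relation inside the visible domain.

    ``j_hat = 2 i gamma E_hat exp(+i gamma d)`` where gamma is real; outside
    the visible disk the current spectrum is set to zero.  No division
    occurs, so the gamma -> 0 rim is benign (the 2*gamma factor vanishes).
    """
    mask = grid.visible_mask(1.0)
    gamma = grid.gamma().real
    d = grid.geometry.distance
    j_hat = 2j * gamma * e_hat * np.exp(1j * gamma * d)
    j_hat = np.where(mask, j_hat, 0.0 + 0.0j)
    return CurrentSpectrum(j_hat, mask, grid)


def visible_filter(spectrum, grid: SpectralGrid = None, fraction: float = 1.0) -> CurrentSpectrum:
    """Zero everything outside the (inclusive) disk of radius fraction*k_water.

    Only the fractions defined by the imaging method are accepted: 1.0 (the
    visible domain) and 0.5 (the half-visible domain, 197 surviving pixels
    fitting a 17 x 17 box).  Idempotent.
    """
    if fraction not in (1.0, 0.5):
        raise ValueError("fraction must be 1.0 or 0.5")
    if isinstance(spectrum, CurrentSpectrum):
        if spectrum.cropped:
            raise ValueError("visible_filter expects a full-grid spectrum")
        grid = spectrum.grid
        values = spectrum.values
    else:
        if grid is None:
            raise ValueError("a SpectralGrid is required for bare arrays")
        values = np.asarray(spectrum)
    mask = grid.visible_mask(fraction)
    return CurrentSpectrum(np.where(mask, values, 0.0 + 0.0j), mask, grid)


def crop_box(filtered: CurrentSpectrum) -> CurrentSpectrum:
    """Extract the 17 x 17 window centered on DC (offsets -8..+8).

    Requires a half-visible-filtered input: any active pixel outside the
    window indicates a wrong mask and raises.
    """
    if filtered.cropped:
        return filtered
    n = filtered.grid.n
    lo = n // 2 - CROP_HALF
    hi = n // 2 + CROP_HALF + 1
    outside = filtered.mask.copy()
    outside[lo:hi, lo:hi] = False
    if outside.any() or (filtered.values * ~filtered.mask).any():
        raise ValueError("active pixels outside the 17x17 crop window")
    return CurrentSpectrum(
        filtered.values[lo:hi, lo:hi].copy(),
        filtered.mask[lo:hi, lo:hi].copy(),
        filtered.grid,
        offset=lo,
    )


def embed(cropped: CurrentSpectrum) -> CurrentSpectrum:
    """Re-embed a 17 x 17 crop into the full spectral grid (exact inverse)."""
    if not cropped.cropped:
        return cropped
    n = cropped.grid.n
    lo = cropped.offset
    hi = lo + cropped.values.shape[0]
    values = np.zeros((n, n), dtype=np.complex128)
    mask = np.zeros((n, n), dtype=bool)
    values[lo:hi, lo:hi] = cropped.values
    mask[lo:hi, lo:hi] = cropped.mask
    return CurrentSpectrum(values, mask, cropped.grid, offset=None)


def backproject(j_hat: CurrentSpectrum) -> np.ndarray:
    """Backpropagation image: inverse centered transform of the filtered j_hat.

    Returns the complex induced-current image j_z(x, z) on the 64 x 64 grid,
    the camera's qualitative image.
    """
    full = embed(j_hat)
    return inverse_field_spectrum(full.values, full.grid.geometry)


def nsd(j_hat: CurrentSpectrum, floor_db: float = -300.0) -> np.ndarray:
    """Normalized spectral density 10*log10(|j_hat|^2 / max |j_hat|^2) in dB.

    The maximum pixel is exactly 0 dB; zero pixels are clipped at
    ``floor_db``.  Raises on an all-zero spectrum.
    """
    power = np.abs(j_hat.values) ** 2
    peak = power.max()
    if peak == 0.0:
        raise ValueError("NSD of an all-zero spectrum is undefined")
    with np.errstate(divide="ignore"):
        out = 10.0 * np.log10(power / peak)
    return np.maximum(out, floor_db)


def differential_image(j_with: np.ndarray, j_without: np.ndarray) -> np.ndarray:
    """Magnitude of the complex difference between two current images."""
    if j_with.shape != j_without.shape:
        raise ValueError("differential images require identical shapes")
    return np.abs(j_with - j_without)
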