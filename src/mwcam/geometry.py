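"""Planar microwave camera geometry.

The camera illuminates a water tank with a z-polarized monochromatic plane
wave at 2.45 GHz and samples the scattered field on a planar "retina" of
64 x 64 dipoles spaced a quarter of the in-water wavelength apart.  The
object under test sits around the observation plane, a distance ``d`` in
front of the retina along the propagation axis ``y``.

Axis convention used throughout the package: the retina lies in the x-z
plane at ``y = d``; the observation plane is ``y = 0``; the incident wave
travels toward +y with phase ``exp(-i k_water y)`` under the ``exp(+i w t)``
time convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Speed of light used for all wavenumber bookkeeping (m/s).
C0 = 3.0e8
#: Vacuum permittivity (F/m).
EPS0 = 8.8541878128e-12


@dataclass(frozen=True)
class CameraGeometry:
    """Frequency, coupling medium and retina sampling of the planar camera.

    Parameters
    ----------
    frequency : float
        Operating frequency in Hz.
    eps_water, sigma_water : float
        Relative permittivity and conductivity (S/m) of the coupling medium.
    n_retina : int
        Number of retina samples per transverse axis.
    distance : float
        Distance ``d`` (m) between the observation plane and the retina.
    """

    frequency: float = 2.45e9
    eps_water: float = 73.0
    sigma_water: float = 1.0
    n_retina: int = 64
    distance: float = 0.10

    @property
    def omega(self) -> float:
        return 2.0 * np.pi * self.frequency

    @property
    def k0(self) -> float:
        """Free-space wavenumber (1/m)."""
        return self.omega / C0

    @property
    def k_water(self) -> float:
        """Real-part-convention wavenumber of the coupling medium (~438 1/m)."""
        return self.k0 * np.sqrt(self.eps_water)

    @property
    def k_water_complex(self) -> complex:
        """Lossy wavenumber k0*sqrt(eps' - i sigma/(w eps0)) with Im < 0."""
        eps_c = self.eps_water - 1j * self.eps_imag(self.sigma_water)
        return self.k0 * np.sqrt(eps_c)

    @property
    def eps_water_complex(self) -> complex:
        """Complex relative permittivity eps' - i eps'' of the water."""
        return self.eps_water - 1j * self.eps_imag(self.sigma_water)

    @property
    def wavelength(self) -> float:
        """In-water wavelength 2*pi/k_water (m)."""
        return 2.0 * np.pi / self.k_water

    @property
    def spacing(self) -> float:
        """Retina sample spacing, lambda_water / 4 (m)."""
        return self.wavelength / 4.0

    @property
    def spectral_step(self) -> float:
        """Spectral grid step 2*pi/(n*spacing); equals k_water/16 for n=64."""
        return 2.0 * np.pi / (self.n_retina * self.spacing)

    def eps_imag(self, sigma: float) -> float:
        """Imaginary permittivity eps'' = sigma / (omega * eps0)."""
        return sigma / (self.omega * EPS0)

    def sigma_from_eps_imag(self, eps_imag: float) -> float:
        """Inverse of :meth:`eps_imag`."""
        return eps_imag * self.omega * EPS0

    def complex_permittivity(self, eps_r: float, sigma: float) -> complex:
        """Complex relative permittivity eps' - i*sigma/(w eps0)."""
        return eps_r - 1j * self.eps_imag(sigma)

    def retina_coords(self) -> np.ndarray:
        """Transverse sample coordinates (m), centered, length ``n_retina``.

        Index ``n_retina // 2`` sits exactly on the camera axis.
        """
        n = self.n_retina
        return (np.arange(n) - n // 2) * self.spacing

    def propagation_wavenumber(self, medium: str = "lossless") -> complex:
        """Wavenumber used in propagation kernels.

        ``"lossless"`` is the real-part convention of the imaging formulas
        (the inversion chain assumes it); ``"lossy"`` includes the water
        attenuation (~22 Np/m at 2.45 GHz) and is the physical choice for
        validating kernels against the free-space Weyl integral.
        """
        if medium == "lossless":
            return complex(self.k_water)
        if medium == "lossy":
            return self.k_water_complex
        raise ValueError(f"unknown medium {medium!r}; use 'lossless' or 'lossy'")
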