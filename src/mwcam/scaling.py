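"""Normalization of network inputs/references and calibration of outputs.

Forward direction (training data): a complex image (the backprojected
current map or the reference contrast map) is min-max scaled per real and
imaginary part to [0, 1], transformed to the spectral domain, half-visible
filtered, cropped to 17 x 17 and divided by its maximum modulus over the
active mask — so real and imaginary spectrum values lie in [-1, 1], the
maximum modulus is exactly 1, and phases are untouched.

Backward direction (reconstruction): the network's 17 x 17 contrast
spectrum is re-embedded into the full grid, inverse transformed, calibrated
against the known coupling medium (the mean of the outside-phantom pixels
maps to eps_r = 73, sigma = 1 S/m), rescaled to the positive band
[min|.|, max|.|], and the contour prior finally enforces the exact water
values outside the phantom support.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .geometry import CameraGeometry
from .spectral import (
    CurrentSpectrum,
    SpectralGrid,
    crop_box,
    embed,
    field_spectrum,
    inverse_field_spectrum,
    visible_filter,
)


@dataclass
class ScaleRecord:
    """Traceability record of one image's normalization."""

    re_min: float
    re_max: float
    im_min: float
    im_max: float
    spectral_max: Optional[float] = None


@dataclass
class NormalizedPair:
    """One training sample: input current spectrum and reference contrast
    spectrum, both 17 x 17, masked, with their scaling records."""

    j_norm: np.ndarray
    c_norm: np.ndarray
    mask: np.ndarray
    j_scale: ScaleRecord
    c_scale: ScaleRecord
    contour: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)


@dataclass
class CalibratedMaps:
    """Water-calibrated dielectric maps reconstructed from a network output."""

    eps_cal: np.ndarray
    sigma_cal: np.ndarray
    m_re: float
    m_im: float
    eps_net: Optional[np.ndarray] = None
    sigma_net: Optional[np.ndarray] = None
    contour: Optional[np.ndarray] = None


def minmax_complex(image: np.ndarray):
    """Min-max scale real and imaginary parts independently to [0, 1].

    Returns the scaled complex image and a :class:`ScaleRecord`.  Raises if
    either component is constant (zero denominator).
    """
    re, im = image.real, image.imag
    re_min, re_max = float(re.min()), float(re.max())
    im_min, im_max = float(im.min()), float(im.max())
    if re_max == re_min or im_max == im_min:
        raise ValueError("min-max scaling of a constant component is undefined")
    # scale each part in real arithmetic (complex division rounds differently)
    re_scaled = (re - re_min) / (re_max - re_min)
    im_scaled = (im - im_min) / (im_max - im_min)
    return re_scaled + 1j * im_scaled, ScaleRecord(re_min, re_max, im_min, im_max)


def spectrum_normalize(
    scaled_image: np.ndarray, grid: SpectralGrid, record: ScaleRecord | None = None
) -> CurrentSpectrum:
    """Half-visible-filtered, cropped, max-modulus-normalized spectrum.

    Division by the maximum modulus over the active mask changes only
    magnitudes, never phases; afterwards both the real and imaginary parts
    lie in [-1, 1] and the maximum modulus is exactly 1.
    """
    spec = field_spectrum(scaled_image, grid.geometry)
    filtered = crop_box(visible_filter(spec, grid, fraction=0.5))
    peak = np.abs(filtered.values[filtered.mask]).max()
    if peak == 0.0:
        raise ValueError("cannot normalize an all-zero spectrum")
    if record is not None:
        record.spectral_max = float(peak)
    return CurrentSpectrum(
        filtered.values / peak, filtered.mask, filtered.grid, filtered.offset
    )


def make_normalized_pair(
    j_image: np.ndarray,
    c_image: np.ndarray,
    contour: np.ndarray,
    grid: SpectralGrid,
    meta: dict | None = None,
) -> NormalizedPair:
    """Build the (input, reference) spectra for one sample."""
    j_scaled, j_rec = minmax_complex(j_image)
    c_scaled, c_rec = minmax_complex(c_image)
    j_spec = spectrum_normalize(j_scaled, grid, j_rec)
    c_spec = spectrum_normalize(c_scaled, grid, c_rec)
    return NormalizedPair(
        j_norm=j_spec.values,
        c_norm=c_spec.values,
        mask=j_spec.mask,
        j_scale=j_rec,
        c_scale=c_rec,
        contour=contour,
        meta=meta or {},
    )


def spectrum_to_image(spectrum17: np.ndarray, grid: SpectralGrid) -> np.ndarray:
    """Inverse-transform a 17 x 17 spectrum re-embedded into the full grid."""
    mask = grid.visible_mask(0.5)
    n = grid.n
    lo = n // 2 - (spectrum17.shape[0] - 1) // 2
    cropped_mask = mask[lo : lo + spectrum17.shape[0], lo : lo + spectrum17.shape[1]]
    cs = CurrentSpectrum(
        np.where(cropped_mask, spectrum17, 0.0), cropped_mask, grid, offset=lo
    )
    return inverse_field_spectrum(embed(cs).values, grid.geometry)


def water_calibrate(
    c_net_image: np.ndarray,
    contour_mask: np.ndarray,
    geometry: CameraGeometry | None = None,
) -> CalibratedMaps:
    """Calibrate a reconstructed contrast image against the coupling medium.

    With M_re, M_im the means of the real/imaginary parts over the
    outside-phantom pixels, ``eps_cal = (Re(C_net)/M_re) * eps_water`` and
    ``sigma_cal = (Im(C_net)/M_im) * sigma_water`` — the water region maps
    to (73, 1 S/m) by construction, and a global rescaling of C_net leaves
    the calibrated maps unchanged.
    """
    geometry = geometry or CameraGeometry()
    outside = ~np.asarray(contour_mask, dtype=bool)
    if not outside.any():
        raise ValueError("calibration requires at least one outside-phantom pixel")
    m_re = float(c_net_image.real[outside].mean())
    m_im = float(c_net_image.imag[outside].mean())
    if m_re == 0.0 or m_im == 0.0:
        raise ValueError("zero water mean; calibration undefined")
    eps_cal = (c_net_image.real / m_re) * geometry.eps_water
    sigma_cal = (c_net_image.imag / m_im) * geometry.sigma_water
    return CalibratedMaps(eps_cal, sigma_cal, m_re, m_im)


def _positive_rescale_eps(m: np.ndarray) -> np.ndarray:
    lo, hi = np.abs(m).min(), np.abs(m).max()
    if m.max() == m.min():
        raise ValueError("constant map cannot be rescaled")
    return lo + (hi - lo) * (m - m.min()) / (m.max() - m.min())


def _positive_rescale_sigma(m: np.ndarray) -> np.ndarray:
    # reversed min/max structure, implemented exactly as specified
    lo, hi = np.abs(m).min(), np.abs(m).max()
    if m.max() == m.min():
        raise ValueError("constant map cannot be rescaled")
    return hi + (lo - hi) * (m - m.min()) / (m.max() - m.min())


def rescale_properties(maps: CalibratedMaps) -> CalibratedMaps:
    """Second min-max pass enforcing positive reconstructed properties.

    ``eps_net`` spans [min|eps_cal|, max|eps_cal|]; ``sigma_net`` uses the
    mirrored affine form, spanning the same positive band of |sigma_cal|.
    Both outputs are therefore non-negative everywhere.
    """
    maps.eps_net = _positive_rescale_eps(maps.eps_cal)
    maps.sigma_net = _positive_rescale_sigma(maps.sigma_cal)
    return maps


def apply_contour_prior(
    maps: CalibratedMaps,
    contour_mask: np.ndarray,
    geometry: CameraGeometry | None = None,
) -> CalibratedMaps:
    """Enforce the exact water values outside the phantom contour."""
    geometry = geometry or CameraGeometry()
    if maps.eps_net is None or maps.sigma_net is None:
        rescale_properties(maps)
    outside = ~np.asarray(contour_mask, dtype=bool)
    eps = maps.eps_net.copy()
    sigma = maps.sigma_net.copy()
    eps[outside] = geometry.eps_water
    sigma[outside] = geometry.sigma_water
    maps.eps_net, maps.sigma_net = eps, sigma
    maps.contour = np.asarray(contour_mask, dtype=bool)
    return maps


def reference_maps(
    contrast: np.ndarray,
    contour_mask: np.ndarray,
    geometry: CameraGeometry | None = None,
):
    """Ground-truth (eps_r, sigma) maps from a reference contrast slice.

    Inverts the contrast definition: eps' = Re(C) + eps'_water and
    sigma = sigma_water - Im(C) * omega * eps0; water values outside the
    contour.
    """
    geometry = geometry or CameraGeometry()
    inside = np.asarray(contour_mask, dtype=bool)
    eps = np.where(inside, contrast.real + geometry.eps_water, geometry.eps_water)
    sigma = np.where(
        inside,
        geometry.sigma_water - geometry.sigma_from_eps_imag(contrast.imag),
        geometry.sigma_water,
    )
    return eps, sigma


def reconstruct_maps(
    c_net_spectrum: np.ndarray,
    contour_mask: np.ndarray,
    grid: SpectralGrid,
) -> CalibratedMaps:
    """Full denormalization chain: 17 x 17 spectrum -> (eps_r, sigma) maps."""
    c_img = spectrum_to_image(c_net_spectrum, grid)
    maps = water_calibrate(c_img, contour_mask, grid.geometry)
    rescale_properties(maps)
    return apply_contour_prior(maps, contour_mask, grid.geometry)
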