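"""Reconstruction-quality metrics.

SSIM uses the standard Gaussian-window convention (window 11, sigma 1.5,
k1=0.01, k2=0.03) with the data range taken as max - min of the reference;
PSNR is 10*log10(range^2 / MSE) with the same range convention.  Metrics
are reported on the real and imaginary parts of the 17 x 17 spectra, for
both the network input (j_norm vs C_norm) and output (C_net vs C_norm),
per batch of three samples and as dataset means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from skimage.metrics import structural_similarity

from .scaling import NormalizedPair, reconstruct_maps, reference_maps
from .spectral import SpectralGrid
from .unet.training import UNetPair, infer


def ssim(a: np.ndarray, b: np.ndarray) -> float:
    """Mean structural similarity of ``a`` against reference ``b``.

    Gaussian window (size 11, sigma 1.5), stability constants k1=0.01,
    k2=0.03, data range = max - min of the reference.  Raises on a constant
    reference (zero dynamic range).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("SSIM requires identical shapes")
    rng = b.max() - b.min()
    if rng == 0.0:
        raise ValueError("SSIM undefined for a constant reference")
    return float(
        structural_similarity(
            b,
            a,
            win_size=11,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            K1=0.01,
            K2=0.03,
            data_range=rng,
        )
    )


def psnr(a: np.ndarray, b: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB, range = max - min of the reference.

    Identical inputs yield +inf (flagged by the caller as a perfect match).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("PSNR requires identical shapes")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return math.inf
    rng = b.max() - b.min()
    return 10.0 * math.log10(rng * rng / mse)


@dataclass
class MetricReport:
    """Per-batch curves and dataset means for input and output quality."""

    batch_ssim: Dict[str, List[float]] = field(default_factory=dict)
    batch_psnr: Dict[str, List[float]] = field(default_factory=dict)
    mean_ssim: Dict[str, float] = field(default_factory=dict)
    mean_psnr: Dict[str, float] = field(default_factory=dict)
    n_full_batches: int = 0
    remainder: int = 0
    snr_db: Optional[float] = None

    KEYS = (
        "input_real",
        "input_imag",
        "output_real",
        "output_imag",
    )


def evaluate_dataset(
    pair: UNetPair,
    dataset: Sequence[NormalizedPair],
    batch_size: int = 3,
    snr_db: Optional[float] = None,
) -> MetricReport:
    """Evaluate SSIM/PSNR per batch on spectra, input vs output.

    Curves cover the full batches only (the dataset mean also includes the
    remainder samples); 359 samples at batch 3 give 119 curve points.
    """
    if len(dataset) == 0:
        raise ValueError("empty evaluation dataset")
    report = MetricReport(snr_db=snr_db)
    per_sample: Dict[str, List[float]] = {k: [] for k in MetricReport.KEYS}
    per_sample_psnr: Dict[str, List[float]] = {k: [] for k in MetricReport.KEYS}
    for sample in dataset:
        out = infer(pair, sample.j_norm)
        for part, take in (("real", np.real), ("imag", np.imag)):
            ref = take(sample.c_norm)
            per_sample[f"input_{part}"].append(ssim(take(sample.j_norm), ref))
            per_sample[f"output_{part}"].append(ssim(take(out), ref))
            per_sample_psnr[f"input_{part}"].append(psnr(take(sample.j_norm), ref))
            per_sample_psnr[f"output_{part}"].append(psnr(take(out), ref))

    _fill_report(report, per_sample, per_sample_psnr, len(dataset), batch_size)
    return report


def evaluate_reconstructions(
    pair: UNetPair,
    samples,
    grid: SpectralGrid,
    batch_size: int = 3,
    snr_db: Optional[float] = None,
):
    """Image-domain quality: SSIM of calibrated maps against the references.

    For each dataset sample the network output is denormalized into
    permittivity and conductivity maps (water calibration, positive rescale,
    contour prior) and compared with the maps implied by the reference
    contrast slice.  Returns a report with keys ``output_eps`` /
    ``output_sigma``.
    """
    if len(samples) == 0:
        raise ValueError("empty evaluation dataset")
    report = MetricReport(snr_db=snr_db)
    per_sample = {"output_eps": [], "output_sigma": []}
    per_psnr = {"output_eps": [], "output_sigma": []}
    for sample in samples:
        c_net = infer(pair, sample.pair.j_norm)
        maps = reconstruct_maps(c_net, sample.contour, grid)
        eps_ref, sigma_ref = reference_maps(
            sample.contrast, sample.contour, grid.geometry
        )
        per_sample["output_eps"].append(ssim(maps.eps_net, eps_ref))
        per_sample["output_sigma"].append(ssim(maps.sigma_net, sigma_ref))
        per_psnr["output_eps"].append(psnr(maps.eps_net, eps_ref))
        per_psnr["output_sigma"].append(psnr(maps.sigma_net, sigma_ref))
    report.KEYS = ("output_eps", "output_sigma")  # type: ignore[misc]
    _fill_report(report, per_sample, per_psnr, len(samples), batch_size)
    return report


def _fill_report(report, per_sample, per_sample_psnr, n_items, batch_size):
    n_full = n_items // batch_size
    report.n_full_batches = n_full
    report.remainder = n_items - n_full * batch_size
    for key in per_sample:
        vals = np.asarray(per_sample[key])
        pvals = np.asarray(per_sample_psnr[key])
        report.batch_ssim[key] = [
            float(vals[i * batch_size : (i + 1) * batch_size].mean())
            for i in range(n_full)
        ]
        report.batch_psnr[key] = [
            float(pvals[i * batch_size : (i + 1) * batch_size].mean())
            for i in range(n_full)
        ]
        report.mean_ssim[key] = float(vals.mean())
        finite = pvals[np.isfinite(pvals)]
        report.mean_psnr[key] = float(finite.mean()) if finite.size else math.inf
    return report
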