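"""End-to-end pipeline: generate -> simulate -> spectra -> train -> evaluate.

Every stochastic choice (tissue jitter, dataset shuffle, noise, weight
initialization) flows from the seeds in the configuration, so a rerun with
the same configuration reproduces every artifact.  Stages write their
artifacts to the output directory and are skipped when the artifact already
exists (resumable; pass ``force=True`` to recompute).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .dataset import Sample, load_dataset, save_dataset
from .evaluate import MetricReport, evaluate_dataset
from .forward import RetinaField, add_awgn, born_forward
from .geometry import CameraGeometry
from .phantoms import (
    GridSpec,
    PhantomConfig,
    TissueDielectrics,
    build_phantom,
    contrast_slice,
    enumerate_configs,
    enumerate_heldout_configs,
    jitter_dielectrics,
    split_dataset,
)
from .scaling import make_normalized_pair
from .spectral import (
    SpectralGrid,
    backproject,
    crop_box,
    diffraction_map,
    field_spectrum,
    visible_filter,
)
from .unet import TrainState, UNetPair, UNetSpec, load_pair, save_pair, train

log = logging.getLogger("mwcam")


@dataclass
class PipelineConfig:
    """Everything a full run needs; see ``examples/`` for small presets."""

    n_rotations: int = 16
    include_mirrors: bool = True
    include_tumors: bool = True
    jitter_amplitude: float = 0.05
    jitter_base_seed: int = 20_000
    grid_ny: int = 27
    train_fraction: float = 0.8
    shuffle_seed: int = 7
    snr_db: Optional[float] = None
    noise_seed: int = 5
    features: Tuple[int, int, int, int] = (32, 64, 128, 256)
    bottleneck: str = "full"
    epochs: int = 30
    batch_size: int = 3
    lr: float = 1e-3
    betas: Tuple[float, float] = (0.9, 0.999)
    train_seed: int = 11
    heldout_rotations: int = 16

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        cfg = cls(**raw)
        return replace(
            cfg,
            features=tuple(cfg.features),
            betas=tuple(cfg.betas),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(
                {
                    k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in asdict(self).items()
                },
                f,
                sort_keys=False,
            )


def simulate_sample(
    config: PhantomConfig,
    geometry: CameraGeometry,
    grid: GridSpec,
    nominal: TissueDielectrics | None = None,
    jitter_amplitude: float = 0.05,
    snr_db: Optional[float] = None,
    noise_rng=None,
    split: str = "",
) -> Sample:
    """Run the whole per-sample chain.

    Jittered dielectrics -> voxel phantom -> Born retina field (optionally
    noisy) -> current spectrum via the diffraction theorem -> half-visible
    filtering -> backprojected current image -> normalized input spectrum,
    paired with the normalized reference contrast spectrum of the
    observation slice.
    """
    nominal = nominal or TissueDielectrics()
    diel = jitter_dielectrics(nominal, config.jitter_seed, jitter_amplitude)
    phantom = build_phantom(config, diel, grid, geometry)
    retina = born_forward(phantom, geometry)
    if snr_db is not None:
        retina = add_awgn(retina, snr_db, noise_rng)
    sgrid = SpectralGrid(geometry)
    e_hat = field_spectrum(retina.field, geometry)
    j_hat = diffraction_map(e_hat, sgrid)
    j_half = visible_filter(j_hat, fraction=0.5)
    j_image = backproject(j_half)
    cmap = contrast_slice(phantom, 0.0)
    pair = make_normalized_pair(j_image, cmap.values, cmap.mask, sgrid)
    iy = len(grid.y_coords()) // 2
    return Sample(
        config=config,
        field=retina.field,
        pair=pair,
        contrast=cmap.values,
        contour=cmap.mask,
        labels_slice=phantom.labels[:, iy, :],
        split=split,
        snr_db=snr_db,
    )


def generate_samples(
    cfg: PipelineConfig, geometry: CameraGeometry | None = None
) -> Tuple[List[Sample], CameraGeometry]:
    """Enumerate, split and simulate the whole database."""
    geometry = geometry or CameraGeometry()
    grid = GridSpec(
        n_transverse=geometry.n_retina, ny=cfg.grid_ny, spacing=geometry.spacing
    )
    configs = enumerate_configs(
        include_tumors=cfg.include_tumors,
        include_mirrors=cfg.include_mirrors,
        n_rotations=cfg.n_rotations,
        jitter_base_seed=cfg.jitter_base_seed,
    )
    train_cfgs, val_cfgs, _ = split_dataset(
        configs, cfg.train_fraction, cfg.shuffle_seed
    )
    test_cfgs = enumerate_heldout_configs(n_rotations=cfg.heldout_rotations)
    noise_rng = np.random.default_rng(cfg.noise_seed)
    samples: List[Sample] = []
    for split, cfgs in (("train", train_cfgs), ("val", val_cfgs), ("test", test_cfgs)):
        for i, c in enumerate(cfgs):
            samples.append(
                simulate_sample(
                    c,
                    geometry,
                    grid,
                    jitter_amplitude=cfg.jitter_amplitude,
                    snr_db=cfg.snr_db,
                    noise_rng=noise_rng,
                    split=split,
                )
            )
        log.info("simulated %d %s samples", len(cfgs), split)
    return samples, geometry


def train_on_samples(
    cfg: PipelineConfig, samples: Sequence[Sample], geometry: CameraGeometry
) -> Tuple[UNetPair, TrainState]:
    sgrid = SpectralGrid(geometry)
    mask17 = crop_box(
        visible_filter(np.ones((geometry.n_retina,) * 2, complex), sgrid, 0.5)
    ).mask
    spec = UNetSpec(features=cfg.features, bottleneck=cfg.bottleneck)
    pair = UNetPair(spec, mask17, seed=cfg.train_seed)
    state = TrainState(
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        lr=cfg.lr,
        betas=cfg.betas,
        seed=cfg.train_seed,
    )
    train_set = [s.pair for s in samples if s.split == "train"]
    val_set = [s.pair for s in samples if s.split == "val"]
    train(pair, train_set, state, validation=val_set)
    return pair, state


def write_train_log(path, state: TrainState) -> None:
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["epoch", "train_real", "train_imag", "val_real", "val_imag"])
        for i in range(len(state.train_loss["real"])):
            row = [i + 1, state.train_loss["real"][i], state.train_loss["imag"][i]]
            row += [
                state.val_loss[p][i] if i < len(state.val_loss[p]) else ""
                for p in ("real", "imag")
            ]
            w.writerow(row)


def write_metrics_csv(path, report: MetricReport) -> None:
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["batch"] + [f"ssim_{k}" for k in report.KEYS])
        for i in range(report.n_full_batches):
            w.writerow([i] + [report.batch_ssim[k][i] for k in report.KEYS])
        w.writerow(["mean"] + [report.mean_ssim[k] for k in report.KEYS])


def run_pipeline(cfg: PipelineConfig, out_dir, force: bool = False) -> dict:
    """Execute every stage, reusing existing artifacts unless ``force``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")

    dataset_path = out / "dataset.h5"
    if force or not dataset_path.exists():
        samples, geometry = generate_samples(cfg)
        save_dataset(dataset_path, samples, geometry)
        log.info("wrote %s", dataset_path)
    samples, geometry = load_dataset(dataset_path)

    ckpt_path = out / "unet_pair.npz"
    log_path = out / "train_log.csv"
    if force or not ckpt_path.exists():
        pair, state = train_on_samples(cfg, samples, geometry)
        save_pair(ckpt_path, pair, state)
        write_train_log(log_path, state)
        log.info("wrote %s", ckpt_path)
    pair = load_pair(ckpt_path)

    metrics_path = out / "metrics_val.csv"
    report = evaluate_dataset(
        pair, [s.pair for s in samples if s.split == "val"], cfg.batch_size
    )
    write_metrics_csv(metrics_path, report)
    test_report = evaluate_dataset(
        pair, [s.pair for s in samples if s.split == "test"], cfg.batch_size
    )
    write_metrics_csv(out / "metrics_test.csv", test_report)
    return {
        "dataset": dataset_path,
        "checkpoint": ckpt_path,
        "val_report": report,
        "test_report": test_report,
    }
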