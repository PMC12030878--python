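"""Training of the U-NET pair on (current spectrum -> contrast spectrum).

One network learns the real part of the transformation, its twin the
imaginary part.  Both are optimized with Adam (lr 0.001, betas 0.9/0.999)
against the weighted mean absolute percentage error, in batches of three
17 x 17 maps; the half-visible mask is applied to both network input and
output before the loss, so pixels outside the 197-pixel support contribute
nothing to either sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ..scaling import NormalizedPair
from .layers import Adam
from .network import UNet, UNetSpec, build_unet


def wmape_loss(predicted: np.ndarray, reference: np.ndarray):
    """WMAPE = sum |pred - ref| / sum |ref| over all entries.

    Returns ``(loss, grad)`` where ``grad`` is d(loss)/d(pred).  Raises if
    the reference is identically zero.
    """
    if predicted.shape != reference.shape:
        raise ValueError("prediction and reference shapes differ")
    denom = np.abs(reference).sum()
    if denom == 0.0:
        raise ValueError("WMAPE undefined for an identically zero reference")
    diff = predicted - reference
    loss = np.abs(diff).sum() / denom
    grad = np.sign(diff) / denom
    return float(loss), grad


@dataclass
class TrainState:
    """Optimizer hyperparameters and per-epoch loss history."""

    epochs: int = 30
    batch_size: int = 3
    lr: float = 1e-3
    betas: Tuple[float, float] = (0.9, 0.999)
    seed: int = 0
    train_loss: Dict[str, List[float]] = field(
        default_factory=lambda: {"real": [], "imag": []}
    )
    val_loss: Dict[str, List[float]] = field(
        default_factory=lambda: {"real": [], "imag": []}
    )


class UNetPair:
    """The real-part and imaginary-part networks plus the shared mask."""

    def __init__(self, spec: UNetSpec, mask: np.ndarray, seed: int = 0):
        self.spec = spec
        self.mask = np.asarray(mask, dtype=bool)
        self.net_real = build_unet(spec, seed=seed)
        self.net_imag = build_unet(spec, seed=seed + 1)

    def network(self, part: str) -> UNet:
        return self.net_real if part == "real" else self.net_imag


def _part_batches(
    dataset: Sequence[NormalizedPair], part: str, mask: np.ndarray
):
    take = (lambda a: a.real) if part == "real" else (lambda a: a.imag)
    x = np.stack([take(s.j_norm) * mask for s in dataset])[:, None]
    y = np.stack([take(s.c_norm) * mask for s in dataset])[:, None]
    return x, y


def n_batches(n_items: int, batch_size: int) -> int:
    """Number of batches covering ``n_items`` (last one possibly partial)."""
    return -(-n_items // batch_size)


def train(
    pair: UNetPair,
    dataset: Sequence[NormalizedPair],
    state: TrainState,
    validation: Optional[Sequence[NormalizedPair]] = None,
) -> TrainState:
    """Train both networks; record mean WMAPE per epoch (train and val).

    Deterministic for fixed seeds: the epoch shuffling derives from
    ``state.seed`` and the weight initialization from the pair's seed.
    """
    if len(dataset) == 0:
        raise ValueError("empty training dataset")
    mask = pair.mask
    for part in ("real", "imag"):
        net = pair.network(part)
        opt = Adam(net.params(), lr=state.lr, betas=state.betas)
        x_all, y_all = _part_batches(dataset, part, mask)
        if validation is not None and len(validation):
            xv, yv = _part_batches(validation, part, mask)
        else:
            xv = yv = None
        rng = np.random.default_rng(state.seed + (0 if part == "real" else 1))
        for _ in range(state.epochs):
            order = rng.permutation(len(dataset))
            losses = []
            for start in range(0, len(dataset), state.batch_size):
                idx = order[start : start + state.batch_size]
                xb, yb = x_all[idx], y_all[idx]
                opt.zero_grad()
                out = net.forward(xb, training=True) * mask
                loss, grad = wmape_loss(out, yb)
                if not np.isfinite(loss):
                    raise RuntimeError(f"non-finite {part} loss encountered")
                net.backward(grad * mask)
                opt.step()
                losses.append(loss)
            state.train_loss[part].append(float(np.mean(losses)))
            if xv is not None:
                out = net.forward(xv, training=False) * mask
                vloss, _ = wmape_loss(out, yv)
                state.val_loss[part].append(float(vloss))
    return state


def infer(pair: UNetPair, j_norm: np.ndarray) -> np.ndarray:
    """Run the pair on a normalized, filtered, cropped input spectrum.

    Raises if the input carries energy outside the half-visible mask; the
    mask is re-applied to the complex output.
    """
    j_norm = np.asarray(j_norm)
    if j_norm.shape != pair.mask.shape:
        raise ValueError("input shape does not match the spectral mask")
    if np.any(np.abs(j_norm[~pair.mask]) > 0):
        raise ValueError("input has active pixels outside the half-visible mask")
    xr = (j_norm.real * pair.mask)[None, None]
    xi = (j_norm.imag * pair.mask)[None, None]
    out_r = pair.net_real.forward(xr, training=False)[0, 0]
    out_i = pair.net_imag.forward(xi, training=False)[0, 0]
    return (out_r + 1j * out_i) * pair.mask


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------


def save_pair(path, pair: UNetPair, state: Optional[TrainState] = None) -> None:
    """Serialize spec, mask, weights and running statistics to an NPZ file."""
    payload = {
        "features": np.asarray(pair.spec.features),
        "kernels": np.asarray(pair.spec.kernels),
        "paddings": np.asarray(pair.spec.paddings),
        "dec_paddings": np.asarray(pair.spec.dec_paddings),
        "in_size": np.asarray(pair.spec.in_size),
        "bottleneck": np.asarray(pair.spec.bottleneck),
        "net_dtype": np.asarray(pair.spec.dtype),
        "mask": pair.mask,
    }
    for tag, net in (("real", pair.net_real), ("imag", pair.net_imag)):
        for i, arr in enumerate(net.state_arrays()):
            payload[f"{tag}_{i:04d}"] = arr
    if state is not None:
        for part in ("real", "imag"):
            payload[f"train_loss_{part}"] = np.asarray(state.train_loss[part])
            payload[f"val_loss_{part}"] = np.asarray(state.val_loss[part])
    np.savez_compressed(path, **payload)


def load_pair(path) -> UNetPair:
    with np.load(path, allow_pickle=False) as data:
        spec = UNetSpec(
            in_size=int(data["in_size"]),
            features=tuple(int(v) for v in data["features"]),
            kernels=tuple(int(v) for v in data["kernels"]),
            paddings=tuple(int(v) for v in data["paddings"]),
            dec_paddings=tuple(int(v) for v in data["dec_paddings"]),
            bottleneck=str(data["bottleneck"]),
            dtype=str(data["net_dtype"]) if "net_dtype" in data else "float64",
        )
        pair = UNetPair(spec, data["mask"])
        for tag, net in (("real", pair.net_real), ("imag", pair.net_imag)):
            for i, arr in enumerate(net.state_arrays()):
                arr[...] = data[f"{tag}_{i:04d}"]
    return pair
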