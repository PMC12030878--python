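"""Spectrum-translation U-NET.

A compact encoder-decoder without pooling: four convolutions with shrinking
kernels (9/7/5/3, paddings 2/2/1/0) compress the 17 x 17 input map to 7 x 7
while growing the features to 256; a dense linear bottleneck bridges to the
decoder, whose four k=3 convolutions (paddings 2/2/2/3) restore 17 x 17,
each consuming the channel-concatenation of the previous output with the
same-size encoder output.  Batch normalization precedes each convolution,
followed by ReLU (omitted before the very first convolution, whose inputs
are already signed values in [-1, 1]); a final 1x1 convolution projects to
one channel.

Spatial arithmetic out = in - k + 1 + 2p is asserted at build time:
17 -> 13 -> 11 -> 9 -> 7 (bottleneck) -> 9 -> 11 -> 13 -> 17.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .layers import BatchNorm2d, Conv2d, Linear, Param, ReLU


@dataclass(frozen=True)
class UNetSpec:
    """Architecture description of one network of the pair."""

    in_size: int = 17
    features: Tuple[int, int, int, int] = (32, 64, 128, 256)
    kernels: Tuple[int, int, int, int] = (9, 7, 5, 3)
    paddings: Tuple[int, int, int, int] = (2, 2, 1, 0)
    dec_kernel: int = 3
    dec_paddings: Tuple[int, int, int, int] = (2, 2, 2, 3)
    bottleneck: str = "full"  # "full" (flatten->dense) or "channelwise"
    dtype: str = "float64"  # "float32" halves memory traffic for desk-scale runs

    def encoder_sizes(self) -> List[int]:
        sizes = []
        s = self.in_size
        for step, (k, p) in enumerate(zip(self.kernels, self.paddings), start=1):
            s = s - k + 1 + 2 * p
            if s <= 0:
                raise ValueError(f"compression step {step} collapses the map (size {s})")
            sizes.append(s)
        return sizes

    def decoder_sizes(self) -> List[int]:
        enc = self.encoder_sizes()
        sizes = []
        s = enc[-1]
        for step, p in enumerate(self.dec_paddings, start=6):
            s = s - self.dec_kernel + 1 + 2 * p
            sizes.append(s)
        return sizes

    def validate(self) -> None:
        enc = self.encoder_sizes()
        dec = self.decoder_sizes()
        if dec[-1] != self.in_size:
            raise ValueError(
                f"decompression step 9 emits {dec[-1]}x{dec[-1]}, "
                f"expected {self.in_size}x{self.in_size}"
            )
        # skip connections concatenate same-size maps
        skips = list(zip([enc[-1]] + dec[:-1], enc[::-1]))
        for step, (a, b) in enumerate(skips, start=6):
            if a != b:
                raise ValueError(
                    f"skip connection at step {step} mismatches: {a} vs {b}"
                )


class UNet:
    """One network of the pair: real 17x17 map in, real 17x17 map out."""

    def __init__(self, spec: UNetSpec, seed: int = 0):
        spec.validate()
        self.spec = spec
        self.dtype = np.dtype(spec.dtype)
        dt = self.dtype
        rng = np.random.default_rng(seed)
        f1, f2, f3, f4 = spec.features
        k, kp = spec.kernels, spec.paddings
        dk, dp = spec.dec_kernel, spec.dec_paddings

        self.enc = [
            [BatchNorm2d(1, dtype=dt), Conv2d(1, f1, k[0], kp[0], rng, dt)],
            [BatchNorm2d(f1, dtype=dt), ReLU(), Conv2d(f1, f2, k[1], kp[1], rng, dt)],
            [BatchNorm2d(f2, dtype=dt), ReLU(), Conv2d(f2, f3, k[2], kp[2], rng, dt)],
            [BatchNorm2d(f3, dtype=dt), ReLU(), Conv2d(f3, f4, k[3], kp[3], rng, dt)],
        ]
        s_bottom = spec.encoder_sizes()[-1]
        self._bottom = (f4, s_bottom)
        if spec.bottleneck == "full":
            self.linear = Linear(
                f4 * s_bottom * s_bottom, f4 * s_bottom * s_bottom, rng, dt
            )
        elif spec.bottleneck == "channelwise":
            self.linear = Linear(s_bottom * s_bottom, s_bottom * s_bottom, rng, dt)
        else:
            raise ValueError("bottleneck must be 'full' or 'channelwise'")
        self.dec = [
            [BatchNorm2d(2 * f4, dtype=dt), ReLU(), Conv2d(2 * f4, f3, dk, dp[0], rng, dt)],
            [BatchNorm2d(2 * f3, dtype=dt), ReLU(), Conv2d(2 * f3, f2, dk, dp[1], rng, dt)],
            [BatchNorm2d(2 * f2, dtype=dt), ReLU(), Conv2d(2 * f2, f1, dk, dp[2], rng, dt)],
            [BatchNorm2d(2 * f1, dtype=dt), ReLU(), Conv2d(2 * f1, f1, dk, dp[3], rng, dt)],
        ]
        self.head = Conv2d(f1, 1, 1, 0, rng, dt)

    # -- parameter plumbing -------------------------------------------------
    def params(self) -> List[Param]:
        out: List[Param] = []
        for block in self.enc + self.dec:
            for layer in block:
                out.extend(layer.params())
        out.extend(self.linear.params())
        out.extend(self.head.params())
        return out

    def state_arrays(self) -> List[np.ndarray]:
        """All learnable values plus batch-norm running statistics."""
        arrays = [p.value for p in self.params()]
        for block in self.enc + self.dec:
            for layer in block:
                if isinstance(layer, BatchNorm2d):
                    arrays.extend([layer.running_mean, layer.running_var])
        return arrays

    # -- forward / backward -------------------------------------------------
    @staticmethod
    def _run_block(block, x, training):
        for layer in block:
            x = layer.forward(x, training)
        return x

    @staticmethod
    def _back_block(block, grad):
        for layer in reversed(block):
            grad = layer.backward(grad)
        return grad

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != 1 or x.shape[2] != self.spec.in_size:
            raise ValueError(
                f"expected (N, 1, {self.spec.in_size}, {self.spec.in_size}) input"
            )
        skips = []
        h = np.ascontiguousarray(x, dtype=self.dtype)
        for block in self.enc:
            h = self._run_block(block, h, training)
            skips.append(h)
        n = h.shape[0]
        f4, s = self._bottom
        if self.spec.bottleneck == "full":
            z = self.linear.forward(h.reshape(n, -1), training).reshape(n, f4, s, s)
        else:
            z = self.linear.forward(h.reshape(n * f4, s * s), training).reshape(
                n, f4, s, s
            )
        self._skip_channels = []
        for block, skip in zip(self.dec, reversed(skips)):
            z = np.concatenate([z, skip], axis=1)
            self._skip_channels.append(skip.shape[1])
            z = self._run_block(block, z, training)
        return self.head.forward(z, training)

    def backward(self, grad_out: np.ndarray) -> None:
        """Accumulate parameter gradients for a forward pass just executed."""
        g = self.head.backward(grad_out)
        skip_grads = []
        for block, c_skip in zip(reversed(self.dec), reversed(self._skip_channels)):
            g = self._back_block(block, g)
            g, g_skip = g[:, :-c_skip], g[:, -c_skip:]
            skip_grads.append(g_skip)
        # reversed(dec) visits the e1-skip first, so skip_grads is ordered e1..e4
        n = g.shape[0]
        f4, s = self._bottom
        if self.spec.bottleneck == "full":
            g = self.linear.backward(g.reshape(n, -1)).reshape(n, f4, s, s)
        else:
            g = self.linear.backward(g.reshape(n * f4, s * s)).reshape(n, f4, s, s)
        g = g + skip_grads[3]
        for idx in (3, 2, 1, 0):
            g = self._back_block(self.enc[idx], g)
            if idx > 0:
                g = g + skip_grads[idx - 1]

    def intermediate_sizes(self) -> List[int]:
        """Spatial sizes emitted by steps 1-4, the bottleneck, and steps 6-9."""
        enc = self.spec.encoder_sizes()
        return enc + [enc[-1]] + self.spec.decoder_sizes()


def build_unet(spec: UNetSpec, seed: int = 0) -> UNet:
    """Construct a seeded network; raises if the size arithmetic breaks."""
    return UNet(spec, seed)
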