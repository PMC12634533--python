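"""Fixed Sobel gradient filter bank and its SAME-padded convolution.

The network's first layer is not learned: it is a stack of 3x3 Sobel kernels
with coefficients scaled to +-0.1/+-0.2, estimating the horizontal (Gx, along
the time axis) and vertical (Gy, across channels) gradients of a channels x
time EEG "image".  The horizontal/vertical pair is replicated ``nf`` times and
concatenated, so a bank built with ``nf`` replications exposes ``2 * nf``
output channels, alternating Gx, Gy.

Both kernels sum to zero, so constant inputs are annihilated and the layer
responds only to local signal structure (edges / gradients).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._conv import xcorr2d

#: Horizontal gradient kernel (responds to change along the time axis).
GX = np.array(
    [[-0.1, 0.0, 0.1],
     [-0.2, 0.0, 0.2],
     [-0.1, 0.0, 0.1]]
)

#: Vertical gradient kernel (responds to change across electrode rows).
GY = GX.T.copy()


@dataclass(frozen=True)
class FilterBank:
    """Ordered stack of 3x3 Sobel kernels, alternating Gx, Gy."""

    kernels: np.ndarray  # (n_out, 3, 3)
    nf: int

    @property
    def n_out(self) -> int:
        return 2 * self.nf

    def conv_weights(self, c_in: int = 1, dtype=np.float64) -> np.ndarray:
        """Bank as (3, 3, c_in, n_out) conv weights.

        For multichannel input each kernel is applied to every feature channel
        and the responses are summed (the standard convolution contract).
        """
        w = np.empty((3, 3, c_in, self.n_out), dtype=dtype)
        for o in range(self.n_out):
            w[:, :, :, o] = self.kernels[o][:, :, None]
        return w


@dataclass
class EpochBatch:
    """A batch of epochs as a (B, H, W, C) tensor; H=channels, W=samples."""

    values: np.ndarray
    sampling_rate: float = 256.0

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim == 3:  # (B, H, W) -> single feature channel
            self.values = self.values[..., None]
        if self.values.ndim != 4:
            raise ValueError("EpochBatch values must be (B, H, W) or (B, H, W, C)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("EpochBatch contains non-finite values")


@dataclass
class GradientMap:
    """Sobel layer output: (B, H, W, n_out), same spatial size as the input."""

    values: np.ndarray


def build_filter_bank(nf: int) -> FilterBank:
    """Build the fixed Sobel bank with ``nf`` Gx/Gy replications (2*nf kernels)."""
    if not isinstance(nf, (int, np.integer)) or isinstance(nf, bool):
        raise TypeError(f"nf must be an integer, got {type(nf).__name__}")
    if nf < 1:
        raise ValueError(f"nf must be >= 1, got {nf}")
    kernels = np.stack([GX if i % 2 == 0 else GY for i in range(2 * nf)])
    return FilterBank(kernels=kernels, nf=int(nf))


def sobel_forward(x, bank: FilterBank) -> GradientMap:
    """Apply the bank as a stride-1, SAME (zero-padded) 2-D cross-correlation.

    Output spatial dimensions equal the input's; channel ``o`` of the output is
    the response of kernel ``o`` summed over the input's feature channels.
    """
    batch = x if isinstance(x, EpochBatch) else EpochBatch(np.asarray(x))
    v = batch.values
    if v.dtype.kind != "f":
        v = v.astype(np.float64)
    _, h, w, c = v.shape
    if h < 3 or w < 3:
        raise ValueError(f"spatial dims must be >= 3x3 for the Sobel kernels, got {h}x{w}")
    weights = bank.conv_weights(c_in=c, dtype=v.dtype if v.dtype.kind == "f" else np.float64)
    out = xcorr2d(v.astype(weights.dtype, copy=False), weights, pad=(1, 1))
    return GradientMap(values=out)
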