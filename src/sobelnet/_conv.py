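"""Batched 2-D cross-correlation primitives (im2col + BLAS matmul).

These back both the fixed Sobel layer and the trainable convolutional block.
Layout convention throughout: activations are (B, H, W, C), weights are
(kh, kw, C_in, C_out).  "Cross-correlation" means no kernel flip, the usual
deep-learning convention.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

# im2col buffers are chunked over the batch axis so a single call never
# materialises more than ~64 MB of patch matrix.
_CHUNK_BYTES = 64 * 2**20


def _batch_chunks(b: int, per_item_bytes: int):
    step = max(1, _CHUNK_BYTES // max(1, per_item_bytes))
    for lo in range(0, b, step):
        yield lo, min(b, lo + step)


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(B, H, W, C) -> (B * Ho * Wo, kh * kw * C) patch matrix."""
    b = x.shape[0]
    # windows: (B, Ho, Wo, C, kh, kw) -> (B, Ho, Wo, kh, kw, C)
    win = sliding_window_view(x, (kh, kw), axis=(1, 2))
    win = win.transpose(0, 1, 2, 4, 5, 3)
    return np.ascontiguousarray(win).reshape(b * win.shape[1] * win.shape[2], -1)


def xcorr2d(x: np.ndarray, w: np.ndarray, pad: tuple[int, int] = (0, 0)) -> np.ndarray:
    """Cross-correlate x (B,H,W,Cin) with w (kh,kw,Cin,Cout), zero padding `pad`."""
    b, h, ww, cin = x.shape
    kh, kw, cw, cout = w.shape
    if cw != cin:
        raise ValueError(f"channel mismatch: input has {cin} channels, kernel expects {cw}")
    if pad != (0, 0):
        x = np.pad(x, ((0, 0), (pad[0], pad[0]), (pad[1], pad[1]), (0, 0)))
    ho = x.shape[1] - kh + 1
    wo = x.shape[2] - kw + 1
    if ho < 1 or wo < 1:
        raise ValueError(
            f"input {h}x{ww} too small for {kh}x{kw} kernel with padding {pad}"
        )
    wm = w.reshape(kh * kw * cin, cout)
    out = np.empty((b, ho, wo, cout), dtype=x.dtype)
    per_item = ho * wo * kh * kw * cin * x.itemsize
    for lo, hi in _batch_chunks(b, per_item):
        cols = _im2col(x[lo:hi], kh, kw)
        out[lo:hi] = (cols @ wm).reshape(hi - lo, ho, wo, cout)
    return out


def xcorr2d_wgrad(
    x: np.ndarray, gout: np.ndarray, kh: int, kw: int, pad: tuple[int, int] = (0, 0)
) -> np.ndarray:
    """Gradient of xcorr2d w.r.t. the weights; returns (kh, kw, Cin, Cout)."""
    if pad != (0, 0):
        x = np.pad(x, ((0, 0), (pad[0], pad[0]), (pad[1], pad[1]), (0, 0)))
    b, _, _, cin = x.shape
    _, ho, wo, cout = gout.shape
    gw = np.zeros((kh * kw * cin, cout), dtype=x.dtype)
    per_item = ho * wo * kh * kw * cin * x.itemsize
    for lo, hi in _batch_chunks(b, per_item):
        cols = _im2col(x[lo:hi], kh, kw)
        gw += cols.T @ gout[lo:hi].reshape(-1, cout)
    return gw.reshape(kh, kw, cin, cout)


def xcorr2d_igrad(
    gout: np.ndarray, w: np.ndarray, pad: tuple[int, int] = (0, 0)
) -> np.ndarray:
    """Gradient of xcorr2d w.r.t. its input.

    Equivalent to a "full" cross-correlation of the output gradient with the
    spatially flipped kernel, with in/out channel axes swapped.
    """
    kh, kw = w.shape[0], w.shape[1]
    wt = np.ascontiguousarray(w[::-1, ::-1].transpose(0, 1, 3, 2))
    return xcorr2d(gout, wt, pad=(kh - 1 - pad[0], kw - 1 - pad[1]))
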