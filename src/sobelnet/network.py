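"""The Sobel Network: fixed gradient layer, two valid convolutions, dense head.

Architecture for an H x W single-channel epoch image (H electrodes, W samples):

    input (H, W, 1)
      -> fixed Sobel bank, SAME conv               (H, W, 2*nf)
      -> 20 filters 2x9, valid conv, ReLU          (H-1, W-8, 20)
      -> 18 filters 8x7, valid conv, linear        (H-8, W-14, 18)
      -> flatten                                   Df = (H-8)*(W-14)*18
      -> dense 350, sigmoid
      -> dense 60, linear
      -> dense 1, sigmoid                          class score in (0, 1)

The convolutional layers carry no biases; the dense layers do.  The network
returns both the class score and the Sobel-processed signal, so the same
forward pass feeds classification and the signal-quality harness.

Forward/backward are implemented directly in numpy; gradients are validated
against central finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

from ._conv import xcorr2d, xcorr2d_igrad, xcorr2d_wgrad
from .sobel import EpochBatch, FilterBank, GradientMap, build_filter_bank

CHECKPOINT_SCHEMA_VERSION = 1

_H_MIN, _W_MIN = 9, 15  # smallest input for which every valid conv is non-empty


def shape_chain(h: int, w: int, nf: int = 10) -> dict:
    """Static shape contract of the network for an h x w input."""
    if h < _H_MIN or w < _W_MIN:
        raise ValueError(
            f"input {h}x{w} too small: the valid convolutions require at least "
            f"{_H_MIN}x{_W_MIN}"
        )
    return {
        "sobel": (h, w, 2 * nf),
        "conv1": (h - 1, w - 8, 20),
        "conv2": (h - 8, w - 14, 18),
        "df": (h - 8) * (w - 14) * 18,
        "dense": (350, 60, 1),
    }


@dataclass
class ModelParams:
    """All trainable tensors plus the input geometry they were built for."""

    w1: np.ndarray  # (2, 9, 2*nf, 20)
    w2: np.ndarray  # (8, 7, 20, 18)
    w3: np.ndarray  # (350, Df)
    b3: np.ndarray  # (350,)
    w4: np.ndarray  # (60, 350)
    b4: np.ndarray  # (60,)
    w5: np.ndarray  # (1, 60)
    b5: np.ndarray  # (1,)
    nf: int
    h: int
    w: int

    TENSOR_NAMES = ("w1", "w2", "w3", "b3", "w4", "b4", "w5", "b5")

    def tensors(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in self.TENSOR_NAMES}

    @property
    def df(self) -> int:
        return (self.h - 8) * (self.w - 14) * 18


@dataclass
class NetworkOutput:
    score: np.ndarray  # (B,), strictly inside (0, 1)
    sobel_signal: GradientMap


def _glorot(rng: np.random.Generator, shape, fan_in, fan_out, dtype):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def init_params(h: int, w: int, nf: int = 10, seed: int = 0, dtype=np.float32) -> ModelParams:
    """Glorot-uniform initialisation, deterministic for a given seed."""
    shape_chain(h, w, nf)  # validates h, w
    df = (h - 8) * (w - 14) * 18
    rng = np.random.default_rng(seed)
    c_in = 2 * nf
    return ModelParams(
        w1=_glorot(rng, (2, 9, c_in, 20), 2 * 9 * c_in, 2 * 9 * 20, dtype),
        w2=_glorot(rng, (8, 7, 20, 18), 8 * 7 * 20, 8 * 7 * 18, dtype),
        w3=_glorot(rng, (350, df), df, 350, dtype),
        b3=np.zeros(350, dtype=dtype),
        w4=_glorot(rng, (60, 350), 350, 60, dtype),
        b4=np.zeros(60, dtype=dtype),
        w5=_glorot(rng, (1, 60), 60, 1, dtype),
        b5=np.zeros(1, dtype=dtype),
        nf=int(nf),
        h=int(h),
        w=int(w),
    )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def conv_block(g, params: ModelParams, return_cache: bool = False):
    """Two valid convolutions: 20 filters 2x9 with ReLU, then 18 filters 8x7 linear."""
    gv = g.values if isinstance(g, GradientMap) else np.asarray(g)
    if gv.shape[-1] != 2 * params.nf:
        raise ValueError(
            f"gradient map has {gv.shape[-1]} channels, expected {2 * params.nf}"
        )
    a1 = xcorr2d(gv, params.w1.astype(gv.dtype, copy=False))
    r1 = np.maximum(a1, 0.0)
    c2 = xcorr2d(r1, params.w2.astype(gv.dtype, copy=False))
    if return_cache:
        return c2, {"g": gv, "a1": a1, "r1": r1}
    return c2


def forward(
    x,
    params: ModelParams,
    bank: FilterBank | None = None,
    return_cache: bool = False,
):
    """Full forward pass; returns class score and the Sobel-processed signal."""
    batch = x if isinstance(x, EpochBatch) else EpochBatch(np.asarray(x, dtype=params.w1.dtype))
    if bank is None:
        bank = build_filter_bank(params.nf)
    v = batch.values.astype(params.w1.dtype, copy=False)
    b = v.shape[0]
    if v.shape[1] != params.h or v.shape[2] != params.w:
        raise ValueError(
            f"input spatial dims {v.shape[1]}x{v.shape[2]} do not match the "
            f"model's configured {params.h}x{params.w}"
        )

    weights = bank.conv_weights(c_in=v.shape[3], dtype=v.dtype)
    g = xcorr2d(v, weights, pad=(1, 1))
    c2, cache = conv_block(g, params, return_cache=True)
    f = c2.reshape(b, -1)
    z3 = f @ params.w3.T + params.b3
    h1 = _sigmoid(z3)
    h2 = h1 @ params.w4.T + params.b4  # linear, no activation
    z5 = h2 @ params.w5.T + params.b5
    score = _sigmoid(z5)[:, 0]
    out = NetworkOutput(score=score, sobel_signal=GradientMap(values=g))
    if not return_cache:
        return out
    cache.update(
        {"x": v, "sobel_w": weights, "f": f, "h1": h1, "h2": h2, "score": score,
         "c2_shape": c2.shape}
    )
    return out, cache


def backward(
    cache: dict,
    d_score: np.ndarray,
    params: ModelParams,
    trainable_sobel: bool = False,
) -> dict[str, np.ndarray]:
    """Backpropagate d(loss)/d(score) to gradients for every trainable tensor."""
    score, h2, h1, f = cache["score"], cache["h2"], cache["h1"], cache["f"]
    d_z5 = (d_score * score * (1.0 - score))[:, None]  # (B, 1)
    grads = {
        "w5": d_z5.T @ h2,
        "b5": d_z5.sum(axis=0),
    }
    d_h2 = d_z5 @ params.w5
    grads["w4"] = d_h2.T @ h1
    grads["b4"] = d_h2.sum(axis=0)
    d_h1 = d_h2 @ params.w4
    d_z3 = d_h1 * h1 * (1.0 - h1)
    grads["w3"] = d_z3.T @ f
    grads["b3"] = d_z3.sum(axis=0)
    d_f = d_z3 @ params.w3
    d_c2 = d_f.reshape(cache["c2_shape"])
    r1, a1, g = cache["r1"], cache["a1"], cache["g"]
    grads["w2"] = xcorr2d_wgrad(r1, d_c2, 8, 7)
    d_r1 = xcorr2d_igrad(d_c2, params.w2.astype(d_c2.dtype, copy=False))
    d_a1 = d_r1 * (a1 > 0)
    grads["w1"] = xcorr2d_wgrad(g, d_a1, 2, 9)
    if trainable_sobel:
        d_g = xcorr2d_igrad(d_a1, params.w1.astype(d_a1.dtype, copy=False))
        grads["sobel_w"] = xcorr2d_wgrad(cache["x"], d_g, 3, 3, pad=(1, 1))
    return grads


def save_checkpoint(params: ModelParams, path) -> None:
    """Write all named tensors plus config to an HDF5 container (bit-exact)."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = CHECKPOINT_SCHEMA_VERSION
        f.attrs["nf"] = params.nf
        f.attrs["h"] = params.h
        f.attrs["w"] = params.w
        for name, tensor in params.tensors().items():
            f.create_dataset(name, data=tensor)


def load_checkpoint(path) -> ModelParams:
    with h5py.File(path, "r") as f:
        version = int(f.attrs["schema_version"])
        if version != CHECKPOINT_SCHEMA_VERSION:
            raise ValueError(f"unsupported checkpoint schema_version {version}")
        tensors = {name: f[name][()] for name in ModelParams.TENSOR_NAMES}
        return ModelParams(
            nf=int(f.attrs["nf"]), h=int(f.attrs["h"]), w=int(f.attrs["w"]), **tensors
        )
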