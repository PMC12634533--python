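"""Noise-injection robustness harness.

White Gaussian noise is added to clean epochs at controlled input SNRs; the
harness then measures how the fixed Sobel layer changes signal quality
(SNR / PSNR / SSIM) and how classification accuracy degrades with noise.

Reference convention: the Sobel layer maps the signal out of the input's
units, so output-side quality is measured against the Sobel transform of the
clean epoch — i.e. input SNR compares (noisy vs clean) and output SNR
compares (Sobel(noisy) vs Sobel(clean)).  Each delta is output minus input.

Because the Sobel layer is linear and the injected noise is white, the SNR
gain it confers is (up to sampling error) independent of the input noise
level; the sweep should therefore produce a flat delta-SNR curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity

from .network import ModelParams
from .sobel import FilterBank, sobel_forward
from .synth import Epoch
from .training import classify, epochs_to_arrays, predict_scores

#: Explicit sentinel for a zero residual; never silently averaged.
INF_DB = float("inf")

REPORT_COLUMNS = [
    "nominal_snr_db", "measured_input_snr_db", "output_snr_db",
    "delta_snr_db", "delta_psnr_db", "delta_ssim", "accuracy", "n_epochs",
]


@dataclass
class NoiseCondition:
    target_snr_db: float
    seed: int = 0
    n_reps: int = 1

    def __post_init__(self):
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


def add_noise_at_snr(clean: np.ndarray, target_snr_db: float, rng: np.random.Generator):
    """Additive white Gaussian noise scaled so the measured SNR equals target.

    The noise realisation is rescaled exactly, so the achieved SNR matches the
    target to floating-point precision (well within 0.01 dB).  The clean array
    is not modified.
    """
    clean = np.asarray(clean, dtype=float)
    p_sig = float(np.mean(clean**2))
    if p_sig == 0:
        raise ValueError("clean epoch has zero power; SNR is undefined")
    noise = rng.standard_normal(clean.shape)
    p_noise_target = p_sig / 10.0 ** (target_snr_db / 10.0)
    noise *= np.sqrt(p_noise_target / np.mean(noise**2))
    return clean + noise


def snr_db(reference: np.ndarray, test: np.ndarray) -> float:
    """10*log10(power(reference) / power(test - reference)); inf if identical."""
    reference = np.asarray(reference, dtype=float)
    test = np.asarray(test, dtype=float)
    if reference.shape != test.shape:
        raise ValueError("reference and test must share a shape")
    p_ref = float(np.mean(reference**2))
    if p_ref == 0:
        raise ValueError("reference has zero power; SNR is undefined")
    p_res = float(np.mean((test - reference) ** 2))
    if p_res == 0:
        return INF_DB
    return 10.0 * np.log10(p_ref / p_res)


def psnr_db(reference: np.ndarray, test: np.ndarray) -> float:
    """Peak SNR using the reference's dynamic range (max - min) as peak."""
    reference = np.asarray(reference, dtype=float)
    test = np.asarray(test, dtype=float)
    if reference.shape != test.shape:
        raise ValueError("reference and test must share a shape")
    rng_ref = float(reference.max() - reference.min())
    if rng_ref == 0:
        raise ValueError("reference has zero dynamic range; PSNR is undefined")
    mse = float(np.mean((test - reference) ** 2))
    if mse == 0:
        return INF_DB
    return 20.0 * np.log10(rng_ref) - 10.0 * np.log10(mse)


def ssim(reference: np.ndarray, test: np.ndarray, win_size: int = 11) -> float:
    """Mean structural similarity with an 11x11 Gaussian window (sigma 1.5).

    Stabiliser constants K1=0.01, K2=0.03; dynamic range taken from the
    reference map.
    """
    reference = np.asarray(reference, dtype=float)
    test = np.asarray(test, dtype=float)
    if reference.shape != test.shape or reference.ndim != 2:
        raise ValueError("ssim expects two 2-D maps of identical shape")
    if min(reference.shape) < win_size:
        raise ValueError(
            f"map {reference.shape} smaller than the {win_size}x{win_size} window"
        )
    data_range = float(reference.max() - reference.min())
    if data_range == 0:
        data_range = 1.0
    return float(
        structural_similarity(
            reference,
            test,
            win_size=win_size,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            K1=0.01,
            K2=0.03,
            data_range=data_range,
        )
    )


def _restandardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=(1, 2, 3), keepdims=True)
    sd = x.std(axis=(1, 2, 3), keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def robustness_sweep(
    params: ModelParams | None,
    bank: FilterBank,
    clean_epochs: Sequence[Epoch],
    conditions: Sequence[NoiseCondition],
    transform: Callable[[np.ndarray], np.ndarray] | None = None,
) -> pd.DataFrame:
    """Run the noise sweep; one report row per condition.

    ``transform`` maps a (B, H, W, 1) batch to the processed signal and
    defaults to the Sobel layer; passing ``lambda x: x`` is the identity
    plumbing control for which every delta must be exactly zero.  When
    ``params`` is None the accuracy column is NaN.
    """
    if len(conditions) == 0:
        raise ValueError("need at least one noise condition")
    if transform is None:
        transform = lambda x: sobel_forward(x, bank).values
    x_clean, y = epochs_to_arrays(clean_epochs)  # standardized, matching training
    x_clean = x_clean.astype(float)
    out_clean = transform(x_clean)

    rows = []
    for cond in conditions:
        rng = np.random.default_rng(cond.seed)
        in_snr, out_snr, d_psnr, d_ssim, correct, total = [], [], [], [], 0, 0
        for _ in range(cond.n_reps):
            noisy = np.stack(
                [add_noise_at_snr(x_clean[i], cond.target_snr_db, rng)
                 for i in range(x_clean.shape[0])]
            )
            out_noisy = transform(noisy)
            for i in range(x_clean.shape[0]):
                in_snr.append(snr_db(x_clean[i], noisy[i]))
                out_snr.append(snr_db(out_clean[i], out_noisy[i]))
                d_psnr.append(
                    psnr_db(out_clean[i], out_noisy[i]) - psnr_db(x_clean[i], noisy[i])
                )
                # SSIM per 2-D map: input image once, output averaged over the
                # distinct gradient channels (all replicas are identical).
                n_distinct = min(2, out_clean.shape[-1])
                out_ssim = np.mean(
                    [ssim(out_clean[i, :, :, c], out_noisy[i, :, :, c])
                     for c in range(n_distinct)]
                )
                d_ssim.append(out_ssim - ssim(x_clean[i, :, :, 0], noisy[i, :, :, 0]))
            if params is not None:
                scores = predict_scores(params, _restandardize(noisy).astype(np.float32))
                correct += int(np.sum(classify(scores) == y))
                total += len(y)
        in_mean = float(np.mean(in_snr))
        out_mean = float(np.mean(out_snr))
        rows.append(
            {
                "nominal_snr_db": cond.target_snr_db,
                "measured_input_snr_db": in_mean,
                "output_snr_db": out_mean,
                "delta_snr_db": out_mean - in_mean,
                "delta_psnr_db": float(np.mean(d_psnr)),
                "delta_ssim": float(np.mean(d_ssim)),
                "accuracy": correct / total if total else float("nan"),
                "n_epochs": len(clean_epochs) * cond.n_reps,
            }
        )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)
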