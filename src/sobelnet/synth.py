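"""Synthetic multichannel resting-state EEG with a tunable two-class effect.

Each channel is a 1/f ("pink") Gaussian background plus band-limited
sinusoidal components in the four classical rhythms (delta 1-4 Hz, theta
4-8 Hz, alpha 8-13 Hz, beta 13-30 Hz) with random frequencies and phases.

The class effect emulates frontal alpha asymmetry, a reported depression
biomarker: in class 1 (MDD) the alpha amplitude over the left frontal
electrodes (Fp1, F3, F7 — odd 10-20 labels) is scaled up by (1 + effect_size)
and over the right frontal electrodes (Fp2, F4, F8) scaled down by the same
factor.  effect_size = 0 makes the two classes statistically identical;
large values make them trivially separable.  Everything is deterministic
given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: 19-channel 10-20 montage (frontal row first; ECG deliberately excluded).
MONTAGE_1020 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6", "O1", "O2",
)
LEFT_FRONTAL = frozenset({"Fp1", "F3", "F7"})
RIGHT_FRONTAL = frozenset({"Fp2", "F4", "F8"})

BANDS = {"delta": (1.0, 4.0), "theta": (4.0, 8.0), "alpha": (8.0, 13.0), "beta": (13.0, 30.0)}

_DEFAULT_BAND_POWERS = {"delta": 1.0, "theta": 0.6, "alpha": 1.2, "beta": 0.4}

_SINES_PER_BAND = 3
_SCALE_UV = 10.0  # overall amplitude scale, microvolt-ish


@dataclass
class SynthConfig:
    n_channels: int = 19
    sampling_rate: float = 256.0
    duration_s: float = 120.0
    class_label: int = 0
    effect_size: float = 0.0
    background_exponent: float = 1.0
    band_powers: dict = field(default_factory=lambda: dict(_DEFAULT_BAND_POWERS))
    include_ecg: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.sampling_rate <= 0 or self.duration_s <= 0:
            raise ValueError("sampling_rate and duration_s must be positive")
        n = self.duration_s * self.sampling_rate
        if abs(n - round(n)) > 1e-6:
            raise ValueError("duration_s * sampling_rate must be an integer sample count")
        if self.class_label not in (0, 1):
            raise ValueError("class_label must be 0 (HC) or 1 (MDD)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        unknown = set(self.band_powers) - set(BANDS)
        if unknown:
            raise ValueError(f"unknown bands: {sorted(unknown)}")
        if any(p < 0 for p in self.band_powers.values()):
            raise ValueError("band powers must be non-negative")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sampling_rate))


@dataclass
class Recording:
    values: np.ndarray          # channels x samples, microvolt-scaled
    channel_labels: tuple[str, ...]
    sampling_rate: float
    subject_id: str
    class_label: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("Recording values must be channels x samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("Recording contains non-finite values")
        if len(self.channel_labels) != self.values.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")


@dataclass
class Epoch:
    """One channels x samples window inheriting its recording's label."""

    values: np.ndarray
    label: int
    subject_id: str
    index: int = 0


def _channel_labels(n: int) -> tuple[str, ...]:
    if n <= len(MONTAGE_1020):
        return MONTAGE_1020[:n]
    extra = tuple(f"X{i}" for i in range(1, n - len(MONTAGE_1020) + 1))
    return MONTAGE_1020 + extra


def _pink_background(rng: np.random.Generator, n: int, rate: float, exponent: float):
    white = rng.standard_normal(n)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    bg = np.fft.irfft(np.fft.rfft(white) * shaping, n=n)
    sd = bg.std()
    return bg / sd if sd > 0 else bg


def _ecg_trace(rng: np.random.Generator, n: int, rate: float) -> np.ndarray:
    """Crude synthetic ECG: narrow pulses at ~72 bpm with jitter."""
    t = np.arange(n) / rate
    rr = 60.0 / 72.0
    beats = np.arange(0, t[-1] + rr, rr) + rng.normal(0, 0.02, size=int(t[-1] / rr) + 2)[: int(t[-1] / rr) + 2]
    trace = np.zeros(n)
    for b in beats:
        trace += np.exp(-0.5 * ((t - b) / 0.015) ** 2)
    return 60.0 * trace  # R-peaks dwarf EEG amplitudes


def generate_recording(cfg: SynthConfig) -> Recording:
    """Simulate one subject's recording; bit-identical for the same config."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    labels = _channel_labels(cfg.n_channels)
    t = np.arange(n) / cfg.sampling_rate
    nyq_cap = 0.45 * cfg.sampling_rate
    values = np.empty((cfg.n_channels, n))
    for ci, label in enumerate(labels):
        sig = _pink_background(rng, n, cfg.sampling_rate, cfg.background_exponent)
        for band, (lo, hi) in BANDS.items():
            power = cfg.band_powers.get(band, 0.0)
            hi_eff = min(hi, nyq_cap)
            if power <= 0 or hi_eff <= lo:
                continue
            amp = np.sqrt(power)
            if band == "alpha" and cfg.class_label == 1 and cfg.effect_size > 0:
                if label in LEFT_FRONTAL:
                    amp *= 1.0 + cfg.effect_size
                elif label in RIGHT_FRONTAL:
                    amp /= 1.0 + cfg.effect_size
            freqs = rng.uniform(lo, hi_eff, size=_SINES_PER_BAND)
            phases = rng.uniform(0, 2 * np.pi, size=_SINES_PER_BAND)
            comp = np.sin(2 * np.pi * freqs[:, None] * t + phases[:, None]).sum(axis=0)
            sig = sig + amp * comp / np.sqrt(_SINES_PER_BAND)
        values[ci] = _SCALE_UV * sig
    if cfg.include_ecg:
        values = np.vstack([values, _ecg_trace(rng, n, cfg.sampling_rate)])
        labels = labels + ("ECG",)
    return Recording(
        values=values,
        channel_labels=labels,
        sampling_rate=cfg.sampling_rate,
        subject_id=f"synth-{cfg.seed}",
        class_label=cfg.class_label,
    )


def generate_dataset(
    n_per_class, seed: int = 0, **overrides
) -> list[Recording]:
    """Simulate a labelled cohort with distinct subjects and derived seeds.

    ``n_per_class`` is either one integer (balanced) or a pair
    (n_mdd, n_hc).  Config ``overrides`` apply to every subject.
    """
    if isinstance(n_per_class, (int, np.integer)):
        n_mdd = n_hc = int(n_per_class)
    else:
        n_mdd, n_hc = (int(v) for v in n_per_class)
    if n_mdd < 1 or n_hc < 1:
        raise ValueError("need at least one subject per class")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_mdd + n_hc) % 2**31
    recordings = []
    i = 0
    for label, count, prefix in ((1, n_mdd, "mdd"), (0, n_hc, "hc")):
        for k in range(count):
            cfg = SynthConfig(
                **{**overrides, "class_label": label, "seed": int(child_seeds[i])}
            )
            rec = generate_recording(cfg)
            rec.subject_id = f"{prefix}{k + 1:03d}"
            recordings.append(rec)
            i += 1
    return recordings


def extract_epochs(rec: Recording, window_s: float = 4.0, stride_s: float = 1.0) -> list[Epoch]:
    """Sliding-window segmentation; a window longer than the recording yields []."""
    if stride_s <= 0:
        raise ValueError("stride_s must be positive")
    win = int(round(window_s * rec.sampling_rate))
    stride = int(round(stride_s * rec.sampling_rate))
    n = rec.values.shape[1]
    if win > n:
        return []
    count = (n - win) // stride + 1
    return [
        Epoch(
            values=rec.values[:, i * stride : i * stride + win].copy(),
            label=rec.class_label,
            subject_id=rec.subject_id,
            index=i,
        )
        for i in range(count)
    ]


def dataset_epochs(
    recordings, window_s: float = 4.0, stride_s: float = 1.0
) -> list[Epoch]:
    """Concatenate per-recording epochs; no epoch ever crosses a recording."""
    out: list[Epoch] = []
    for rec in recordings:
        out.extend(extract_epochs(rec, window_s, stride_s))
    return out
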