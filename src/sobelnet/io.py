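"""Recording/report file I/O and run configuration.

Recordings travel either as EDF (European Data Format, 16-bit) or as plain
delimited matrices (one row per channel) with a small YAML sidecar carrying
the sampling rate and channel labels.  EDF reading goes through mne; writing
uses a minimal EDF writer (1-s data records, int16 with per-channel physical
scaling), so round-trips are exact up to 16-bit quantisation.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synth import Recording


class ParseError(ValueError):
    """A recording file could not be parsed."""


# ---------------------------------------------------------------------------
# delimited-matrix format

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.yaml")


def write_recording_csv(rec: Recording, path) -> None:
    path = Path(path)
    np.savetxt(path, rec.values, delimiter=",", fmt="%.6f")
    meta = {
        "sampling_rate": float(rec.sampling_rate),
        "channel_labels": list(rec.channel_labels),
        "subject_id": rec.subject_id,
        "class_label": int(rec.class_label),
    }
    _sidecar_path(path).write_text(yaml.safe_dump(meta))


def read_recording_csv(path, sampling_rate: float | None = None) -> Recording:
    path = Path(path)
    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text()) or {}
    rate = meta.get("sampling_rate", sampling_rate)
    if rate is None:
        raise ParseError(
            f"{path}: no sampling rate; provide the sidecar {sidecar.name} or an "
            "explicit sampling_rate"
        )
    try:
        with open(path) as fh:
            first = fh.readline()
        # optional header row of sample indices (0,1,2,...)
        skip = 0
        tokens = first.strip().split(",")
        if tokens and all(t.strip().lstrip("+-").isdigit() for t in tokens):
            as_int = [int(t) for t in tokens]
            if as_int == list(range(len(as_int))) and len(as_int) > 2:
                skip = 1
        values = np.loadtxt(path, delimiter=",", skiprows=skip, ndmin=2)
    except (OSError, ValueError) as exc:
        raise ParseError(f"{path}: malformed delimited matrix ({exc})") from exc
    labels = meta.get("channel_labels") or [f"CH{i + 1:02d}" for i in range(values.shape[0])]
    return Recording(
        values=values,
        channel_labels=tuple(labels),
        sampling_rate=float(rate),
        subject_id=str(meta.get("subject_id", path.stem)),
        class_label=int(meta.get("class_label", 0)),
    )


# ---------------------------------------------------------------------------
# EDF

def _edf_field(text: str, width: int) -> bytes:
    b = str(text)[:width].encode("ascii", "replace")
    return b + b" " * (width - len(b))


def write_recording_edf(rec: Recording, path) -> None:
    """Minimal EDF writer: 1-second records, int16 samples, physical scaling."""
    rate = rec.sampling_rate
    if abs(rate - round(rate)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate; use CSV instead")
    spr = int(round(rate))  # samples per 1-s record, per signal
    ns, n_samp = rec.values.shape
    n_records = n_samp // spr
    if n_records * spr != n_samp:
        raise ValueError("EDF export requires a whole number of seconds; use CSV instead")

    phys_min = rec.values.min(axis=1)
    phys_max = rec.values.max(axis=1)
    flat = phys_max - phys_min == 0
    phys_max[flat] += 1.0
    dig_min, dig_max = -32768, 32767
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    digital = np.round((rec.values - phys_min[:, None]) / scale[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as f:
        f.write(_edf_field("0", 8))
        f.write(_edf_field(f"{rec.subject_id} class={int(rec.class_label)}", 80))
        f.write(_edf_field("sobelnet synthetic recording", 80))
        f.write(_edf_field("01.01.00", 8))
        f.write(_edf_field("00.00.00", 8))
        f.write(_edf_field(str(256 * (ns + 1)), 8))
        f.write(_edf_field("", 44))
        f.write(_edf_field(str(n_records), 8))
        f.write(_edf_field("1", 8))
        f.write(_edf_field(str(ns), 4))
        for label in rec.channel_labels:
            f.write(_edf_field(label, 16))
        for _ in range(ns):
            f.write(_edf_field("", 80))            # transducer
        for _ in range(ns):
            f.write(_edf_field("uV", 8))           # physical dimension
        for v in phys_min:
            f.write(_edf_field(f"{v:.6g}"[:8], 8))
        for v in phys_max:
            f.write(_edf_field(f"{v:.6g}"[:8], 8))
        for _ in range(ns):
            f.write(_edf_field(str(dig_min), 8))
        for _ in range(ns):
            f.write(_edf_field(str(dig_max), 8))
        for _ in range(ns):
            f.write(_edf_field("", 80))            # prefiltering
        for _ in range(ns):
            f.write(_edf_field(str(spr), 8))
        for _ in range(ns):
            f.write(_edf_field("", 32))
        for r in range(n_records):
            f.write(digital[:, r * spr : (r + 1) * spr].tobytes())


def read_recording_edf(path) -> Recording:
    path = Path(path)
    try:
        with open(path, "rb") as f:
            header = f.read(256)
        if len(header) < 256:
            raise ParseError(f"{path}: truncated EDF header")
        header_bytes = int(header[184:192])
        n_records = int(header[236:244])
        ns = int(header[252:256])
        with open(path, "rb") as f:
            f.seek(256 + ns * 216)
            spr = [int(f.read(8)) for _ in range(ns)]
        expected = header_bytes + n_records * sum(spr) * 2
        actual = path.stat().st_size
        if actual != expected:
            raise ParseError(
                f"{path}: truncated or padded EDF ({actual} bytes, expected {expected})"
            )
        subject_field = header[8:88].decode("ascii", "replace").strip()
    except (ValueError, OSError) as exc:
        raise ParseError(f"{path}: malformed EDF header ({exc})") from exc

    import mne  # deferred: mne import is slow

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    values = raw.get_data() * 1e6  # mne loads EEG in volts; we store microvolts
    subject_id, class_label = path.stem, 0
    if subject_field:
        parts = subject_field.split()
        subject_id = parts[0]
        for p in parts[1:]:
            if p.startswith("class="):
                class_label = int(p.split("=", 1)[1])
    return Recording(
        values=values,
        channel_labels=tuple(raw.ch_names),
        sampling_rate=float(raw.info["sfreq"]),
        subject_id=subject_id,
        class_label=class_label,
    )


# ---------------------------------------------------------------------------
# front door

def write_recording(rec: Recording, path, format: str | None = None) -> None:
    fmt = format or ("edf" if str(path).lower().endswith(".edf") else "csv")
    if fmt == "edf":
        write_recording_edf(rec, path)
    elif fmt == "csv":
        write_recording_csv(rec, path)
    else:
        raise ValueError(f"unknown recording format {fmt!r}")


def read_recording(path, format: str | None = None, sampling_rate: float | None = None) -> Recording:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("edf" if path.suffix.lower() == ".edf" else "csv")
    if fmt == "edf":
        return read_recording_edf(path)
    if fmt == "csv":
        return read_recording_csv(path, sampling_rate=sampling_rate)
    raise ValueError(f"unknown recording format {fmt!r}")


# ---------------------------------------------------------------------------
# manifests, tables, run config

def write_manifest(rows: list[dict], path) -> None:
    pd.DataFrame(rows, columns=["subject_id", "label", "path", "format"]).to_csv(
        path, sep="\t", index=False
    )


def read_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_epochs_manifest(epochs, path) -> None:
    """One row per extracted epoch: subject, label, index within recording."""
    pd.DataFrame(
        [{"subject_id": e.subject_id, "label": e.label, "epoch_index": e.index}
         for e in epochs]
    ).to_csv(path, sep="\t", index=False)


def load_dataset(data_dir) -> list[Recording]:
    """Read every recording listed in <data_dir>/manifest.tsv."""
    data_dir = Path(data_dir)
    manifest = read_manifest(data_dir / "manifest.tsv")
    recs = []
    for _, row in manifest.iterrows():
        rec = read_recording(data_dir / row["path"], format=row["format"])
        rec.subject_id = str(row["subject_id"])
        rec.class_label = int(row["label"])
        recs.append(rec)
    return recs


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


#: Every key a run-config file may set (flat YAML, flag-name spelling).
RUN_CONFIG_KEYS = frozenset(
    {
        "seed", "out", "n_mdd", "n_hc", "duration", "rate", "channels",
        "effect_size", "format", "window", "stride", "nf", "epochs",
        "batch_size", "lr", "momentum", "nesterov", "dropout", "snr",
        "data", "checkpoint", "split",
    }
)


def load_run_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: run config must be a flat key-value mapping")
    unknown = set(cfg) - RUN_CONFIG_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
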