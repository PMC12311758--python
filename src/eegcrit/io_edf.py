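"""Minimal EDF (European Data Format) reader/writer for multichannel EEG.

EDF is a fixed-layout format: a 256-byte ASCII global header, 256 ASCII bytes
per signal of per-channel metadata, then data records of little-endian int16
samples scaled linearly between a digital and a physical range.  This module
implements exactly that subset (one record per second, identical rate on all
channels, physical units microvolts), which covers everything the pipeline
needs.  Condition annotations travel in a plain-CSV sidecar
(``<stem>.annotations.csv`` with columns onset_s,duration_s,label) rather than
an EDF+ annotations channel.
"""

from __future__ import annotations

import csv
import math
from pathlib import Path

import numpy as np

from .recording import Annotation, Recording

__all__ = ["read_edf", "write_edf", "read_annotations_csv", "write_annotations_csv"]

_DIG_MIN, _DIG_MAX = -32768, 32767


def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: Recording, path, annotations_sidecar: bool = True) -> Path:
    """Write a recording as 16-bit EDF (physical units microvolts).

    The sampling rate must divide the record layout evenly; non-integer rates
    use one record of ``n_samples`` samples.  Returns the path written.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) < 1e-9 and rec.n_samples % int(round(fs)) == 0:
        spr = int(round(fs))  # one-second records
        n_records = rec.n_samples // spr
        record_dur = 1.0
    else:
        spr = rec.n_samples
        n_records = 1
        record_dur = rec.n_samples / fs

    ns = rec.n_channels
    # Symmetric physical range per channel, padded so rounding never clips.
    phys_max = np.maximum(np.abs(rec.data).max(axis=1), 1e-6) * 1.000001
    phys_min = -phys_max

    header = b"".join([
        _ascii("0", 8),
        _ascii(rec.meta.get("subject_id", "X"), 80),
        _ascii(rec.meta.get("recording_id", "eegcrit"), 80),
        _ascii("01.01.00", 8),
        _ascii("00.00.00", 8),
        _ascii(256 * (1 + ns), 8),
        _ascii("", 44),
        _ascii(n_records, 8),
        _ascii(f"{record_dur:.7g}"[:8], 8),
        _ascii(ns, 4),
    ])
    sig_header = b"".join([
        b"".join(_ascii(lab, 16) for lab in rec.channel_labels),
        b"".join(_ascii("EEG", 80) for _ in range(ns)),
        b"".join(_ascii("uV", 8) for _ in range(ns)),
        b"".join(_ascii(f"{v:.8g}"[:8], 8) for v in phys_min),
        b"".join(_ascii(f"{v:.8g}"[:8], 8) for v in phys_max),
        b"".join(_ascii(_DIG_MIN, 8) for _ in range(ns)),
        b"".join(_ascii(_DIG_MAX, 8) for _ in range(ns)),
        b"".join(_ascii("", 80) for _ in range(ns)),
        b"".join(_ascii(spr, 8) for _ in range(ns)),
        b"".join(_ascii("", 32) for _ in range(ns)),
    ])

    # Re-read the headers we wrote so digitization uses exactly the stored ranges.
    pm_stored = np.array([float(f"{v:.8g}"[:8]) for v in phys_max])
    scale = (pm_stored - (-pm_stored)) / (_DIG_MAX - _DIG_MIN)
    digital = np.round((rec.data - (-pm_stored)[:, None]) / scale[:, None] + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for r in range(n_records):
            block = digital[:, r * spr:(r + 1) * spr]
            fh.write(block.tobytes())

    if annotations_sidecar and rec.annotations:
        write_annotations_csv(rec.annotations, _sidecar_path(path))
    return path


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".annotations.csv")


def write_annotations_csv(annotations: list[Annotation], path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["onset_s", "duration_s", "label"])
        for ann in annotations:
            w.writerow([f"{ann.onset:g}", f"{ann.duration:g}", ann.label])
    return path


def read_annotations_csv(path) -> list[Annotation]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(Annotation(float(row["onset_s"]), float(row["duration_s"]), row["label"]))
    return out


def read_edf(path, annotations_sidecar: bool = True) -> Recording:
    """Read a 16-bit EDF/BDF-style file written with uniform per-channel rates."""
    path = Path(path)
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise ValueError(f"{path} is not an EDF file (truncated header)")
        header_bytes = int(head[184:192])
        n_records = int(head[236:244])
        record_dur = float(head[244:252])
        ns = int(head[252:256])
        sig = fh.read(256 * ns)
        labels = [sig[16 * i:16 * (i + 1)].decode("ascii").strip() for i in range(ns)]
        off = 16 * ns + 80 * ns + 8 * ns
        phys_min = np.array([float(sig[off + 8 * i: off + 8 * (i + 1)]) for i in range(ns)])
        off += 8 * ns
        phys_max = np.array([float(sig[off + 8 * i: off + 8 * (i + 1)]) for i in range(ns)])
        off += 8 * ns
        dig_min = np.array([float(sig[off + 8 * i: off + 8 * (i + 1)]) for i in range(ns)])
        off += 8 * ns
        dig_max = np.array([float(sig[off + 8 * i: off + 8 * (i + 1)]) for i in range(ns)])
        off += 8 * ns + 80 * ns
        spr = [int(sig[off + 8 * i: off + 8 * (i + 1)]) for i in range(ns)]
        if len(set(spr)) != 1:
            raise ValueError("mixed per-channel sampling rates are not supported")
        spr = spr[0]
        fh.seek(header_bytes)
        raw = np.frombuffer(fh.read(), dtype="<i2")

    expected = n_records * ns * spr
    raw = raw[:expected].reshape(n_records, ns, spr)
    data = np.concatenate([raw[r] for r in range(n_records)], axis=1).astype(float)
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    data = (data - dig_min[:, None]) * scale[:, None] + phys_min[:, None]
    fs = spr / record_dur
    # the 8-char header limits the record-duration precision; snap near-integer rates
    if abs(fs - round(fs)) < 1e-3 * max(fs, 1.0):
        fs = round(fs)

    annotations: list[Annotation] = []
    sidecar = _sidecar_path(path)
    if annotations_sidecar and sidecar.exists():
        annotations = read_annotations_csv(sidecar)
    return Recording(data=data, fs=fs, channel_labels=labels, annotations=annotations)


def edf_quantization_step(rec: Recording) -> np.ndarray:
    """Per-channel quantization step of a 16-bit EDF round trip (for tests)."""
    phys_max = np.maximum(np.abs(rec.data).max(axis=1), 1e-6) * 1.000001
    return 2 * phys_max / (_DIG_MAX - _DIG_MIN)


def _check_record_layout(fs: float, n: int) -> None:  # pragma: no cover - debug aid
    if not math.isclose(fs, round(fs)):
        raise ValueError("non-integer sampling rates are written as a single record")
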