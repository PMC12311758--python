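"""Idealized 10-10 electrode coordinates on the unit sphere.

The construction is the textbook geometric one: the head is a unit sphere with
the vertex (Cz) at the pole; nasion and inion lie 90 degrees anterior and
posterior of the vertex on the midsagittal great circle.  The 10-20
"circumferential ring" (Fpz, Fp1/2, AF7/8, F7/8, FT7/8, T7/8, TP7/8, P7/8,
PO7/8, O1/2, Oz) sits at 72 degrees of inclination from the vertex, with ring
electrodes every 18 degrees of azimuth.  Midline electrodes are spaced every
18 degrees along the midsagittal arc, and interior chain electrodes (e.g. C3,
FC1) divide the great-circle arc from the ring electrode to the midline
electrode into equal parts (quarters for 10-10 chains).

Axes: x to the right ear, y to the nasion, z up.
"""

from __future__ import annotations

import csv
from importlib import resources

import numpy as np

__all__ = ["ideal_1010_positions", "load_montage_csv", "standard_montage"]

_RING_INCLINATION = np.deg2rad(72.0)

# Ring electrodes: label -> azimuth in degrees (0 at nasion, positive to the right).
_RING = {
    "Fpz": 0, "Fp2": 18, "AF8": 36, "F8": 54, "FT8": 72, "T8": 90,
    "TP8": 108, "P8": 126, "PO8": 144, "O2": 162, "Oz": 180,
    "O1": -162, "PO7": -144, "P7": -126, "TP7": -108, "T7": -90,
    "FT7": -72, "F7": -54, "AF7": -36, "Fp1": -18,
}

# Midline: label -> anterior angle from vertex in degrees (positive toward nasion).
_MIDLINE = {
    "AFz": 54, "Fz": 36, "FCz": 18, "Cz": 0, "CPz": -18, "Pz": -36, "POz": -54,
}

# Interior chains: (ring endpoint left, ring endpoint right, midline electrode,
# [(label_left, fraction from ring to midline), ...]); right labels mirror left.
_CHAINS = [
    ("AF7", "AF8", "AFz", [("AF3", 0.5)]),
    ("F7", "F8", "Fz", [("F5", 0.25), ("F3", 0.5), ("F1", 0.75)]),
    ("FT7", "FT8", "FCz", [("FC5", 0.25), ("FC3", 0.5), ("FC1", 0.75)]),
    ("T7", "T8", "Cz", [("C5", 0.25), ("C3", 0.5), ("C1", 0.75)]),
    ("TP7", "TP8", "CPz", [("CP5", 0.25), ("CP3", 0.5), ("CP1", 0.75)]),
    ("P7", "P8", "Pz", [("P5", 0.25), ("P3", 0.5), ("P1", 0.75)]),
    ("PO7", "PO8", "POz", [("PO3", 0.5)]),
]

_MIRROR = {"1": "2", "3": "4", "5": "6", "7": "8"}


def _ring_xyz(azimuth_deg: float) -> np.ndarray:
    a = np.deg2rad(azimuth_deg)
    s = np.sin(_RING_INCLINATION)
    return np.array([s * np.sin(a), s * np.cos(a), np.cos(_RING_INCLINATION)])


def _midline_xyz(anterior_deg: float) -> np.ndarray:
    a = np.deg2rad(anterior_deg)
    return np.array([0.0, np.sin(a), np.cos(a)])


def _slerp(u: np.ndarray, v: np.ndarray, f: float) -> np.ndarray:
    omega = np.arccos(np.clip(u @ v, -1.0, 1.0))
    if omega < 1e-12:
        return u.copy()
    return (np.sin((1 - f) * omega) * u + np.sin(f * omega) * v) / np.sin(omega)


def _mirror_label(label: str) -> str:
    # F5 -> F6 etc.: mirror the trailing digit.
    return label[:-1] + _MIRROR[label[-1]]


def ideal_1010_positions() -> dict[str, np.ndarray]:
    """Return label -> unit-sphere xyz for the idealized 61-channel 10-10 set."""
    pos: dict[str, np.ndarray] = {}
    for lab, az in _RING.items():
        pos[lab] = _ring_xyz(az)
    for lab, ant in _MIDLINE.items():
        pos[lab] = _midline_xyz(ant)
    for left_ring, right_ring, mid, interior in _CHAINS:
        for lab, frac in interior:
            pos[lab] = _slerp(pos[left_ring], pos[mid], frac)
            pos[_mirror_label(lab)] = _slerp(pos[right_ring], pos[mid], frac)
    return {k: v / np.linalg.norm(v) for k, v in pos.items()}


def load_montage_csv(path) -> dict[str, np.ndarray]:
    """Load a montage CSV with columns label,x,y,z; coordinates are re-normalized."""
    pos = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            v = np.array([float(row["x"]), float(row["y"]), float(row["z"])])
            pos[row["label"]] = v / np.linalg.norm(v)
    return pos


def standard_montage() -> dict[str, np.ndarray]:
    """Load the packaged idealized 10-10 montage."""
    ref = resources.files("eegcrit") / "data" / "montage_1010.csv"
    with resources.as_file(ref) as path:
        return load_montage_csv(path)


def positions_for(labels: list[str], montage: dict[str, np.ndarray] | None = None) -> np.ndarray:
    """Stack montage positions for the given labels into an (n, 3) array."""
    montage = montage if montage is not None else standard_montage()
    missing = [lab for lab in labels if lab not in montage]
    if missing:
        raise KeyError(f"labels missing from montage: {missing}")
    return np.stack([montage[lab] for lab in labels])
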