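"""Deterministic signal conditioning of raw multichannel recordings.

Pipeline order is fixed: notch -> bad-channel interpolation -> FIR bandpass ->
spherical-spline surface Laplacian -> condition selection.  All filters are
applied zero-phase so that downstream phase metrics (wPLI) do not inherit
filter group delay.  Which channels are bad is taken from the recording's
metadata; no automatic artifact detection is attempted.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sps
from numpy.polynomial import legendre as npleg

from .recording import Recording

__all__ = [
    "notch_filter",
    "bandpass_fir",
    "interpolate_bad_channels",
    "surface_laplacian",
    "select_condition",
    "preprocess_pipeline",
    "SubjectRejectedError",
]

#: Legendre-series truncation for the spherical splines.  For spline order
#: m=4 the terms decay as n^-7, so 50 terms leave truncation error < 1e-6.
N_LEGENDRE_TERMS = 50


class SubjectRejectedError(RuntimeError):
    """Raised when a recording does not retain enough usable data."""


def notch_filter(rec: Recording, freq: float = 50.0, order: int = 2) -> Recording:
    """Zero-phase band-stop at the power-line frequency (order-2 IIR notch)."""
    if freq >= rec.fs / 2:
        raise ValueError(f"notch frequency {freq:g} Hz is at or above Nyquist ({rec.fs / 2:g} Hz)")
    if order != 2:
        raise ValueError("only the order-2 notch design is implemented")
    b, a = sps.iirnotch(freq, Q=30.0, fs=rec.fs)
    out = sps.filtfilt(b, a, rec.data, axis=1)
    return rec.copy_with(data=out)


def bandpass_fir(rec: Recording, lo: float = 1.0, hi: float = 80.0,
                 order: int = 1858, kaiser_beta: float = 5.0) -> Recording:
    """Zero-phase FIR bandpass (Kaiser window) with group-delay compensation.

    The filter is linear-phase (Type I, even ``order``), applied forward on a
    reflection-padded signal with the kernel centred, which compensates the
    group delay exactly.
    """
    if not lo < hi < rec.fs / 2:
        raise ValueError(f"need lo < hi < Nyquist; got lo={lo}, hi={hi}, fs={rec.fs}")
    if order % 2:
        order += 1  # keep the group delay an integer number of samples
    if rec.n_samples < 3 * order:
        raise ValueError(
            f"signal too short for FIR order {order}: need >= {3 * order} samples, "
            f"got {rec.n_samples}"
        )
    taps = sps.firwin(order + 1, [lo, hi], window=("kaiser", kaiser_beta),
                      pass_zero=False, fs=rec.fs)
    pad = order
    xp = np.pad(rec.data, ((0, 0), (pad, pad)), mode="reflect")
    y = sps.fftconvolve(xp, taps[None, :], mode="same", axes=1)[:, pad:-pad]
    return rec.copy_with(data=y)


# --------------------------------------------------------------------------
# spherical splines (Perrin et al. construction)
# --------------------------------------------------------------------------

def _legendre_series(coeffs: np.ndarray, x: np.ndarray) -> np.ndarray:
    return npleg.legval(np.clip(x, -1.0, 1.0), coeffs)


def _g_coeffs(m: int) -> np.ndarray:
    n = np.arange(1, N_LEGENDRE_TERMS + 1, dtype=float)
    c = np.zeros(N_LEGENDRE_TERMS + 1)
    c[1:] = (2 * n + 1) / (n * (n + 1)) ** m / (4 * np.pi)
    return c


def _h_coeffs(m: int) -> np.ndarray:
    # Second spatial derivative removes one power of n(n+1).
    n = np.arange(1, N_LEGENDRE_TERMS + 1, dtype=float)
    c = np.zeros(N_LEGENDRE_TERMS + 1)
    c[1:] = (2 * n + 1) / (n * (n + 1)) ** (m - 1) / (4 * np.pi)
    return c


def interpolate_bad_channels(rec: Recording, m_order: int = 4,
                             reg: float = 1e-8) -> Recording:
    """Replace bad channels by spherical-spline estimates from good channels."""
    if rec.positions is None:
        raise ValueError(
            "recording has no electrode positions; supply a montage "
            "(eegcrit.montage.standard_montage) before interpolating"
        )
    if not rec.bad_channels:
        return rec.copy_with()
    good = rec.good_channel_indices()
    bad = np.array([i for i in range(rec.n_channels) if i not in good], dtype=int)
    if good.size < 4:
        raise ValueError(f"need >= 4 good channels to interpolate, have {good.size}")
    gc = _g_coeffs(m_order)
    pg = rec.positions[good]
    pb = rec.positions[bad]
    G = _legendre_series(gc, pg @ pg.T) + reg * np.eye(good.size)
    Gb = _legendre_series(gc, pb @ pg.T)
    # Solve [[G, 1], [1^T, 0]] [c; c0] = [v; 0] for all time points at once.
    A = np.zeros((good.size + 1, good.size + 1))
    A[:-1, :-1] = G
    A[:-1, -1] = 1.0
    A[-1, :-1] = 1.0
    rhs = np.vstack([rec.data[good], np.zeros(rec.n_samples)])
    sol = np.linalg.solve(A, rhs)
    est = Gb @ sol[:-1] + sol[-1]
    out = rec.data.copy()
    out[bad] = est
    return rec.copy_with(data=out, bad_channels=[])


def surface_laplacian(rec: Recording, lambda_: float = 1e-5,
                      m_order: int = 4) -> Recording:
    """Scalp current density via the spherical-spline surface Laplacian.

    Perrin-style: spline weights are fitted to the potentials with Tikhonov
    regularization ``lambda_`` on the spline matrix and a zero-sum
    constraint, and the current source density is read out through the
    once-differentiated Legendre series.  Output spatial mean over channels is
    approximately zero at every sample, and the transform is invariant to a
    channel-common offset.
    """
    if rec.positions is None:
        raise ValueError("surface Laplacian requires electrode positions for all channels")
    if rec.n_channels < 16:
        warnings.warn(
            f"surface Laplacian on {rec.n_channels} channels is poorly conditioned",
            RuntimeWarning, stacklevel=2,
        )
    cosang = rec.positions @ rec.positions.T
    G = _legendre_series(_g_coeffs(m_order), cosang) + lambda_ * np.eye(rec.n_channels)
    H = _legendre_series(_h_coeffs(m_order), cosang)
    Gi = np.linalg.inv(G)
    tc = Gi.sum(axis=1)
    sgi = tc.sum()
    C = Gi @ rec.data
    c0 = C.sum(axis=0) / sgi
    C = C - np.outer(tc, c0)
    out = H @ C
    return rec.copy_with(data=out)


def select_condition(rec: Recording, label: str = "eyes-closed",
                     min_duration: float = 60.0) -> Recording:
    """Concatenate all annotation segments with ``label``; record splice points.

    Rejects the subject (raises :class:`SubjectRejectedError`) when less than
    ``min_duration`` seconds of the condition survive, mirroring the study
    design of discarding subjects with under a minute of usable eyes-closed
    rest.
    """
    if not rec.annotations:
        raise ValueError("recording has no annotations")
    segs = [a for a in rec.annotations if a.label == label]
    if not segs:
        labels = sorted({a.label for a in rec.annotations})
        raise ValueError(f"no annotation with label {label!r}; present labels: {labels}")
    pieces = []
    splices = []
    total = 0
    for a in sorted(segs, key=lambda a: a.onset):
        i0 = int(round(a.onset * rec.fs))
        i1 = min(rec.n_samples, i0 + int(round(a.duration * rec.fs)))
        if i1 <= i0:
            continue
        pieces.append(rec.data[:, i0:i1])
        total += i1 - i0
        splices.append(total)
    splices = splices[:-1]  # boundaries between pieces only
    if total / rec.fs < min_duration:
        raise SubjectRejectedError(
            f"only {total / rec.fs:.1f} s of {label!r} data; subject rejected "
            f"(< {min_duration:g} s)"
        )
    out = np.concatenate(pieces, axis=1)
    return rec.copy_with(data=out, annotations=[], splices=list(splices))


def preprocess_pipeline(rec: Recording, notch_freq: float = 50.0,
                        bandpass: tuple[float, float] = (1.0, 80.0),
                        fir_order: int = 1858, laplacian_lambda: float = 1e-5,
                        laplacian_m: int = 4,
                        condition: str | None = "eyes-closed") -> Recording:
    """Run the full conditioning chain in the fixed order; records the order used."""
    out = notch_filter(rec, freq=notch_freq)
    steps = ["notch"]
    if out.bad_channels:
        out = interpolate_bad_channels(out)
        steps.append("interpolate_bad_channels")
    out = bandpass_fir(out, *bandpass, order=fir_order)
    steps.append("bandpass_fir")
    if out.positions is not None:
        out = surface_laplacian(out, lambda_=laplacian_lambda, m_order=laplacian_m)
        steps.append("surface_laplacian")
    if condition is not None and out.annotations:
        out = select_condition(out, condition)
        steps.append("select_condition")
    out.meta["preprocess_order"] = steps
    return out
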