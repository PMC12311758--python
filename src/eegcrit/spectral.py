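"""Morlet time-frequency decomposition.

All criticality and synchrony metrics consume the complex narrowband
coefficients produced here: 30 log-spaced complex Morlet wavelets covering
2-70 Hz with m = 5 cycles, where m is the ratio of center frequency to the
Gaussian bandwidth (temporal SD sigma_t = m / (2*pi*f)).  Wavelets are
L2-normalized; every downstream metric is scale-invariant, so the
normalization convention only fixes the (arbitrary) envelope units.
Convolution is FFT-based on a reflection-padded signal, and a validity mask
excludes 3 sigma_t of edge transient per side as well as samples within the
same margin of any splice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .recording import Recording

__all__ = ["WaveletBank", "NarrowbandDecomposition", "make_bank", "transform",
           "CANONICAL_BANDS", "band_frequency_indices"]

#: Canonical frequency bands in Hz (inclusive bounds).
CANONICAL_BANDS = {
    "delta": (2.0, 4.0),
    "theta": (5.0, 7.0),
    "alpha": (8.0, 13.0),
    "beta": (15.0, 30.0),
    "gamma": (30.0, 70.0),
}

N_FREQS = 30
F_LO, F_HI = 2.0, 70.0
EDGE_SIGMAS = 3.0


@dataclass(frozen=True)
class WaveletBank:
    """30 log-spaced Morlet center frequencies with m cycles at sampling rate fs."""

    freqs: np.ndarray
    m: float
    fs: float

    def sigma_t(self, k: int) -> float:
        """Temporal Gaussian SD of wavelet k in seconds."""
        return self.m / (2 * np.pi * self.freqs[k])

    def nearest_index(self, freq: float) -> int:
        return int(np.argmin(np.abs(self.freqs - freq)))


def make_bank(fs: float, m: float = 5.0) -> WaveletBank:
    """The standard bank: freqs[k] = 2 * 35**(k/29), k = 0..29."""
    if fs <= 2 * F_HI:
        raise ValueError(
            f"fs={fs:g} Hz violates the Nyquist constraint: need fs > {2 * F_HI:g} Hz "
            f"to resolve the {F_HI:g} Hz wavelet"
        )
    if m <= 0:
        raise ValueError("m must be positive")
    freqs = F_LO * (F_HI / F_LO) ** (np.arange(N_FREQS) / (N_FREQS - 1))
    return WaveletBank(freqs=freqs, m=m, fs=fs)


@dataclass
class NarrowbandDecomposition:
    """Complex analytic coefficients, channel x frequency x time.

    ``valid_mask`` (frequency x time) is False within ``EDGE_SIGMAS`` wavelet
    SDs of the signal edges and of every splice; windowed metrics must only
    use valid samples.
    """

    coeffs: np.ndarray
    freqs: np.ndarray
    fs: float
    valid_mask: np.ndarray
    channel_labels: list[str]
    bank: WaveletBank

    @property
    def envelope(self) -> np.ndarray:
        return np.abs(self.coeffs)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.coeffs)

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[0]

    @property
    def n_freqs(self) -> int:
        return self.coeffs.shape[1]


def _morlet(freq: float, fs: float, m: float) -> np.ndarray:
    sigma_t = m / (2 * np.pi * freq)
    half = int(np.ceil(5 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    w = np.exp(-t ** 2 / (2 * sigma_t ** 2)) * np.exp(2j * np.pi * freq * t)
    return w / np.linalg.norm(w)


def transform(rec: Recording, bank: WaveletBank | None = None,
              freq_indices=None, channels=None) -> NarrowbandDecomposition:
    """Convolve the recording with the Morlet bank.

    ``freq_indices`` / ``channels`` restrict the decomposition (memory/time);
    the returned object's ``freqs`` and ``channel_labels`` reflect the subset.
    """
    bank = bank if bank is not None else make_bank(rec.fs)
    if abs(bank.fs - rec.fs) > 1e-9:
        raise ValueError(f"bank built for fs={bank.fs:g}, recording has fs={rec.fs:g}")
    idx = np.arange(len(bank.freqs)) if freq_indices is None else np.atleast_1d(freq_indices)
    ch = np.arange(rec.n_channels) if channels is None else np.atleast_1d(channels)
    min_dur = 10.0 / bank.freqs[idx].min()
    if rec.duration < min_dur:
        raise ValueError(
            f"recording of {rec.duration:g} s is shorter than 10 cycles of the "
            f"lowest requested frequency ({min_dur:g} s)"
        )
    n = rec.n_samples
    coeffs = np.empty((ch.size, idx.size, n), dtype=complex)
    valid = np.ones((idx.size, n), dtype=bool)
    for j, k in enumerate(idx):
        w = _morlet(bank.freqs[k], rec.fs, bank.m)
        pad = w.size // 2
        margin = int(np.ceil(EDGE_SIGMAS * bank.sigma_t(k) * rec.fs))
        valid[j, :margin] = False
        valid[j, n - margin:] = False
        for s in rec.splices:
            valid[j, max(0, s - margin):min(n, s + margin)] = False
        for i, c in enumerate(ch):
            xp = np.pad(rec.data[c], pad, mode="reflect")
            coeffs[i, j] = sps.fftconvolve(xp, w, mode="same")[pad:pad + n]
    return NarrowbandDecomposition(
        coeffs=coeffs, freqs=bank.freqs[idx], fs=rec.fs, valid_mask=valid,
        channel_labels=[rec.channel_labels[c] for c in ch], bank=bank,
    )


def band_frequency_indices(freqs: np.ndarray, band: str | tuple[float, float]) -> np.ndarray:
    """Indices of bank frequencies inside a canonical band (inclusive bounds).

    Raises if the band contains no bank frequency.
    """
    if isinstance(band, str):
        if band not in CANONICAL_BANDS:
            raise KeyError(f"unknown band {band!r}; canonical bands: {list(CANONICAL_BANDS)}")
        lo, hi = CANONICAL_BANDS[band]
        name = band
    else:
        lo, hi = band
        name = f"{lo:g}-{hi:g} Hz"
    idx = np.where((freqs >= lo) & (freqs <= hi))[0]
    if idx.size == 0:
        raise ValueError(f"band {name} contains no bank frequency")
    return idx
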