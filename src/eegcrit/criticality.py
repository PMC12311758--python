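"""Per-channel, per-frequency criticality assessments: DFA, fEI, BiS.

* DFA (detrended fluctuation analysis): RMS residual of linearly detrended
  cumulative-sum windows versus window size; the slope in log-log coordinates
  is the scaling exponent (0.5 = uncorrelated, (0.5, 1] = persistent
  long-range temporal correlations).
* fEI (functional excitation-inhibition ratio): 1 minus the Pearson
  correlation, across 40-cycle windows at 80% overlap, between the window mean
  amplitude and the window's amplitude-normalized detrended fluctuation.
  fEI = 1 at the critical balance, < 1 inhibition-dominated, > 1
  excitation-dominated.  Computed only where the DFA exponent exceeds 0.6:
  without LRTC, amplitude and fluctuation do not covary and the ratio is
  meaningless.
* BiS (bistability index): the normalized power series R^2 (unit-rate
  exponential under the Gaussian-narrowband null) is fitted with a
  single-exponential and a two-exponential mixture; BiS = log10 of the BIC
  advantage of the mixture, floored at zero.  BiS > 3 indicates a clearly
  bimodal amplitude distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectral import NarrowbandDecomposition

__all__ = ["DFAResult", "FEIResult", "BiSFit", "CriticalityProfile",
           "dfa", "fei", "fit_bis", "profile", "bis_from_dbic",
           "default_dfa_window_sizes"]

DFA_GATE = 0.6           # minimum DFA exponent for fEI to be defined
FEI_WINDOW_CYCLES = 40
FEI_OVERLAP = 0.8
DFA_N_SIZES = 10
#: Smallest fit scale in cycles of the wavelet frequency.  An m=5 Morlet
#: wavelet cannot resolve amplitude modulation faster than ~1/5 of the
#: carrier; small windows measure the wavelet's own amplitude response and
#: bias the exponent upward (~+0.1 at a 5-cycle floor on this chain, ~+0.03
#: at 20 cycles, ~+0.01 at 30), so the fit starts well above the wavelet
#: width.  The cost is that frequency f needs ~300/f seconds of signal.
DFA_MIN_CYCLES = 30.0
DFA_MAX_FRACTION = 0.1   # largest fit scale as a fraction of the signal length
DFA_OVERLAP = 0.5
BIS_SAMPLES_PER_CYCLE = 2.0
BIS_MIN_SAMPLES = 200
EM_MAX_ITER = 500
EM_TOL = 1e-8


# --------------------------------------------------------------------------
# DFA
# --------------------------------------------------------------------------

@dataclass
class DFAResult:
    exponent: float
    fit_r2: float
    window_sizes: np.ndarray          # seconds
    fluctuation: np.ndarray           # F(n) per window size
    degenerate: bool = False


def default_dfa_window_sizes(freq: float, n_samples: int, fs: float,
                             n_sizes: int = DFA_N_SIZES,
                             min_cycles: float = DFA_MIN_CYCLES) -> np.ndarray:
    """Log-spaced window sizes (seconds) from ``min_cycles`` of ``freq`` to n/10."""
    lo = min_cycles / freq
    hi = DFA_MAX_FRACTION * n_samples / fs
    if hi <= lo:
        raise ValueError(
            f"signal too short for DFA at {freq:g} Hz: largest window {hi:g} s "
            f"must exceed the smallest ({lo:g} s)"
        )
    return np.geomspace(lo, hi, n_sizes)


def _detrended_rms(windows: np.ndarray) -> np.ndarray:
    """Per-row RMS of the least-squares linear-detrend residual."""
    m, n = windows.shape
    t = np.arange(n, dtype=float)
    t -= t.mean()
    denom = (t ** 2).sum()
    mean = windows.mean(axis=1, keepdims=True)
    slope = (windows @ t)[:, None] / denom
    resid = windows - mean - slope * t
    return np.sqrt((resid ** 2).mean(axis=1))


def dfa(envelope: np.ndarray, fs_env: float,
        window_sizes: np.ndarray | None = None,
        freq: float | None = None, overlap: float = DFA_OVERLAP) -> DFAResult:
    """Classic DFA of a positive envelope series.

    ``window_sizes`` in seconds; if omitted they are derived from ``freq``
    (see :func:`default_dfa_window_sizes`).  Returns NaN exponent with the
    ``degenerate`` flag set for a constant envelope.
    """
    envelope = np.asarray(envelope, dtype=float)
    if window_sizes is None:
        if freq is None:
            raise ValueError("provide window_sizes or the oscillation frequency")
        window_sizes = default_dfa_window_sizes(freq, envelope.size, fs_env)
    window_sizes = np.asarray(window_sizes, dtype=float)
    if window_sizes.size < 5 or np.any(np.diff(window_sizes) <= 0):
        raise ValueError("need >= 5 strictly increasing window sizes")
    n_max = int(round(window_sizes.max() * fs_env))
    if envelope.size < 10 * n_max:
        raise ValueError(
            f"envelope length {envelope.size} must be >= 10 x the largest window "
            f"({10 * n_max} samples)"
        )
    if np.ptp(envelope) == 0:
        return DFAResult(np.nan, np.nan, window_sizes,
                         np.full(window_sizes.size, np.nan), degenerate=True)

    prof = np.cumsum(envelope - envelope.mean())
    fluct = np.empty(window_sizes.size)
    for i, w in enumerate(window_sizes):
        n = max(4, int(round(w * fs_env)))
        step = max(1, int(round(n * (1 - overlap))))
        starts = np.arange(0, prof.size - n + 1, step)
        windows = prof[starts[:, None] + np.arange(n)]
        rms = _detrended_rms(windows)
        fluct[i] = np.sqrt((rms ** 2).mean())
    logn = np.log10(window_sizes)
    logf = np.log10(fluct)
    slope, intercept = np.polyfit(logn, logf, 1)
    pred = slope * logn + intercept
    ss_res = ((logf - pred) ** 2).sum()
    ss_tot = ((logf - logf.mean()) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return DFAResult(float(slope), float(r2), window_sizes, fluct)


# --------------------------------------------------------------------------
# fEI
# --------------------------------------------------------------------------

@dataclass
class FEIResult:
    fei: float
    valid: bool
    n_windows: int
    n_dropped: int
    window_len_cycles: int = FEI_WINDOW_CYCLES
    overlap: float = FEI_OVERLAP


def fei(envelope: np.ndarray, freq: float, fs_env: float,
        dfa_exponent: float, valid_mask: np.ndarray | None = None) -> FEIResult:
    """Functional E/I ratio of a positive envelope at oscillation frequency ``freq``.

    Windows of 40 cycles with 80% overlap, laid out left to right (a final
    partial window is discarded); windows overlapping invalid samples or with
    zero mean amplitude are dropped.  Missing (NaN) when the DFA gate fails,
    fewer than 20 windows remain, or more than 20% of windows were dropped.
    """
    envelope = np.asarray(envelope, dtype=float)
    if not np.isfinite(dfa_exponent) or dfa_exponent <= DFA_GATE:
        return FEIResult(np.nan, False, 0, 0)
    win = int(round(FEI_WINDOW_CYCLES * fs_env / freq))
    step = max(1, int(round(win * (1 - FEI_OVERLAP))))
    starts = np.arange(0, envelope.size - win + 1, step)
    if starts.size < 20:
        return FEIResult(np.nan, False, int(starts.size), 0)
    idx = starts[:, None] + np.arange(win)
    keep = np.ones(starts.size, dtype=bool)
    if valid_mask is not None:
        keep &= np.asarray(valid_mask, dtype=bool)[idx].all(axis=1)
    windows = envelope[idx]
    w_amp = windows.mean(axis=1)
    nonzero = w_amp > 0
    n_dropped = int((~(keep & nonzero)).sum())
    keep &= nonzero
    if keep.sum() < 20 or n_dropped > 0.2 * starts.size:
        return FEIResult(np.nan, False, int(keep.sum()), n_dropped)
    windows = windows[keep]
    w_amp = w_amp[keep]
    prof = np.cumsum(windows / w_amp[:, None] - 1.0, axis=1)
    w_dnf = _detrended_rms(prof)
    r = np.corrcoef(w_amp, w_dnf)[0, 1]
    return FEIResult(float(1.0 - r), True, int(keep.sum()), n_dropped)


# --------------------------------------------------------------------------
# BiS
# --------------------------------------------------------------------------

@dataclass
class BiSFit:
    gamma: float
    gamma1: float
    gamma2: float
    delta1: float
    delta2: float
    loglik_single: float
    loglik_bi: float
    n_eff: int
    bic_single: float
    bic_double: float
    dbic: float
    bis: float
    k_single: int = 1
    k_bi: int = 4
    em_converged: bool = True


def bis_from_dbic(dbic: float) -> float:
    """BiS = log10(dBIC) when the mixture wins (dBIC > 0), else 0."""
    return float(np.log10(dbic)) if dbic > 0 else 0.0


def _mixture_loglik(y: np.ndarray, d1: float, g1: float, g2: float) -> float:
    p = d1 * g1 * np.exp(-g1 * y) + (1 - d1) * g2 * np.exp(-g2 * y)
    return float(np.log(np.maximum(p, 1e-300)).sum())


def _em_fit(y: np.ndarray, d1: float, g1: float, g2: float):
    """EM for a two-component exponential mixture; returns (d1, g1, g2, ll, ok)."""
    ll_old = -np.inf
    ok = False
    for _ in range(EM_MAX_ITER):
        p1 = d1 * g1 * np.exp(-g1 * y)
        p2 = (1 - d1) * g2 * np.exp(-g2 * y)
        tot = np.maximum(p1 + p2, 1e-300)
        r1 = p1 / tot
        w1 = r1.sum()
        w2 = y.size - w1
        if w1 < 1e-9 or w2 < 1e-9:
            break
        d1 = w1 / y.size
        g1 = w1 / max((r1 * y).sum(), 1e-300)
        g2 = w2 / max(((1 - r1) * y).sum(), 1e-300)
        ll = _mixture_loglik(y, d1, g1, g2)
        if abs(ll - ll_old) <= EM_TOL * abs(ll_old):
            ok = True
            break
        ll_old = ll
    return d1, g1, g2, _mixture_loglik(y, d1, g1, g2), ok


def fit_bis(envelope: np.ndarray, fs_env: float, freq: float) -> BiSFit:
    """Fit single- vs bi-exponential models to the normalized power series.

    The envelope is normalized by its RMS so the power R^2 has unit mean (a
    Gaussian narrowband null gives a unit-rate exponential), and the power is
    decimated to 2 samples per oscillation cycle so the BIC sample count is
    not inflated by within-cycle autocorrelation.  The mixture is fitted by EM
    from 10 spread starting points plus a near-degenerate start at the
    single-model solution (which guarantees loglik_bi >= loglik_single);
    components are ordered gamma1 < gamma2.
    """
    envelope = np.asarray(envelope, dtype=float)
    rms = np.sqrt(np.mean(envelope ** 2))
    if rms == 0:
        raise ValueError("zero envelope")
    dec = max(1, int(round(fs_env / (BIS_SAMPLES_PER_CYCLE * freq))))
    y = (envelope / rms)[::dec] ** 2
    n = y.size
    if n < BIS_MIN_SAMPLES:
        raise ValueError(f"need >= {BIS_MIN_SAMPLES} effective samples after decimation, got {n}")

    g_hat = 1.0 / y.mean()
    ll_single = n * np.log(g_hat) - g_hat * y.sum()
    bic_single = np.log(n) * 1 - 2 * ll_single

    # Restarts: rate ratios log-spaced 2..32 x weights {0.3, 0.7}, plus the
    # near-single start.  Each start matches the sample mean.
    starts = []
    for ratio in np.geomspace(2.0, 32.0, 5):
        for d1 in (0.3, 0.7):
            g1 = g_hat * (d1 + (1 - d1) / ratio)
            starts.append((d1, g1, ratio * g1))
    starts.append((0.5, g_hat * 0.999, g_hat * 1.001))

    best = None
    any_ok = False
    for d1, g1, g2 in starts:
        d1f, g1f, g2f, ll, ok = _em_fit(y, d1, g1, g2)
        any_ok = any_ok or ok
        if best is None or ll > best[3]:
            best = (d1f, g1f, g2f, ll)
    d1, g1, g2, ll_bi = best
    if not any_ok:
        # EM never converged: fall back to the single model, flagged.
        return BiSFit(g_hat, g_hat, g_hat, 1.0, 0.0, ll_single, ll_single, n,
                      bic_single, bic_single, 0.0, 0.0, em_converged=False)
    if ll_bi < ll_single:       # numerical safety; the nested start prevents this
        d1, g1, g2, ll_bi = 1.0, g_hat, g_hat, ll_single
    if g1 > g2:
        g1, g2 = g2, g1
        d1 = 1.0 - d1
    bic_bi = np.log(n) * 4 - 2 * ll_bi
    dbic = bic_single - bic_bi
    return BiSFit(float(g_hat), float(g1), float(g2), float(d1), float(1 - d1),
                  float(ll_single), float(ll_bi), n, float(bic_single),
                  float(bic_bi), float(dbic), bis_from_dbic(dbic))


# --------------------------------------------------------------------------
# full profile
# --------------------------------------------------------------------------

@dataclass
class CriticalityProfile:
    """Per channel x frequency criticality metrics with diagnostics."""

    freqs: np.ndarray
    channel_labels: list[str]
    dfa_exponent: np.ndarray
    dfa_r2: np.ndarray
    fei: np.ndarray
    fei_valid: np.ndarray
    bis: np.ndarray
    dbic: np.ndarray
    gamma1: np.ndarray
    gamma2: np.ndarray
    delta1: np.ndarray
    meta: dict = field(default_factory=dict)

    def to_dataframe(self, subject_id: str = "", visit: str = ""):
        """Long-format export: one row per channel x frequency."""
        import pandas as pd
        from .spectral import CANONICAL_BANDS

        rows = []
        for c, lab in enumerate(self.channel_labels):
            for k, f in enumerate(self.freqs):
                band = next((b for b, (lo, hi) in CANONICAL_BANDS.items()
                             if lo <= f <= hi), "")
                rows.append({
                    "subject": subject_id, "visit": visit, "channel": lab,
                    "freq_hz": f, "band": band,
                    "dfa": self.dfa_exponent[c, k], "dfa_r2": self.dfa_r2[c, k],
                    "fei": self.fei[c, k], "fei_valid": bool(self.fei_valid[c, k]),
                    "bis": self.bis[c, k], "dbic": self.dbic[c, k],
                    "gamma1": self.gamma1[c, k], "gamma2": self.gamma2[c, k],
                    "delta1": self.delta1[c, k],
                })
        return pd.DataFrame(rows)


def profile(decomp: NarrowbandDecomposition, min_valid_seconds: float = 60.0,
            compute_bis: bool = True) -> CriticalityProfile:
    """Apply DFA, fEI (gated on DFA) and BiS per channel x frequency.

    Channel-frequency cells whose valid duration falls below
    ``min_valid_seconds`` are left missing; missing values propagate, never
    silently imputed.
    """
    n_ch, n_fr = decomp.n_channels, decomp.n_freqs
    shape = (n_ch, n_fr)
    out = {k: np.full(shape, np.nan) for k in
           ("dfa_exponent", "dfa_r2", "fei", "bis", "dbic", "gamma1", "gamma2", "delta1")}
    fei_valid = np.zeros(shape, dtype=bool)
    env_all = decomp.envelope
    for k in range(n_fr):
        freq = decomp.freqs[k]
        mask = decomp.valid_mask[k]
        if mask.sum() / decomp.fs < min_valid_seconds:
            continue
        sl = slice(np.argmax(mask), len(mask) - np.argmax(mask[::-1]))
        inner_mask = mask[sl]
        for c in range(n_ch):
            env = env_all[c, k, sl]
            try:
                d = dfa(env, decomp.fs, freq=freq)
            except ValueError:
                continue
            if d.degenerate:
                continue
            out["dfa_exponent"][c, k] = d.exponent
            out["dfa_r2"][c, k] = d.fit_r2
            f = fei(env, freq, decomp.fs, d.exponent, valid_mask=inner_mask)
            out["fei"][c, k] = f.fei
            fei_valid[c, k] = f.valid
            if compute_bis:
                try:
                    b = fit_bis(env[inner_mask], decomp.fs, freq)
                except ValueError:
                    continue
                out["bis"][c, k] = b.bis
                out["dbic"][c, k] = b.dbic
                out["gamma1"][c, k] = b.gamma1
                out["gamma2"][c, k] = b.gamma2
                out["delta1"][c, k] = b.delta1
    return CriticalityProfile(
        freqs=decomp.freqs, channel_labels=list(decomp.channel_labels),
        fei_valid=fei_valid, **out,
    )
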