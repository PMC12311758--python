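"""DFA, fEI and BiS against brute-force oracles and generator ground truth."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegcrit.criticality import (
    bis_from_dbic,
    dfa,
    fei,
    fit_bis,
)
from eegcrit.synthetic import SignalSpec, fgn, gen_lrtc_oscillation


# --------------------------------------------------------------------------
# brute-force oracles (explicit loops, numpy only for storage)
# --------------------------------------------------------------------------

def dfa_bruteforce(envelope, fs, window_sizes, overlap=0.5):
    """Direct DFA with explicit loops and np.polyfit per window."""
    prof = np.cumsum(envelope - envelope.mean())
    fluct = []
    for w in window_sizes:
        n = max(4, int(round(w * fs)))
        step = max(1, int(round(n * (1 - overlap))))
        sq = []
        for start in range(0, prof.size - n + 1, step):
            seg = prof[start:start + n]
            t = np.arange(n)
            coef = np.polyfit(t, seg, 1)
            resid = seg - np.polyval(coef, t)
            sq.append(np.mean(resid ** 2))
        fluct.append(np.sqrt(np.mean(sq)))
    slope, _ = np.polyfit(np.log10(window_sizes), np.log10(fluct), 1)
    return slope, np.array(fluct)


def fei_windows_bruteforce(envelope, win, step):
    """Window statistics of the fEI operationalization, one window at a time."""
    w_amp, w_dnf = [], []
    for start in range(0, envelope.size - win + 1, step):
        seg = envelope[start:start + win]
        amp = seg.mean()
        prof = np.cumsum(seg / amp - 1.0)
        t = np.arange(win)
        coef = np.polyfit(t, prof, 1)
        resid = prof - np.polyval(coef, t)
        w_amp.append(amp)
        w_dnf.append(np.sqrt(np.mean(resid ** 2)))
    return np.array(w_amp), np.array(w_dnf)


# --------------------------------------------------------------------------
# DFA
# --------------------------------------------------------------------------

class TestDFA:
    def test_matches_bruteforce_exactly(self, rng):
        env = np.abs(rng.standard_normal(2000)) + 0.1
        sizes = np.geomspace(0.05, 0.4, 6)  # seconds at fs=500
        res = dfa(env, 500.0, window_sizes=sizes)
        slope, fluct = dfa_bruteforce(env, 500.0, sizes)
        np.testing.assert_allclose(res.fluctuation, fluct, rtol=1e-10)
        assert res.exponent == pytest.approx(slope, abs=1e-10)

    def test_iid_envelope_gives_half(self):
        """Temporally uncorrelated positive envelope: exponent 0.5 +/- 0.05."""
        est = []
        for seed in range(5):
            env = np.abs(np.random.default_rng(seed).standard_normal(60_000)) + 0.2
            est.append(dfa(env, 100.0, freq=8.0).exponent)
        assert np.mean(est) == pytest.approx(0.5, abs=0.05)

    def test_fgn_envelope_recovers_hurst(self):
        est = []
        for seed in range(5):
            env = np.exp(0.3 * fgn(60_000, 0.75, np.random.default_rng(seed)))
            est.append(dfa(env, 100.0, freq=8.0).exponent)
        assert np.mean(est) == pytest.approx(0.75, abs=0.05)

    def test_anticorrelated_envelope_below_half(self, rng):
        """Alternating construction has negative lag-1 correlation: exponent < 0.5."""
        base = np.abs(rng.standard_normal(60_000)) + 0.5
        env = base.copy()
        env[1::2] = 2.0 * base[1::2].mean() - base[1::2]  # mirror every other sample
        env = np.abs(env) + 0.05
        assert dfa(env, 100.0, freq=8.0).exponent < 0.5

    def test_constant_envelope_degenerate(self):
        res = dfa(np.full(50_000, 2.0), 100.0, freq=8.0)
        assert res.degenerate and np.isnan(res.exponent)

    def test_window_size_contract(self):
        env = np.abs(np.random.default_rng(0).standard_normal(5000)) + 0.1
        with pytest.raises(ValueError, match="increasing"):
            dfa(env, 100.0, window_sizes=np.array([1.0, 0.5, 2.0, 3.0, 4.0]))
        with pytest.raises(ValueError, match="largest window"):
            dfa(env, 100.0, window_sizes=np.geomspace(1.0, 40.0, 6))


# --------------------------------------------------------------------------
# fEI
# --------------------------------------------------------------------------

class TestFEI:
    def test_windows_match_bruteforce_exactly(self, rng):
        freq, fs = 8.0, 100.0
        win = int(round(40 * fs / freq))     # 500 samples
        step = int(round(win * 0.2))
        env = np.abs(rng.standard_normal(win + 44 * step)) + 0.3
        n_windows = (env.size - win) // step + 1
        assert n_windows <= 50
        w_amp, w_dnf = fei_windows_bruteforce(env, win, step)
        r = np.corrcoef(w_amp, w_dnf)[0, 1]
        res = fei(env, freq, fs, dfa_exponent=0.8)
        assert res.fei == pytest.approx(1.0 - r, abs=1e-10)
        assert res.n_windows == n_windows

    def test_dfa_gate_returns_missing(self, rng):
        env = np.abs(rng.standard_normal(20_000)) + 0.3
        res = fei(env, 8.0, 100.0, dfa_exponent=0.55)
        assert not res.valid and np.isnan(res.fei)

    def test_too_few_windows_missing(self, rng):
        env = np.abs(rng.standard_normal(1000)) + 0.3
        res = fei(env, 8.0, 100.0, dfa_exponent=0.8)
        assert not res.valid

    def test_windows_crossing_invalid_samples_dropped(self, rng):
        env = np.abs(rng.standard_normal(40_000)) + 0.3
        mask = np.ones(env.size, dtype=bool)
        mask[20_000:20_100] = False
        full = fei(env, 8.0, 100.0, 0.8)
        masked = fei(env, 8.0, 100.0, 0.8, valid_mask=mask)
        assert masked.n_windows < full.n_windows
        assert masked.n_dropped > 0


# --------------------------------------------------------------------------
# BiS
# --------------------------------------------------------------------------

class TestBiS:
    def test_bis_from_dbic_formula(self):
        assert bis_from_dbic(10.0) == pytest.approx(1.0)
        assert bis_from_dbic(1000.0) == pytest.approx(3.0)
        assert bis_from_dbic(0.0) == 0.0
        assert bis_from_dbic(-5.0) == 0.0

    def test_exponential_power_prefers_single_model(self):
        """Pure exponential power (Rayleigh envelope): BiS = 0 in most draws."""
        zeros = 0
        for seed in range(6):
            env = np.sqrt(np.random.default_rng(seed).exponential(size=3000))
            fit = fit_bis(env, fs_env=2.0, freq=1.0)
            zeros += fit.bis == 0.0
        assert zeros >= 5

    def test_two_state_mixture_recovered(self):
        """Power from a 50/50 mixture of exponentials with rate ratio 16
        yields a decisive mixture preference and correct parameters."""
        rng = np.random.default_rng(3)
        n = 5000
        comp = rng.random(n) < 0.5
        power = np.where(comp, rng.exponential(1.0, n), rng.exponential(16.0, n))
        env = np.sqrt(power)
        fit = fit_bis(env, fs_env=2.0, freq=1.0)
        assert fit.bis > 3.0
        assert fit.gamma2 / fit.gamma1 == pytest.approx(16.0, rel=0.25)
        assert fit.delta1 == pytest.approx(0.5, abs=0.1)
        assert fit.delta1 + fit.delta2 == pytest.approx(1.0, abs=1e-9)

    def test_nesting_loglik(self, rng):
        """The mixture never fits worse than the single model it nests."""
        for _ in range(5):
            env = np.abs(rng.standard_normal(1200)) + 0.01
            fit = fit_bis(env, fs_env=2.0, freq=1.0)
            assert fit.loglik_bi >= fit.loglik_single - 1e-6
            assert fit.bic_single == pytest.approx(
                np.log(fit.n_eff) * 1 - 2 * fit.loglik_single)
            assert fit.bic_double == pytest.approx(
                np.log(fit.n_eff) * 4 - 2 * fit.loglik_bi)

    def test_decimation_sets_n_eff(self):
        env = np.sqrt(np.random.default_rng(0).exponential(size=51_200))
        fit = fit_bis(env, fs_env=512.0, freq=8.0)   # 2 samples/cycle -> dec 32
        assert fit.n_eff == 1600

    def test_min_samples_error(self):
        with pytest.raises(ValueError, match="effective samples"):
            fit_bis(np.abs(np.random.default_rng(0).standard_normal(100)) + 0.1,
                    fs_env=2.0, freq=1.0)

    def test_bis_monotone_in_amp_ratio(self, wavelet_envelope):
        """Mean BiS is non-decreasing over amp_ratio 1 -> 2 -> 4."""
        from eegcrit.synthetic import gen_bistable_oscillation, gen_rayleigh_oscillation

        means = []
        for ratio in (1.0, 2.0, 4.0):
            vals = []
            for seed in range(8):
                spec = SignalSpec(center_freq=8.0, duration=200, fs=512,
                                  bistable=ratio > 1, amp_ratio=max(ratio, 1.5),
                                  seed=seed)
                if ratio == 1.0:
                    rec = gen_rayleigh_oscillation(spec)
                else:
                    rec = gen_bistable_oscillation(spec)
                env, f = wavelet_envelope(rec)
                vals.append(fit_bis(env, 512.0, f).bis)
            means.append(np.mean(vals))
        assert means[0] <= means[1] <= means[2]


# --------------------------------------------------------------------------
# shared invariants
# --------------------------------------------------------------------------

@settings(max_examples=10, deadline=None, derandomize=True)
@given(scale=st.floats(min_value=1e-3, max_value=1e3))
def test_scale_invariance_of_all_three_metrics(scale):
    """Multiplying the envelope by a positive constant changes nothing."""
    env = np.exp(0.3 * fgn(20_000, 0.7, np.random.default_rng(5)))
    a = dfa(env, 100.0, freq=8.0)
    b = dfa(env * scale, 100.0, freq=8.0)
    assert b.exponent == pytest.approx(a.exponent, abs=1e-9)
    fa = fei(env, 8.0, 100.0, 0.8)
    fb = fei(env * scale, 8.0, 100.0, 0.8)
    assert fb.fei == pytest.approx(fa.fei, abs=1e-9)
    ba = fit_bis(env, 100.0, 8.0)
    bb = fit_bis(env * scale, 100.0, 8.0)
    assert bb.bis == pytest.approx(ba.bis, abs=1e-9)


def test_profile_shapes_and_gating(wavelet_envelope, bank512):
    """Profile on a short LRTC recording fills one frequency row coherently."""
    from eegcrit.criticality import profile
    from eegcrit.spectral import transform

    rec = gen_lrtc_oscillation(SignalSpec(center_freq=8.0, duration=300, fs=512,
                                          hurst=0.75, seed=2))
    k = bank512.nearest_index(8.0)
    d = transform(rec, bank512, freq_indices=[k])
    prof = profile(d)
    assert prof.dfa_exponent.shape == (1, 1)
    assert prof.dfa_exponent[0, 0] == pytest.approx(0.75, abs=0.12)
    assert prof.fei_valid[0, 0]
    assert np.isfinite(prof.bis[0, 0])
    df = prof.to_dataframe("s1", "baseline")
    assert list(df.columns[:5]) == ["subject", "visit", "channel", "freq_hz", "band"]
    assert len(df) == 1
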