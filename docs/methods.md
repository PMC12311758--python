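# Methods

`eegcrit` assesses where cortical oscillatory dynamics sit relative to the
critical transition between asynchronous (subcritical) and hypersynchronous
(supercritical) regimes, from sensor-level resting-state EEG. Three
per-channel, per-frequency markers are computed on the amplitude envelope of
narrowband oscillations — the DFA scaling exponent (long-range temporal
correlations), the functional excitation–inhibition ratio fEI, and the
bistability index BiS — together with sensor-space phase-synchronization
networks (wPLI) and a cohort-statistics layer. Because clinical EEG of this
kind is rarely shareable, the package ships a synthetic-signal and
synthetic-cohort generator with exact ground truth for every estimator; all
calibration claims below are reproduced by `tests/test_acceptance.py` and
`scripts/acceptance.py`.

## Measurement chain

**Preprocessing** (fixed order): order-2 IIR notch at the line frequency
(50 Hz, Q = 30, applied forward–backward so it is zero-phase);
spherical-spline interpolation of operator-flagged bad channels; linear-phase
FIR bandpass 1–80 Hz (Kaiser window, order 1858, β = 5) applied on a
reflection-padded signal with the kernel centred, which compensates the group
delay exactly; spherical-spline surface Laplacian (Perrin-style scalp current
density, λ = 1e-5, spline order m = 4, Legendre series truncated at 50 terms
— terms decay as n⁻⁷ at m = 4, so truncation error is below 1e-6); selection
and concatenation of eyes-closed segments, recording splice points so that no
windowed metric ever straddles a splice. Zero-phase filtering is used
throughout because the phase metric (wPLI) must not inherit filter delay.
Subjects retaining less than 60 s of eyes-closed data are rejected. Whether a
channel is bad is metadata, not detected: the corresponding step in the
emulated workflow is visual inspection. The Laplacian output has only
approximately zero spatial mean (the electrode cap covers a cap, not the full
sphere); exact invariants are offset invariance and the vanishing of
channel-common signals.

**Spectral decomposition**: 30 log-spaced complex Morlet wavelets,
freqs[k] = 2·35^(k/29) Hz (2–70 Hz), m = 5 cycles, where m is the ratio of
center frequency to Gaussian bandwidth (σ_t = m/(2πf)). Wavelets are
L2-normalized; every downstream metric is invariant to envelope scale, so the
normalization only fixes units. Convolution is FFT-based on reflection-padded
data; a per-frequency validity mask removes 3σ_t per edge and around every
splice. A cautionary fact that shapes everything below: an m = 5 wavelet
cannot resolve amplitude modulation faster than ~f/5, so the measured
envelope is a band-limited version of the physical envelope.

**DFA**: cumulative sum of the mean-centred envelope, least-squares linear
detrend per window, F(n) = RMS residual aggregated over 50%-overlapping
windows, exponent = slope of log F vs log n. Fit range: 10 log-spaced window
sizes from 30 cycles of the wavelet frequency to 1/10 of the valid signal
length. The 30-cycle floor is a calibration of this chain: windows comparable
to the wavelet's amplitude-response width measure the wavelet, not the
signal, inflating the exponent by ~+0.1 at a 5-cycle floor, ~+0.03 at 20
cycles and ~+0.01 at 30. The cost is that frequency f needs roughly 300/f
seconds of signal for a usable fit range (delta-band DFA needs long
recordings). A constant envelope returns missing with a degenerate-input
flag.

**fEI**: windows of 40 cycles at 80% overlap, laid left to right with a final
partial window discarded; per window, wAmp = mean envelope, and wDNF = RMS of
the linearly detrended cumulative sum of (envelope/wAmp − 1);
fEI = 1 − Pearson r(wAmp, wDNF). Computed only where the DFA exponent
exceeds 0.6 — without long-range correlations, amplitude and fluctuation do
not covary and the ratio is uninformative — and returned missing when fewer
than 20 windows survive or more than 20% are dropped (zero amplitude or
splice overlap).

**BiS**: the normalized power R² = (envelope/RMS envelope)² is unit-mean, so
Gaussian narrowband noise yields a unit-rate exponential. The power series is
decimated to 2 samples per oscillation cycle before likelihood evaluation;
without this, the within-cycle autocorrelation of the envelope inflates the
BIC sample count n and makes the index scale with the sampling rate — this
choice (and the R² normalization) is the main source of cross-implementation
BiS differences. A single-exponential model (γ̂ = 1/mean, k = 1) and a
two-exponential mixture (EM, k = 4 as conventionally counted even though the
weight constraint δ₁+δ₂ = 1 leaves three free parameters) are compared by
BIC = ln(n)k − 2 ln L̂; BiS = log₁₀(BIC_exp − BIC_biexp) when positive, else
0. EM runs from 10 spread starts (rate ratios 2–32, weights 0.3/0.7) plus a
near-degenerate start at the single-model solution, which guarantees the
nesting inequality loglik_bi ≥ loglik_single; non-convergence of every start
falls back to the single model with a flag. Components are ordered γ₁ < γ₂.

**wPLI**: |E[Im X]| / E[|Im X|] with X the wavelet cross-spectrum over valid
samples (plain estimator, not the debiased-squared variant). A vanishing
denominator — identical or exactly zero-lag channels, where Im X is pure
rounding noise at ~1e-15 of |X| — returns missing; the test is relative
(denominator ≤ 1e-12·mean|X|). Band graphs average the per-frequency wPLI
matrices over in-band bank frequencies (matrix-first, for noise reduction),
then compute nodal strength, the Onnela geometric-mean weighted clustering
coefficient with weights normalized by the matrix maximum, and eigenvector
centrality by power iteration (tolerance 1e-10) scaled to unit maximum.
Missing matrix entries enter nodal sums as zero, with a per-graph missing
count. Canonical bands: delta 2–4, theta 5–7, alpha 8–13, beta 15–30, gamma
30–70 Hz; bank frequencies in the 4–5 and 7–8 Hz gaps belong to no band.

## Synthetic ground truth

**fGn core.** Fractional Gaussian noise is synthesized by circulant
(Davies–Harte) embedding — exact target covariance, verified in tests
against the closed form ρ(k) = (|k+1|^2H − 2|k|^2H + |k−1|^2H)/2 — so DFA
recovery has a provable reference.

**LRTC signal.** The log-envelope is fGn with the requested Hurst exponent,
generated on a half-cycle modulation grid (f_mod = 2·center_freq) and
interpolated to the sampling rate, then exponentiated (envelope =
exp(0.3·fGn), strictly positive and smooth). The coarse grid is not an
optimization: amplitude dynamics of a narrowband oscillation are physically
defined only down to ~cycle resolution, and a full-rate white log-envelope
puts >99% of its modulation power outside the wavelet band, leaving a
measured envelope uncorrelated with the ground truth. Carrier phase is the
integral of the center frequency plus a small diffusive jitter. Measured
calibration of the full chain (generator → wavelet → DFA, 500-s signals):
exponent 0.53 ± 0.03 at H = 0.5 and mean absolute error ≤ 0.04 for
H ∈ {0.6, 0.75, 0.9}.

**E/I signal.** The fGn log-envelope is split (on the modulation grid) into a
slow component at the 40-cycle fEI window scale and a fast residual; the fast
part is rescaled by g = 1 − ei_coupling·tanh(z) with z the standardized slow
level, normalized so E[g²] = 1. Negative coupling makes high-amplitude epochs
relatively more variable (fEI < 1, inhibition-dominated); positive coupling
the opposite. Two corrections make ei_coupling = 0 genuinely the no-coupling
condition: the gain normalization preserves the slow/fast power balance, and
a convexity-compensation term subtracts the running window-scale variance
(scaled by 2.0·σ/2) from the log-envelope — a log-normal envelope's window
mean otherwise rises with local variability, which alone yields a spurious
fEI ≈ 0.93. The factor 2.0 was calibrated once against the measured
amplitude–fluctuation correlation at zero coupling and validated on held-out
seeds (fEI = 1.01 ± 0.08). Strong negative coupling drags the measured DFA
exponent toward the 0.6 gate, so isolated replicates can be gated to missing;
summaries average the valid replicates, as the estimator contract prescribes.

**Bistable signal.** A two-state continuous-time Markov chain (rates r₁₂,
r₂₁) switches the envelope mean between 1 and amp_ratio; within each state
the envelope is the modulus of smoothed complex Gaussian noise (Rayleigh), so
the normalized power density is exactly a two-exponential mixture with
weights equal to the stationary occupancies r₂₁/(r₁₂+r₂₁), 1 − that, and
rate ratio amp_ratio⁻². Rates whose dwell times fall under two oscillation
cycles are rejected as unresolvable. A separate Rayleigh generator (no
switching) provides the single-exponential null. Calibration: BiS = 0 in
18/20 null replicates; BiS ≥ 3 in 20/20 replicates at amp_ratio 4 with 2-s
mean dwells over 300 s.

**Coupled pair.** Channel phases are 2πft + c·ψ₀ + (1−c)·ψ_k with independent
mean-reverting (OU) phase walks ψ (stationary SD 2 rad — nearly uniform on
the circle — relaxation 0.3 s, generated on a coarse grid, interpolated and
smoothed so the carrier stays strictly narrowband), plus a fixed offset on
channel 2; amplitudes are smooth log-normal fields blending from independent
(c = 0) to shared (c = 1). At c = 1 and lag π/2 the wavelet cross-spectrum is
single-signed and wPLI is exactly 1.0 in floating point; at lag 0 the
channels are bit-identical and wPLI is missing; at c = 0 the 500-s null level
is 0.03 ± 0.02.

**Cohort.** Four groups encode increasing latent severity
(HC = 0, ncRBD = 1, lRBD = 2, eRBD = 3), default sizes 46/41/10/8 matching
the emulated study's imbalance. Per-band signal parameters shift linearly
with severity; the defaults inject moderate (Cohen's d ≈ 0.6) HC-vs-patients
differences in delta/theta DFA, fEI and bistability, in the direction the
emulated study reports. Because no quantitative effect sizes are published
beyond a d > 0.5 shading, d ≈ 0.6 is a design choice, not a literature value.
Covariates: age ~ N(70, 7); sex with group-dependent male fraction; MMSE and
UPDRS-III with severity-dependent means; putamen/caudate SBR =
baseline − slope·severity + noise (slope 0.25, noise SD 0.3, baselines
2.8/3.4 — typical DaT-SPECT binding ratios). Converter groups receive a
follow-up visit with severity incremented by 1, mirroring partial follow-up.
Two paths: `render_signals=True` synthesizes multichannel EEG (one narrowband
component per configured band, channels as independent realizations of the
subject's parameters) for end-to-end pipeline runs; `render_signals=False`
emits band metrics directly from the latent parameters plus measurement noise
(SDs 0.05/0.08/0.30 for DFA/fEI/BiS) — the scale at which 300-cohort
statistics calibrations are feasible. The latent fEI is mapped as
1 + 0.5·ei_coupling, the 0.5 being the measured response of the fEI estimator
to this generator's coupling axis; the latent bistability is
2·log₁₀(amp_ratio), floored at 0.

What the generators do **not** emulate: 1/f broadband background, artifacts
(ocular, muscular, electrode), volume conduction and realistic sensor
covariance, non-stationary vigilance drift, or any biophysical
(neural-mass/branching) mechanism of criticality. Passing calibrations
therefore demonstrate estimator correctness on signals with known statistical
structure, not robustness to real-EEG nuisance structure.

## Statistics layer

Group contrasts are Gaussian GLMs (OLS) of channel-averaged band metrics on
group membership with age and sex (two-level factor, F reference) as
covariates; "RBD" pools the three patient groups. Cohen's d is computed on
the raw (unadjusted) group values with pooled SD and classified
small/medium/large at 0.2/0.5/0.8. The Bonferroni family is the five
canonical bands per metric (α_corrected = 0.01 at α = 0.05); with that family
definition the family-wise guarantee is per metric, not across the 15-test
battery jointly. Longitudinal contrasts fit the visit effect on subjects with
both visits. Brain–behavior models (SBR ~ band metric, clinical score ~ band
metric, fEI ~ nodal synchrony) are linear mixed models with a random subject
intercept, fitted by REML with Wald p-values; a singular fit falls back to
fixed effects with a flag. Demographics use Kruskal–Wallis (chi-square on
counts for sex); exploratory correlations use Spearman or Kendall rank
coefficients. Missing rows are dropped listwise with counts reported.

Monte-Carlo calibration is tested statistically, decided before any run:
the empirical family-wise error over 200 null cohorts is compared with the
one-sided 95% binomial bound at p = 0.05 (≤ 16/200) — a correctly calibrated
procedure fails a raw ≤ 0.05 check about half the time; 95% CI coverage over
100 replicates is compared with the one-sided 95% binomial lower bound at
p = 0.95 (≥ 89/100). Sign recovery, where power is essentially 1, is held to
the literal ≥ 95/100. The CI-coverage check applies to the injected group
shift (group is the regressor, so the GLM coefficient is unbiased for it);
the fEI→SBR mixed-model slope is checked in sign only, because measurement
noise on fEI attenuates its magnitude (errors-in-variables).

## Problem sizes

Calibration runs use 500-s single-channel signals at 512 Hz (20 replicates
per condition), 300-s signals for bistability, 200 null + 300 effect cohorts
on the table-only path, and a rendered 20-subject end-to-end cohort of
3-channel, 240-s recordings at 256 Hz with only the theta band rendered —
sizes chosen so the full suite runs on a laptop-class single core in a few
minutes while keeping Monte-Carlo error well inside every tolerance.

## Numerical choices and edge cases

EDF I/O is 16-bit with symmetric physical ranges padded so rounding never
clips; the 8-character header field limits fractional record durations, so
near-integer sampling rates are snapped on read. Annotations travel in a
plain-CSV sidecar. The packaged 10-10 montage is the idealized geometric
construction (ring at 72° inclination, 18° azimuth steps, coronal chains by
spherical interpolation), 61 labelled unit vectors. Power iteration ties and
all-zero graphs return missing eigencentrality. EM tolerance is 1e-8
relative log-likelihood, 500 iterations. The DFA log–log fit reports R²;
exponents are reported even when R² is low — filtering on fit quality is the
caller's decision.

## Known limitations

- The wavelet envelope's band-limit biases DFA upward by ~+0.01 even at the
  30-cycle fit floor; exponents from different m or fit floors are not
  directly comparable.
- BiS depends on the decimation rate and the effective n convention (see
  above); compare BiS values only within one convention.
- The E/I coupling axis is ordinal by construction: the imposed
  amplitude–fluctuation correlation is monotone in `ei_coupling` but not
  equal to it sample-for-sample.
- The bistable generator's measured mixture rate ratio is compressed
  relative to amp_ratio² by wavelet smoothing across state switches.
- The statistics layer assumes Gaussian responses; the bistability metric is
  zero-floored and mildly violates this, which matters for small groups.
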