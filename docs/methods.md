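# Methods

This note documents the models, parameter choices and numerical decisions
behind `rhythmarousal`, and what the synthetic-data validation does and does
not establish about real recordings.

## Photometry preprocessing

The chain operates per trial (the 15 min recording unit; trials shorter than
60 s are skipped with a warning).

**Bleach model.** Photobleaching is modeled as a single decaying exponential
`A·exp(−t/τ) + C`, fit by nonlinear least squares to the 0.1 Hz-low-passed
channel and subtracted from the **raw** channel. Initialization: `C` from the
trace minimum, `A` from the initial value, `τ` from the 1/e crossing. A flat
or rising trace falls back to `A = 0, C = mean` (the fit is also rejected in
favor of this fallback if it explains less variance than a constant). A
double-exponential was considered and deliberately not made the default: the
single exponential is identifiable on 15 min trials and matches the
generator; nothing in the code precludes fitting residual slow drift by a
second pass.

**Motion correction** is unscaled subtraction of the bleach-corrected
reference from the bleach-corrected signal. A least-squares-scaled variant
exists behind `scaled_motion=True` but is off by default — with artifacts
entering both channels at equal gain, plain subtraction cancels them exactly
and adds no estimation noise.

**Robust z-score.** `z = (x − median)/MAD`, with MAD carrying *no* 1.4826
normal-consistency constant; one z therefore equals one median absolute
deviation of the trial, not one standard deviation. The median/MAD are
computed per trial (the recording unit); a session-wide scope would couple
trials through slow state composition differences. Degenerate case: when the
motion-corrected trace is identically constant (exact cancellation; MAD = 0)
the divisor falls back to 1 so the null input maps to an identically zero
trace instead of 0/0.

**Filters.** All low- and high-passes are 4th-order Butterworth applied
forward-backward (`sosfiltfilt`): zero phase, −3 dB at the stated cutoff.
The final smoothing is 5 Hz; passing `final_cutoff_hz=None` exposes the
exactly-centered/scaled z for verification.

## Transient detection

Local maxima of the z-trace are gated by **topographic prominence** — the
peak value minus the higher of the two lowest levels separating it from the
nearest higher samples (or the trace ends) — and by width measured where the
trace crosses `peak − prominence/2`, linearly interpolated. Plateau maxima
report their leftmost sample. The implementation rests on
`scipy.signal.find_peaks`/`peak_prominences`/`peak_widths` (identical
definitions to the MATLAB peak finder commonly used for this analysis); an
exhaustive per-peak oracle in the test suite verifies exact equivalence on
random traces. Defaults (prominence ≥ 0.1 z, width ≥ 80 ms) are the
operating point used for scoring GCaMP transients in cleanly demodulated
recordings; both gates are parameters.

**Operating point for the synthetic validation.** The generator's noise is
white, and after z-scoring and 5 Hz smoothing its peaks reach prominences of
2–3.5 z, so the 0.1 z gate would pass thousands of noise peaks. A noise-only
calibration (prominence distribution of detections on zero-rate sessions)
places the validation operating point at **2.25 z** for transients generated
at 5× the raw noise SD (≈5.2 z after MAD scaling): noise false alarms fall
below ~1% of the expected event count while leaving >2× amplitude headroom.

**Dead time.** With the default kernel (difference of exponentials, 0.2 s
rise / 1.5 s decay — GCaMP6s-like; peak lag ≈ 0.47 s) two equal events
closer than ~1.5–2 s merge into a single detected peak, because the dip
between them never reaches the prominence gate. Counts therefore
undercount a Poisson process approximately paralyzably, `m = r·e^(−rD)`.
`resolvable_dead_time` measures the noiseless resolution by scanning the
two-kernel separation with the detector itself;
`validation.effective_dead_time` refines it by Monte-Carlo over the trace's
own noise (noise occasionally splits near-merged pairs, shortening the
effective dead time to ≈1.5 s at the reference SNR).
`transient_rate_by_state(..., dead_time_s=D)` inverts the paralyzable law
per state. This is an instrument-style calibration computed entirely from
the forward model (kernel, amplitude, noise level) — ground-truth event
times are never consulted.

**Per-state statistics** assign each peak to the hypnogram epoch containing
its clock-mapped peak time (peaks, not onsets, are what gets counted);
exposure time per state is the scored non-ARTIFACT time inside the analyzed
coverage (trial windows by default). Events peaking just across a state
boundary are charged to the neighboring state — visible as a small leak in
recoveries with sharply state-confined rates.

## Clock synchronization

TTL rising edges are thresholded at half the channel maximum, runs shorter
than 0.5 s rejected as glitches. Pulse trains are matched greedily
(nearest neighbor after coarse alignment by first pulses; ties to the
earlier index) and an affine map `t_EEG = offset + drift·t_phot` fit by
least squares; drift is the estimated relative clock rate, and values
outside (0.9, 1.1) are rejected as implausible. Sub-sample edge
interpolation is out of scope; with 30 pulses over 90 min, sample-rounded
edges at 400 Hz already constrain the offset to ~1 ms and drift to well
under 5 ppm.

## Sleep architecture and spectra

* **Bouts** are maximal runs of one non-ARTIFACT state **strictly longer**
  than 30 s, i.e. at least four 10 s epochs (a `>=` mode is available, as is
  merging NREM+REM into "sleep" runs).
* **%-state bins** count only non-ARTIFACT epochs; an all-ARTIFACT bin is
  NaN, so WAKE+NREM+REM always partition 100% where anything was scored.
* **Latency to arousal** requires NREM at stimulus onset (otherwise the
  trial is rejected) and runs to the start of the first WAKE epoch.
* **Welch PSDs** use Hann windows of 512 or 1024 points with 50% overlap
  (overlap and window family are conventional defaults, exposed as code but
  not as options), one-sided density scaling so the integral recovers the
  variance.
* **Spectrograms** are STFT power with a 30 s Hann window and 60% overlap,
  then smoothed along the *time* axis by a Hann-weighted rolling average of
  5 columns (axis and width are this package's choices; edge columns are
  renormalized so no power is lost).
* **Band power** integrates the PSD by the trapezoid rule with linearly
  interpolated band edges, so a flat density `c` yields exactly `c·(hi−lo)`.
* **EMG amplitude** is the per-epoch RMS of the 10 Hz-high-passed EMG
  (mean-rectified mode available); relative EMG amplitude divides window
  means by the mean over NREM epochs inside the pre-stimulus window and is
  undefined without NREM there.

## Patch-clamp analysis

Spikes are upward crossings of −20 mV with a 2 ms refractory hold-off —
parameters chosen for rendered action potentials that overshoot 0 mV, both
configurable. Spontaneous rate is the baseline spike count over the
baseline duration, requiring ≥30 s. f-I rates count spikes strictly inside
each 100 ms step (rate quantization is therefore 10 Hz per spike); steps
are ordered by current and may not overlap. Evoked analyses can be
restricted to cells with spontaneous rate > 0, reporting the retained
fraction.

## Behavior

Locomotor windows sum only bins lying fully inside the window; profiles
average across whole days with optional circular smoothing. "Significant
pre-tone vibration" is operationalized as pre-window RMS exceeding 3× the
session baseline RMS (the criterion is not standardized; the factor is a
parameter), and Vavg is the mean rectified platform voltage over the 100 ms
after tone onset.

## The synthetic generator

* **Hypnogram:** semi-Markov chain on the 10 s epoch grid; dwell per visit
  geometric with the configured mean (memoryless per epoch, the simplest law
  consistent with epoch-based scoring), then a jump by the transition row.
  Self-transitions are disallowed except explicit absorbing rows
  `{state: 1}`; states no other state can enter are rejected. Defaults:
  mean dwells WAKE 150 s / NREM 150 s / REM 70 s and a mouse-like topology
  (WAKE→NREM; NREM→WAKE 0.7 / REM 0.3; REM→WAKE 0.9 / NREM 0.1).
* **Photometry** is generated post-demodulation at 120 Hz (24× the final
  5 Hz cutoff); the raw-rate lock-in stage is out of scope. Transient times
  are Poisson per epoch at the state's rate, rendered as unit-peak
  difference-of-exponential kernels of amplitude `transient_amp_z·noise_sd`;
  ARTIFACT epochs generate no events (their truth would be unscorable
  anyway). Both channels share one bleach curve and identical biphasic
  motion pulses; each carries independent Gaussian noise. The reference
  channel contains zero transient energy by construction.
* **EEG/EMG:** band-filtered-noise mixing (delta 0.5–4, theta 5–9,
  broadband 10–30 Hz) with per-state weights — NREM delta-dominant, REM
  theta-dominant, WAKE broadband — and an EMG noise envelope WAKE ≫ NREM >
  REM, with the 0.5 Hz / 10 Hz acquisition high-passes applied. This is a
  spectral emulation, not biophysics: adequate for validating band-power
  and amplitude analyses, silent about waveform morphology (spindles,
  K-complexes, phase structure).
* **Patch traces:** Euler-integrated leaky integrate-and-fire at 20 kHz
  (rest −60 mV, threshold −40 mV, reset −55 mV, τ = 20 ms, R = 500 MΩ →
  rheobase 40 pA, 3 ms refractory), numba-accelerated; threshold crossings
  are replaced by a stereotyped 1 ms waveform overshooting 0 mV and logged
  as ground truth. Population heterogeneity enters through a normal
  spontaneous-drive distribution, N(30, 19.07²) pA by default, placing 30%
  of cells above rheobase.
* **Behavior:** Poisson beam-break counts with a 3× night/day rate ratio;
  startle traces with a decaying-oscillation response burst scaled by tone
  level and optional pre-tone contamination bursts flagged in ground truth.
* **Determinism:** every generator draws from `default_rng([seed, tag])`
  with a fixed per-modality tag; identical configs give bit-identical
  output.

Where the recording schedule needed concrete values they follow the
in vivo convention embedded in the defaults: 15 min trials with 15 min
breaks, six trials, 1 s TTLs every 3 min, 400 Hz EEG/EMG, 10 s scoring
epochs. Photometry noise has no published reference value; `noise_sd` was
set so that detection at the reference SNR is non-trivial (amplitude fixed
at 5× noise SD by the validation conditions).

## Validation protocol and its limits

The reference recovery experiment uses 40 min single-trial sessions
(20 seeds) rather than full six-trial days, keeping the suite fast while
leaving ≥150 expected WAKE events per seed so Poisson error bars are
meaningful. Sensitivity counts ground-truth events with a detection within
the detector's noiseless resolution (~1.9 s — events closer than that are
indistinguishable from one event by construction); the false-discovery
rate counts detections with no ground-truth event within the same window;
recovered rates are dead-time-corrected and compared to the realized
per-seed truth within 2 Poisson SE. At the reference conditions this yields
≈99.5% sensitivity, <1% FDR, and ≥90% of seeds within 2 SE for all states
with ≥2 min exposure.

Passing these tests shows the chain is internally correct and recovers
known parameters under the generator's assumptions — white noise, exact
exponential bleach, equal-gain motion coupling, stationary kinetics. Real
recordings violate all four to some degree (correlated noise,
multi-component bleach, wavelength-dependent motion gain, amplitude
heterogeneity), so detector operating points and the dead-time calibration
must be re-derived per dataset; the machinery for doing so
(`validation.effective_dead_time`, the noise-calibration approach) is part
of the package. The EEG generator validates spectral bookkeeping, not
sleep-scoring itself — scoring is consumed as input, never produced.
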