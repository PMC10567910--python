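"""Synthetic multi-modal recordings with known ground truth.

Every downstream stage of the pipeline is testable against data generated
here: semi-Markov hypnograms on the 10 s scoring grid; dual-channel
photometry with state-dependent GCaMP transients riding on a decaying
exponential photobleach, shared motion artifacts and Gaussian noise;
state-dependent EEG/EMG with the acquisition high-pass filters applied and
the shared TTL pulse train on a shifted/drifting clock; leaky
integrate-and-fire membrane traces under the −10..100 pA current-step
protocol; and beam-break/startle behavior.

Ground truth (event times, bleach parameters, the true clock map) is
returned alongside each artifact so recovery can be scored exactly.  All
generators are deterministic for a fixed :class:`SynthConfig` seed: each
modality draws from an independent stream derived from ``(seed, tag)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from scipy import signal as sps

from ._exceptions import ConfigError
from .behavior import LocomotorSeries, StartleTrial
from .ephys import CurrentProtocol, PatchRecording
from .photometry import PhotometrySession
from .sleep import ARTIFACT, NREM, REM, STATES, WAKE, EEGRecord, Hypnogram
from .sync import ClockMap

_TAG_HYPNOGRAM = 1
_TAG_PHOTOMETRY = 2
_TAG_EEG = 3
_TAG_PATCH = 4
_TAG_BEHAVIOR = 5


def _default_dwell() -> dict[str, float]:
    # mouse-scale mean bout dwells (seconds)
    return {WAKE: 150.0, NREM: 150.0, REM: 70.0}


def _default_transitions() -> dict[str, dict[str, float]]:
    return {
        WAKE: {NREM: 1.0},
        NREM: {WAKE: 0.7, REM: 0.3},
        REM: {WAKE: 0.9, NREM: 0.1},
    }


def _default_rates() -> dict[str, float]:
    # events/min: wake-dominant transients, sparse in NREM
    return {WAKE: 10.0, NREM: 1.0, REM: 5.0}


@dataclass
class SynthConfig:
    """All knobs of the synthetic study, with recording-schedule defaults.

    The schedule mirrors the in vivo sessions: 15 min photometry trials
    separated by 15 min breaks, six trials, a 1 s TTL every 3 min,
    photometry generated post-demodulation at 120 Hz, EEG/EMG at 400 Hz.
    """

    seed: int = 0
    epoch_s: float = 10.0
    state_mean_dwell_s: dict[str, float] = field(default_factory=_default_dwell)
    transition_probs: dict[str, dict[str, float]] = field(
        default_factory=_default_transitions
    )
    artifact_fraction: float = 0.0
    # photometry
    transient_rate_per_min: dict[str, float] = field(default_factory=_default_rates)
    transient_amp_z: float = 5.0
    transient_rise_s: float = 0.2
    transient_decay_s: float = 1.5
    bleach_amp: float = 5.0
    bleach_tau_s: float = 300.0
    bleach_offset: float = 2.0
    motion_rate_per_min: float = 0.5
    motion_amp: float = 0.5
    motion_width_s: float = 0.4
    noise_sd: float = 0.05
    photometry_fs_hz: float = 120.0
    eeg_fs_hz: float = 400.0
    trial_on_s: float = 900.0
    trial_off_s: float = 900.0
    n_trials: int = 6
    ttl_period_s: float = 180.0
    ttl_width_s: float = 1.0
    clock_offset_s: float = 0.0
    clock_drift_ppm: float = 0.0
    # behavior
    locomotor_day_rate: float = 2.0
    locomotor_night_ratio: float = 3.0
    locomotor_days: int = 2
    startle_n_trials: int = 15
    startle_response_mv: float = 50.0
    startle_noise_mv: float = 2.0
    startle_contamination_fraction: float = 0.0
    startle_fs_hz: float = 1000.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        nonneg = {
            "epoch_s": self.epoch_s, "transient_amp_z": self.transient_amp_z,
            "bleach_tau_s": self.bleach_tau_s, "motion_rate_per_min": self.motion_rate_per_min,
            "motion_amp": self.motion_amp, "noise_sd": self.noise_sd,
            "trial_on_s": self.trial_on_s, "trial_off_s": self.trial_off_s,
            "ttl_period_s": self.ttl_period_s, "ttl_width_s": self.ttl_width_s,
        }
        for name, val in nonneg.items():
            if val < 0:
                raise ConfigError(f"{name} must be non-negative, got {val}")
        if any(v < 0 for v in self.transient_rate_per_min.values()):
            raise ConfigError("transient rates must be non-negative")
        if any(v <= 0 for v in self.state_mean_dwell_s.values()):
            raise ConfigError("mean dwell times must be positive")
        if self.photometry_fs_hz <= 10:
            raise ConfigError("photometry_fs_hz must exceed 10 Hz (5 Hz Nyquist)")
        if self.eeg_fs_hz != 400:
            raise ConfigError("eeg_fs_hz is fixed at 400 Hz")
        if self.transient_decay_s <= self.transient_rise_s:
            raise ConfigError("transient_decay_s must exceed transient_rise_s")
        if not 0 <= self.artifact_fraction < 1:
            raise ConfigError("artifact_fraction must lie in [0, 1)")
        self._validate_transitions()

    def _validate_transitions(self) -> None:
        states = list(self.transition_probs)
        for s, row in self.transition_probs.items():
            total = sum(row.values())
            if any(p < 0 for p in row.values()):
                raise ConfigError(f"negative transition probability from {s}")
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"transition row for {s} must sum to 1")
            self_p = row.get(s, 0.0)
            if self_p not in (0.0,) and not (self_p == 1.0 and len(row) == 1):
                raise ConfigError(
                    f"self-transition for {s} must be 0 (dwell is geometric) "
                    "or an explicit absorbing row {state: 1.0}"
                )
            for t in row:
                if t not in states:
                    raise ConfigError(f"transition target {t} has no own row")
        if len(states) > 1:
            incoming = {s: 0.0 for s in states}
            for s, row in self.transition_probs.items():
                for t, p in row.items():
                    if t != s:
                        incoming[t] += p
            # a state no other state ever enters is unreachable once left
            unreachable = [s for s, p in incoming.items() if p == 0.0]
            if unreachable:
                raise ConfigError(f"unreachable state(s): {unreachable}")

    @property
    def session_duration_s(self) -> float:
        """Photometry-clock span of the trial schedule (last break omitted)."""
        return self.n_trials * self.trial_on_s + max(0, self.n_trials - 1) * self.trial_off_s

    def trial_windows(self) -> list[tuple[float, float]]:
        period = self.trial_on_s + self.trial_off_s
        return [(k * period, k * period + self.trial_on_s) for k in range(self.n_trials)]

    def true_clock_map(self) -> ClockMap:
        return ClockMap(
            offset_s=self.clock_offset_s,
            drift=1.0 + self.clock_drift_ppm * 1e-6,
        )

    def rng(self, tag: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(tag)])

    def with_seed(self, seed: int) -> "SynthConfig":
        return replace(self, seed=seed)


@dataclass
class GroundTruth:
    """Oracle record for parameter-recovery tests."""

    hypnogram: Hypnogram | None = None
    transient_times_s: np.ndarray | None = None  # kernel peak times, photometry clock
    transient_states: np.ndarray | None = None
    motion_times_s: np.ndarray | None = None
    bleach_params: tuple[float, float, float] | None = None
    spike_times_s: np.ndarray | None = None
    clock_map_true: tuple[float, float] | None = None  # (offset_s, drift_ppm)


# ---------------------------------------------------------------------------
# hypnogram


def generate_hypnogram(cfg: SynthConfig, duration_s: float) -> Hypnogram:
    """Semi-Markov hypnogram: geometric dwell (in epochs), then a jump.

    The dwell of every state visit is geometric with the configured mean,
    matching the memoryless-per-epoch character of epoch-based scoring;
    the next state is drawn from the transition row (self-transitions are
    disallowed except for explicit absorbing states).  ARTIFACT epochs are
    injected independently at ``cfg.artifact_fraction``.
    """
    n_epochs = duration_s / cfg.epoch_s
    if abs(n_epochs - round(n_epochs)) > 1e-9 or n_epochs < 1:
        raise ConfigError("duration_s must be a positive multiple of epoch_s")
    n_epochs = int(round(n_epochs))
    rng = cfg.rng(_TAG_HYPNOGRAM)
    states = list(cfg.transition_probs)
    for s in states:
        if s not in cfg.state_mean_dwell_s:
            raise ConfigError(f"no mean dwell configured for state {s}")
    state = states[int(rng.integers(len(states)))]
    labels: list[str] = []
    while len(labels) < n_epochs:
        mean_epochs = max(1.0, cfg.state_mean_dwell_s[state] / cfg.epoch_s)
        dwell = int(rng.geometric(1.0 / mean_epochs))
        labels.extend([state] * dwell)
        row = cfg.transition_probs[state]
        if row.get(state, 0.0) == 1.0:  # absorbing
            continue
        targets = list(row)
        probs = np.array([row[t] for t in targets])
        state = targets[int(rng.choice(len(targets), p=probs))]
    labels = labels[:n_epochs]
    if cfg.artifact_fraction > 0:
        art = rng.random(n_epochs) < cfg.artifact_fraction
        labels = [ARTIFACT if a else lab for lab, a in zip(labels, art)]
    return Hypnogram(labels=np.array(labels, dtype=object), epoch_s=cfg.epoch_s)


# ---------------------------------------------------------------------------
# photometry


def transient_kernel(cfg: SynthConfig, fs: float) -> tuple[np.ndarray, float]:
    """Unit-peak difference-of-exponentials kernel and its peak lag (s)."""
    tr, td = cfg.transient_rise_s, cfg.transient_decay_s
    t_peak = tr * td / (td - tr) * np.log(td / tr)
    length = int(np.ceil(6 * td * fs))
    t = np.arange(length) / fs
    k = np.exp(-t / td) - np.exp(-t / tr)
    return k / k.max(), float(t_peak)


def generate_photometry(
    cfg: SynthConfig, hyp: Hypnogram
) -> tuple[PhotometrySession, GroundTruth]:
    """Dual-channel demodulated photometry for the configured trial schedule.

    signal_465 = bleach + state-rate Poisson transients + motion + noise;
    reference_405 = identical bleach and motion + independent noise, with
    no transient energy at all.  Transient times are drawn per hypnogram
    epoch at that state's rate (ARTIFACT epochs produce none); the stored
    ground-truth times are kernel *peak* times on the photometry clock.
    """
    fs = cfg.photometry_fs_hz
    duration = cfg.session_duration_s
    cmap = cfg.true_clock_map()
    # the hypnogram (EEG clock) must cover the mapped photometry span
    if cmap.to_eeg(0.0) < hyp.t0_s - 1e-9 or cmap.to_eeg(duration) > hyp.end_s + 1e-9:
        raise ConfigError("hypnogram does not cover the mapped trial schedule")
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    rng = cfg.rng(_TAG_PHOTOMETRY)

    kernel, t_peak = transient_kernel(cfg, fs)
    amp = cfg.transient_amp_z * cfg.noise_sd
    transient_wave = np.zeros(n)
    peak_times: list[float] = []
    peak_states: list[str] = []
    for lab, e0 in zip(hyp.labels, hyp.epoch_starts_s()):
        rate = 0.0 if lab == ARTIFACT else cfg.transient_rate_per_min.get(lab, 0.0)
        if rate <= 0:
            continue
        p0 = float(cmap.to_photometry(e0))
        p1 = float(cmap.to_photometry(e0 + hyp.epoch_s))
        lo, hi = max(p0, 0.0), min(p1, duration)
        if hi <= lo:
            continue
        count = rng.poisson(rate / 60.0 * (hi - lo))
        onsets = np.sort(rng.uniform(lo, hi, size=count))
        for onset in onsets:
            if onset + t_peak >= duration:
                continue
            i0 = int(round(onset * fs))
            seg = min(len(kernel), n - i0)
            transient_wave[i0 : i0 + seg] += amp * kernel[:seg]
            peak_times.append(onset + t_peak)
            peak_states.append(lab)

    motion_wave = np.zeros(n)
    n_motion = rng.poisson(cfg.motion_rate_per_min / 60.0 * duration)
    motion_times = np.sort(rng.uniform(0, duration, size=n_motion))
    m_len = max(2, int(round(cfg.motion_width_s * fs)))
    pulse = cfg.motion_amp * np.sin(2 * np.pi * np.arange(m_len) / m_len)  # biphasic
    for mt in motion_times:
        i0 = int(round(mt * fs))
        seg = min(m_len, n - i0)
        if seg > 0:
            motion_wave[i0 : i0 + seg] += pulse[:seg]

    bleach = cfg.bleach_amp * np.exp(-t / cfg.bleach_tau_s) + cfg.bleach_offset
    sig = bleach + transient_wave + motion_wave
    ref = bleach + motion_wave
    if cfg.noise_sd > 0:
        sig = sig + rng.normal(0.0, cfg.noise_sd, size=n)
        ref = ref + rng.normal(0.0, cfg.noise_sd, size=n)

    ttl = np.arange(0.0, duration, cfg.ttl_period_s)
    session = PhotometrySession(
        time_s=t, signal_465=sig, reference_405=ref, fs=fs,
        ttl_onsets_s=ttl, trial_windows=cfg.trial_windows(),
    )
    truth = GroundTruth(
        hypnogram=hyp,
        transient_times_s=np.array(peak_times),
        transient_states=np.array(peak_states, dtype=object),
        motion_times_s=motion_times,
        bleach_params=(cfg.bleach_amp, cfg.bleach_tau_s, cfg.bleach_offset),
        clock_map_true=(cfg.clock_offset_s, cfg.clock_drift_ppm),
    )
    return session, truth


# ---------------------------------------------------------------------------
# EEG / EMG

_EEG_BANDS = ((0.5, 4.0), (5.0, 9.0), (10.0, 30.0))  # delta, theta, broadband
_EEG_WEIGHTS = {
    NREM: (1.0, 0.2, 0.1),
    REM: (0.15, 1.0, 0.1),
    WAKE: (0.35, 0.6, 0.5),
    ARTIFACT: (0.35, 0.6, 0.5),
}
_EMG_ENVELOPE = {WAKE: 1.0, NREM: 0.3, REM: 0.08, ARTIFACT: 1.0}


def generate_eeg_emg(cfg: SynthConfig, hyp: Hypnogram) -> EEGRecord:
    """State-dependent EEG/EMG by band-filtered noise mixing, plus the TTL.

    EEG mixes three band-limited noise carriers (delta 0.5–4 Hz, theta
    5–9 Hz, broadband 10–30 Hz) with per-state weights — delta-dominant in
    NREM, theta-dominant in REM, broadband/theta in WAKE.  EMG is white
    noise under a state envelope (WAKE ≫ NREM > REM atonia).  The
    acquisition filters (0.5 Hz EEG / 10 Hz EMG high-pass) are applied, and
    the TTL channel carries the photometry pulse train mapped through the
    configured clock offset and drift.
    """
    fs = cfg.eeg_fs_hz
    n = int(round(hyp.duration_s * fs))
    rng = cfg.rng(_TAG_EEG)
    carriers = []
    for lo, hi in _EEG_BANDS:
        sos = sps.butter(4, (lo, hi), btype="bandpass", fs=fs, output="sos")
        x = sps.sosfiltfilt(sos, rng.normal(size=n))
        carriers.append(x / np.std(x))
    weights = np.array(
        [[_EEG_WEIGHTS[lab][b] for b in range(3)] for lab in hyp.labels]
    )
    per_epoch = int(round(hyp.epoch_s * fs))
    w_samples = np.repeat(weights, per_epoch, axis=0)[:n]
    eeg = sum(w_samples[:, b] * carriers[b] for b in range(3)) * 50.0  # µV scale
    sos_hp = sps.butter(4, 0.5, btype="highpass", fs=fs, output="sos")
    eeg = sps.sosfiltfilt(sos_hp, eeg)

    env = np.repeat(
        np.array([_EMG_ENVELOPE[lab] for lab in hyp.labels]), per_epoch
    )[:n]
    emg = env * rng.normal(size=n) * 30.0
    sos_emg = sps.butter(4, 10.0, btype="highpass", fs=fs, output="sos")
    emg = sps.sosfiltfilt(sos_emg, emg)

    ttl = np.zeros(n)
    cmap = cfg.true_clock_map()
    onsets_phot = np.arange(0.0, cfg.session_duration_s, cfg.ttl_period_s)
    w_ttl = int(round(cfg.ttl_width_s * fs))
    for onset in cmap.to_eeg(onsets_phot):
        i0 = int(round((onset - hyp.t0_s) * fs))
        if 0 <= i0 < n:
            ttl[i0 : min(n, i0 + w_ttl)] = 5.0
    return EEGRecord(eeg=eeg, emg=emg, fs=fs, ttl=ttl)


# ---------------------------------------------------------------------------
# patch clamp (leaky integrate-and-fire)


@dataclass
class LIFParams:
    """Leaky integrate-and-fire membrane parameters.

    Defaults give rheobase (vth − el)/r_gohm = 40 pA, inside the
    −10..100 pA protocol range.  ``spontaneous_drive_pa`` is a constant
    background current; above rheobase it produces baseline firing.
    """

    el_mv: float = -60.0
    vth_mv: float = -40.0
    vreset_mv: float = -55.0
    tau_m_s: float = 0.02
    r_gohm: float = 0.5
    t_ref_s: float = 0.003
    noise_mv: float = 0.0  # stationary membrane-noise SD
    spontaneous_drive_pa: float = 0.0

    @property
    def rheobase_pa(self) -> float:
        return (self.vth_mv - self.el_mv) / self.r_gohm


@njit(cache=False)
def _lif_loop(current_pa, noise_steps, el, vth, vreset, tau, r_gohm, dt, ref_steps):
    n = current_pa.shape[0]
    v = np.empty(n)
    spike_idx = np.empty(n, dtype=np.int64)
    n_spikes = 0
    vi = el
    hold = 0
    for i in range(n):
        if hold > 0:
            vi = vreset
            hold -= 1
        else:
            vinf = el + r_gohm * current_pa[i]
            vi = vi + dt / tau * (vinf - vi) + noise_steps[i]
            if vi >= vth:
                spike_idx[n_spikes] = i
                n_spikes += 1
                vi = vreset
                hold = ref_steps
        v[i] = vi
    return v, spike_idx[:n_spikes]


def generate_patch_recording(
    cfg: SynthConfig,
    protocol: CurrentProtocol | None = None,
    lif: LIFParams | None = None,
    rng: np.random.Generator | None = None,
    fs: float = 20000.0,
) -> tuple[PatchRecording, GroundTruth]:
    """Simulate one cell under the current-step protocol.

    Euler-integrated leaky integrate-and-fire membrane at 20 kHz with
    optional membrane noise and constant spontaneous drive; threshold
    crossings are replaced by a stereotyped 1 ms spike waveform that
    overshoots 0 mV, and ground-truth crossing times are recorded.
    """
    protocol = protocol or CurrentProtocol()
    lif = lif or LIFParams()
    rng = rng or cfg.rng(_TAG_PATCH)
    n = int(round(protocol.total_duration_s * fs))
    dt = 1.0 / fs
    current = np.full(n, lif.spontaneous_drive_pa)
    sweeps = protocol.sweep_table()
    for i_pa, s0, d in sweeps:
        a, b = int(round(s0 * fs)), int(round((s0 + d) * fs))
        current[a:b] += i_pa
    if lif.noise_mv > 0:
        noise = rng.normal(0.0, lif.noise_mv * np.sqrt(2 * dt / lif.tau_m_s), size=n)
    else:
        noise = np.zeros(n)
    v, spike_idx = _lif_loop(
        current, noise, lif.el_mv, lif.vth_mv, lif.vreset_mv,
        lif.tau_m_s, lif.r_gohm, dt, int(round(lif.t_ref_s * fs)),
    )
    # render stereotyped spikes: 0.5 ms rise to +20 mV, 0.5 ms fall to reset
    half = max(1, int(round(0.0005 * fs)))
    up = np.linspace(lif.vth_mv, 20.0, half, endpoint=False)
    down = np.linspace(20.0, lif.vreset_mv, half)
    waveform = np.concatenate([up, down])
    for si in spike_idx:
        seg = min(len(waveform), n - si)
        v[si : si + seg] = waveform[:seg]
    rec = PatchRecording(
        vm_mv=v, fs=fs, sweeps=sweeps,
        baseline_duration_s=protocol.baseline_duration_s,
    )
    truth = GroundTruth(spike_times_s=spike_idx / fs)
    return rec, truth


def generate_cell_population(
    cfg: SynthConfig,
    n_cells: int,
    protocol: CurrentProtocol | None = None,
    drive_mean_pa: float = 30.0,
    drive_sd_pa: float = 19.07,
    noise_mv: float = 0.1,
) -> list[tuple[PatchRecording, GroundTruth]]:
    """Population with heterogeneous spontaneous drive.

    With the default LIF rheobase of 40 pA, a N(30, 19.07²) pA drive puts
    ~30% of cells above rheobase — the spontaneously firing minority to
    which evoked analyses are restricted.  Membrane noise is kept small:
    over a 30 s baseline even rare noise excursions fire a near-rheobase
    cell at least once, which would bias the firing fraction upward.
    """
    protocol = protocol or CurrentProtocol()
    rng = cfg.rng(_TAG_PATCH)
    out = []
    for _ in range(n_cells):
        drive = float(rng.normal(drive_mean_pa, drive_sd_pa))
        lif = LIFParams(noise_mv=noise_mv, spontaneous_drive_pa=drive)
        out.append(generate_patch_recording(cfg, protocol, lif, rng=rng))
    return out


# ---------------------------------------------------------------------------
# behavior


def generate_behavior(
    cfg: SynthConfig,
) -> tuple[LocomotorSeries, list[StartleTrial]]:
    """Beam-break counts (day/night Poisson rates) and startle trials.

    Locomotor counts are Poisson per 10 s bin at ``locomotor_day_rate``
    during CT0–12 and ``locomotor_night_ratio`` times that during CT12–24,
    for ``locomotor_days`` days.  Startle trials cycle through the 100/110/
    120 dB tones; a configurable fraction receives a pre-tone contamination
    burst (flagged in ``contaminated_truth``) that the exclusion rule
    should catch.
    """
    rng = cfg.rng(_TAG_BEHAVIOR)
    bins_per_h = int(round(3600.0 / 10.0))
    hours = np.arange(cfg.locomotor_days * 24 * bins_per_h) / bins_per_h
    ct = hours % 24.0
    rate = np.where(
        ct < 12.0, cfg.locomotor_day_rate,
        cfg.locomotor_day_rate * cfg.locomotor_night_ratio,
    )
    counts = rng.poisson(rate)
    series = LocomotorSeries(counts=counts, bin_s=10.0, t0_hours=0.0, lights="DD")

    trials: list[StartleTrial] = []
    fs = cfg.startle_fs_hz
    n = int(round(0.4 * fs))
    tone_onset = 0.2
    i_tone = int(round(tone_onset * fs))
    n_win = int(round(0.1 * fs))
    db_scale = {100: 0.5, 110: 1.0, 120: 1.5}
    for k in range(cfg.startle_n_trials):
        db = (100, 110, 120)[k % 3]
        trace = rng.normal(0.0, cfg.startle_noise_mv, size=n)
        if cfg.startle_response_mv > 0:
            resp_t = np.arange(n_win) / fs
            burst = (
                cfg.startle_response_mv * db_scale[db]
                * np.exp(-resp_t / 0.03)
                * np.sin(2 * np.pi * 40.0 * resp_t)
            )
            trace[i_tone : i_tone + n_win] += burst
        contaminated = bool(rng.random() < cfg.startle_contamination_fraction)
        if contaminated:
            pre_t = np.arange(n_win) / fs
            trace[i_tone - n_win : i_tone] += (
                10.0 * cfg.startle_noise_mv * np.sin(2 * np.pi * 25.0 * pre_t)
            )
        trials.append(
            StartleTrial(
                trace_mv=trace, fs=fs, tone_onset_s=tone_onset, tone_db=db,
                contaminated_truth=contaminated,
            )
        )
    return series, trials
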