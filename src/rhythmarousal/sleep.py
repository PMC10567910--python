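"""Hypnogram data model and EEG/EMG sleep-architecture analyses.

Vigilance states are scored visually in fixed 10 s epochs as WAKE, NREM or
REM; epochs contaminated by artifacts carry the ARTIFACT label and are
excluded from every quantitative summary.  This module provides the epoch
container plus the standard analyses built on it: bout extraction
(runs of one state longer than 30 s), percent-state time in arbitrary bins,
latency to arousal after a stimulus, Welch power spectral densities, STFT
spectrograms with rolling-Hann smoothing, band power, and EMG amplitude
normalized to the pre-stimulus NREM baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from ._exceptions import DataError, ParameterError, TrialRejectedError

WAKE = "WAKE"
NREM = "NREM"
REM = "REM"
ARTIFACT = "ARTIFACT"

#: the three scoreable vigilance states (ARTIFACT is an exclusion mark)
STATES = (WAKE, NREM, REM)

DELTA_BAND = (0.5, 4.0)
THETA_BAND = (5.0, 9.0)


@dataclass
class Hypnogram:
    """Sequence of vigilance-state labels on a fixed epoch grid.

    Parameters
    ----------
    labels
        One label per epoch, each in ``{WAKE, NREM, REM, ARTIFACT}``.
    epoch_s
        Epoch duration in seconds (10 s scoring granularity by default).
    t0_s
        Start time of the first epoch on the EEG clock.
    """

    labels: np.ndarray
    epoch_s: float = 10.0
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.size == 0:
            raise DataError("hypnogram needs at least one epoch")
        if self.epoch_s <= 0:
            raise ParameterError("epoch_s must be positive")
        bad = set(self.labels) - {WAKE, NREM, REM, ARTIFACT}
        if bad:
            raise DataError(f"unknown vigilance labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def duration_s(self) -> float:
        return len(self.labels) * self.epoch_s

    @property
    def end_s(self) -> float:
        return self.t0_s + self.duration_s

    def epoch_starts_s(self) -> np.ndarray:
        return self.t0_s + self.epoch_s * np.arange(len(self.labels))

    def epoch_index(self, t_s: float | np.ndarray) -> np.ndarray:
        """Index of the epoch containing time ``t_s`` (EEG clock).

        Times outside the scored span map to -1.
        """
        t = np.atleast_1d(np.asarray(t_s, dtype=float))
        idx = np.floor((t - self.t0_s) / self.epoch_s).astype(int)
        idx[(t < self.t0_s) | (t >= self.end_s)] = -1
        return idx

    def state_at(self, t_s: float | np.ndarray) -> np.ndarray:
        """Label of the epoch containing each time; None outside the span."""
        idx = self.epoch_index(t_s)
        out = np.empty(idx.shape, dtype=object)
        inside = idx >= 0
        out[inside] = self.labels[idx[inside]]
        out[~inside] = None
        return out

    def state_seconds(self, state: str) -> float:
        """Total scored time carrying ``state``, in seconds."""
        return float(np.sum(self.labels == state) * self.epoch_s)


@dataclass
class Bout:
    """Maximal run of a single vigilance state longer than the cutoff."""

    state: str
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class EEGRecord:
    """Raw EEG/EMG channels with the synchronization TTL channel."""

    eeg: np.ndarray
    emg: np.ndarray
    fs: float
    ttl: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=float)
        self.emg = np.asarray(self.emg, dtype=float)
        if self.eeg.shape != self.emg.shape:
            raise DataError("EEG and EMG channels must have equal length")
        if self.ttl is not None:
            self.ttl = np.asarray(self.ttl, dtype=float)
            if self.ttl.shape != self.eeg.shape:
                raise DataError("TTL channel length must match EEG")


@dataclass
class PSD:
    """One-sided Welch power spectral density."""

    freqs_hz: np.ndarray
    power: np.ndarray
    nfft: int

    def __post_init__(self) -> None:
        if np.any(self.power < 0):
            raise DataError("PSD power must be non-negative")


@dataclass
class Spectrogram:
    """Short-time Fourier power, time by frequency."""

    times_s: np.ndarray
    freqs_hz: np.ndarray
    power: np.ndarray  # shape (freqs, times)


def find_bouts(
    hyp: Hypnogram,
    min_duration_s: float = 30.0,
    sleep_mode: bool = False,
    strict: bool = True,
) -> list[Bout]:
    """Extract state bouts: maximal runs strictly longer than ``min_duration_s``.

    A bout is a maximal run of identical non-ARTIFACT labels.  With
    ``sleep_mode=True`` NREM and REM merge into a single "SLEEP" pseudo-state
    before run extraction.  ``strict`` keeps the literal ``>`` cutoff (a run
    of exactly 30 s is *not* a bout); set it to False for ``>=`` semantics.
    """
    labels = list(hyp.labels)
    if sleep_mode:
        labels = ["SLEEP" if lab in (NREM, REM) else lab for lab in labels]
    bouts: list[Bout] = []
    i = 0
    n = len(labels)
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        dur = (j - i) * hyp.epoch_s
        keep = dur > min_duration_s if strict else dur >= min_duration_s
        if labels[i] != ARTIFACT and keep:
            bouts.append(
                Bout(
                    state=labels[i],
                    start_s=hyp.t0_s + i * hyp.epoch_s,
                    end_s=hyp.t0_s + j * hyp.epoch_s,
                )
            )
        i = j
    return bouts


def percent_state_binned(hyp: Hypnogram, state: str, bin_s: float) -> np.ndarray:
    """Percent of scored (non-ARTIFACT) epochs in each bin carrying ``state``.

    ``bin_s`` must be a multiple of the epoch duration.  Bins that contain
    only ARTIFACT epochs are undefined and reported as NaN.  A trailing
    partial bin is evaluated over the epochs it does contain.
    """
    ratio = bin_s / hyp.epoch_s
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
        raise ParameterError("bin_s must be a positive multiple of epoch_s")
    per_bin = int(round(ratio))
    labels = hyp.labels
    n_bins = int(np.ceil(len(labels) / per_bin))
    out = np.full(n_bins, np.nan)
    for b in range(n_bins):
        chunk = labels[b * per_bin : (b + 1) * per_bin]
        scored = chunk != ARTIFACT
        if scored.any():
            out[b] = 100.0 * np.sum(chunk[scored] == state) / scored.sum()
    return out


def latency_to_arousal(hyp: Hypnogram, stim_onset_s: float) -> float:
    """Seconds from stimulus onset to the start of the first WAKE epoch.

    The trial is only valid if the animal is in NREM sleep at stimulus
    onset; otherwise it is rejected.  Returns NaN when no WAKE epoch follows
    within the scored record.
    """
    idx = int(hyp.epoch_index(stim_onset_s)[0])
    if idx < 0:
        raise TrialRejectedError("stimulus onset outside the scored record")
    if hyp.labels[idx] != NREM:
        raise TrialRejectedError(
            f"animal not in NREM at stimulus onset (was {hyp.labels[idx]})"
        )
    for j in range(idx, len(hyp.labels)):
        if hyp.labels[j] == WAKE:
            return hyp.t0_s + j * hyp.epoch_s - stim_onset_s
    return float("nan")


def welch_psd(
    x: np.ndarray,
    fs: float,
    nfft: int = 1024,
    allow_any_nfft: bool = False,
) -> PSD:
    """Welch PSD with Hann-windowed ``nfft``-sample segments, 50% overlap.

    ``nfft`` is restricted to the 512/1024 point sizes used for sleep EEG
    unless ``allow_any_nfft`` is set.
    """
    x = np.asarray(x, dtype=float)
    if not allow_any_nfft and nfft not in (512, 1024):
        raise ParameterError("nfft must be 512 or 1024 (or allow_any_nfft=True)")
    if len(x) < nfft:
        raise DataError(f"need at least nfft={nfft} samples, got {len(x)}")
    freqs, power = signal.welch(
        x, fs=fs, window="hann", nperseg=nfft, noverlap=nfft // 2,
        scaling="density", detrend=False,
    )
    return PSD(freqs_hz=freqs, power=power, nfft=nfft)


def spectrogram_stft(
    x: np.ndarray,
    fs: float,
    window_s: float = 30.0,
    overlap: float = 0.6,
    smooth_bins: int = 5,
) -> Spectrogram:
    """STFT power spectrogram with rolling-Hann temporal smoothing.

    Hann analysis windows of ``window_s`` seconds advance by
    ``window_s * (1 - overlap)``; the resulting power matrix is then
    smoothed along time with a Hann-weighted rolling average of
    ``smooth_bins`` columns (set 0/1 to disable).
    """
    x = np.asarray(x, dtype=float)
    if not 0.0 <= overlap <= 0.95:
        raise ParameterError("overlap must lie in [0, 0.95]")
    nperseg = int(round(window_s * fs))
    if len(x) < nperseg:
        raise DataError("signal shorter than one analysis window")
    hop = max(1, int(round(nperseg * (1.0 - overlap))))
    freqs, times, power = signal.spectrogram(
        x, fs=fs, window="hann", nperseg=nperseg,
        noverlap=nperseg - hop, mode="psd", detrend=False,
    )
    if smooth_bins and smooth_bins > 1 and power.shape[1] > 1:
        w = signal.windows.hann(smooth_bins, sym=True)
        if w.sum() == 0:  # hann(2) degenerates to zeros
            w = np.ones(smooth_bins)
        kernel = w / w.sum()
        # normalized convolution so edge columns keep unit total weight
        ones = np.ones(power.shape[1])
        norm = np.convolve(ones, kernel, mode="same")
        power = np.apply_along_axis(
            lambda row: np.convolve(row, kernel, mode="same") / norm, 1, power
        )
    return Spectrogram(times_s=times, freqs_hz=freqs, power=power)


def bandpower(psd: PSD, lo_hz: float, hi_hz: float) -> float:
    """Trapezoidal integral of the PSD over the [lo, hi] band (µV²).

    Band edges falling between frequency bins are handled by linear
    interpolation, so a flat density c integrates to exactly c·(hi−lo).
    """
    if not 0 <= lo_hz < hi_hz:
        raise ParameterError("band must satisfy 0 <= lo < hi")
    if hi_hz > psd.freqs_hz[-1] + 1e-12:
        raise ParameterError("band extends beyond the PSD frequency range")
    inner = (psd.freqs_hz > lo_hz) & (psd.freqs_hz < hi_hz)
    grid = np.concatenate(([lo_hz], psd.freqs_hz[inner], [hi_hz]))
    vals = np.interp(grid, psd.freqs_hz, psd.power)
    return float(np.trapezoid(vals, grid))


def emg_epoch_amplitude(
    emg: np.ndarray,
    fs: float,
    hyp: Hypnogram,
    highpass_hz: float = 10.0,
    mode: str = "rms",
) -> np.ndarray:
    """Per-epoch EMG amplitude: RMS (default) or mean-rectified value of the
    10 Hz high-passed EMG within each hypnogram epoch."""
    emg = np.asarray(emg, dtype=float)
    if highpass_hz > 0:
        sos = signal.butter(4, highpass_hz, btype="highpass", fs=fs, output="sos")
        emg = signal.sosfiltfilt(sos, emg)
    per_epoch = int(round(hyp.epoch_s * fs))
    n_epochs = min(len(hyp.labels), len(emg) // per_epoch)
    amps = np.full(len(hyp.labels), np.nan)
    for e in range(n_epochs):
        seg = emg[e * per_epoch : (e + 1) * per_epoch]
        if mode == "rms":
            amps[e] = np.sqrt(np.mean(seg**2))
        elif mode == "rectified":
            amps[e] = np.mean(np.abs(seg))
        else:
            raise ParameterError(f"unknown amplitude mode {mode!r}")
    return amps


def relative_emg_amplitude(
    emg: np.ndarray,
    fs: float,
    hyp: Hypnogram,
    windows: dict[str, tuple[float, float]],
    highpass_hz: float = 10.0,
    mode: str = "rms",
) -> dict[str, float]:
    """EMG amplitude per window normalized to the pre-window NREM baseline.

    ``windows`` maps names (conventionally ``pre``, ``stim``, ``post``) to
    (start_s, end_s) spans on the EEG clock.  The normalizer is the mean
    per-epoch amplitude over NREM epochs inside the ``pre`` window; if that
    window contains no NREM epoch every value is undefined (NaN).
    """
    if "pre" not in windows:
        raise ParameterError("windows must include a 'pre' baseline window")
    amps = emg_epoch_amplitude(emg, fs, hyp, highpass_hz=highpass_hz, mode=mode)
    starts = hyp.epoch_starts_s()

    def window_mask(w: tuple[float, float]) -> np.ndarray:
        lo, hi = w
        return (starts >= lo) & (starts + hyp.epoch_s <= hi) & np.isfinite(amps)

    pre_mask = window_mask(windows["pre"])
    baseline_mask = pre_mask & (hyp.labels == NREM)
    if not baseline_mask.any():
        return {name: float("nan") for name in windows}
    baseline = float(np.mean(amps[baseline_mask]))
    out: dict[str, float] = {}
    for name, w in windows.items():
        mask = window_mask(w) & (hyp.labels != ARTIFACT)
        out[name] = float(np.mean(amps[mask]) / baseline) if mask.any() else float("nan")
    return out
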