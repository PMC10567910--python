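"""Fiber-photometry preprocessing: bleach removal, motion correction,
robust z-scoring and final smoothing.

The chain operates per 15 min trial on the demodulated Ca²⁺-dependent
(465 nm excitation) and isosbestic reference (405 nm) channels:

1. low-pass each channel at 0.1 Hz and fit a single decaying exponential
   ``A·exp(−t/τ) + C`` to capture photobleaching;
2. subtract each fitted curve from its raw channel;
3. subtract the bleach-corrected reference from the bleach-corrected
   signal — motion artifacts hit both channels equally and cancel;
4. robust z-score: subtract the median, divide by the median absolute
   deviation (no normal-consistency constant);
5. zero-phase low-pass at 5 Hz.

All filters are 4th-order Butterworth applied forward-backward, so cutoffs
are −3 dB points and no phase is introduced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal

from ._exceptions import DataError, ParameterError


@dataclass
class PhotometrySession:
    """Dual-channel demodulated fluorescence with TTLs and trial windows."""

    time_s: np.ndarray
    signal_465: np.ndarray
    reference_405: np.ndarray
    fs: float
    ttl_onsets_s: np.ndarray = field(default_factory=lambda: np.array([]))
    trial_windows: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.signal_465 = np.asarray(self.signal_465, dtype=float)
        self.reference_405 = np.asarray(self.reference_405, dtype=float)
        self.ttl_onsets_s = np.asarray(self.ttl_onsets_s, dtype=float)
        n = len(self.time_s)
        if len(self.signal_465) != n or len(self.reference_405) != n:
            raise DataError("channel arrays must share one length")
        if n >= 2:
            dt = np.diff(self.time_s)
            if np.any(dt <= 0) or not np.allclose(dt, 1.0 / self.fs, rtol=1e-6):
                raise DataError("time must increase uniformly at 1/fs")
        if not self.trial_windows:
            self.trial_windows = [(float(self.time_s[0]), float(self.time_s[-1]) + 1.0 / self.fs)]
        ws = sorted(self.trial_windows)
        for (a0, a1), (b0, b1) in zip(ws, ws[1:]):
            if b0 < a1:
                raise DataError("trial windows must not overlap")


@dataclass
class BleachFit:
    """Single-exponential photobleach model ``A·exp(−t/τ) + C``."""

    amplitude: float
    tau_s: float
    offset: float
    rss: float = 0.0

    def __post_init__(self) -> None:
        if self.tau_s <= 0:
            raise ParameterError("bleach time constant must be positive")
        if self.rss < 0:
            raise ParameterError("residual sum of squares cannot be negative")

    def curve(self, time_s: np.ndarray) -> np.ndarray:
        t = np.asarray(time_s, dtype=float)
        return self.amplitude * np.exp(-(t - t[0]) / self.tau_s) + self.offset


@dataclass
class ZScoreTrace:
    """Robust-z-scored fluorescence, concatenated across trials.

    ``trial_slices`` keeps the per-trial sample boundaries so downstream
    hierarchical (per-trial) averaging remains possible.
    """

    time_s: np.ndarray
    z: np.ndarray
    fs: float
    trial_slices: list[tuple[int, int]] = field(default_factory=list)
    #: per-trial (median, MAD) of the motion-corrected trace before z-scoring
    trial_stats: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if len(self.time_s) != len(self.z):
            raise DataError("time and z must share one length")
        if len(self.z) and not np.all(np.isfinite(self.z)):
            raise DataError("z-trace contains non-finite values")
        if not self.trial_slices:
            self.trial_slices = [(0, len(self.z))]

    @property
    def duration_s(self) -> float:
        return len(self.z) / self.fs

    def trial_spans_s(self) -> list[tuple[float, float]]:
        """(start, end) seconds of each trial segment on the photometry clock."""
        return [
            (float(self.time_s[a]), float(self.time_s[b - 1]) + 1.0 / self.fs)
            for a, b in self.trial_slices
        ]


def lowpass(trace: np.ndarray, fs: float, cutoff_hz: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass; output length equals input length."""
    if not 0 < cutoff_hz < fs / 2:
        raise ParameterError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={fs / 2} Hz)"
        )
    x = np.asarray(trace, dtype=float)
    sos = signal.butter(order, cutoff_hz, btype="lowpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def robust_zscore(x: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Median/MAD z-score; returns (z, median, mad).

    The MAD carries no 1.4826 consistency constant.  A degenerate trace
    (MAD = 0, e.g. the exact-cancellation null) falls back to a unit
    divisor so the output stays finite (and zero for an all-constant input).
    """
    x = np.asarray(x, dtype=float)
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    denom = mad if mad > 0 else 1.0
    return (x - med) / denom, med, mad


def fit_bleach(trace_lp: np.ndarray, time_s: np.ndarray) -> BleachFit:
    """Least-squares single-exponential fit to a 0.1 Hz-low-passed trace.

    Initialization: offset from the trace minimum, amplitude from the
    initial value, time constant from the 1/e crossing.  A flat or rising
    trace falls back to a zero-amplitude fit around the mean.
    """
    x = np.asarray(trace_lp, dtype=float)
    t = np.asarray(time_s, dtype=float)
    if len(x) < 10:
        raise DataError("need at least 10 samples to fit a bleach curve")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(t))):
        raise DataError("non-finite values in bleach-fit input")
    t0 = t - t[0]
    span = float(t0[-1]) if t0[-1] > 0 else 1.0

    def flat_fallback() -> BleachFit:
        c = float(np.mean(x))
        return BleachFit(amplitude=0.0, tau_s=span, offset=c,
                         rss=float(np.sum((x - c) ** 2)))

    a0 = float(x[0] - x.min())
    if a0 <= 0 or x[0] <= x[-1]:
        return flat_fallback()
    c0 = float(x.min())
    below = np.flatnonzero(x - c0 <= a0 / np.e)
    tau0 = float(t0[below[0]]) if below.size else span
    tau0 = min(max(tau0, 1e-3), 10 * span)

    def model(tt, a, tau, c):
        return a * np.exp(-tt / tau) + c

    try:
        popt, _ = optimize.curve_fit(
            model, t0, x, p0=[a0, tau0, c0],
            bounds=([0.0, 1e-6, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError):
        return flat_fallback()
    a, tau, c = (float(v) for v in popt)
    rss = float(np.sum((x - model(t0, a, tau, c)) ** 2))
    fit = BleachFit(amplitude=a, tau_s=tau, offset=c, rss=rss)
    if fit.rss > np.sum((x - np.mean(x)) ** 2):  # worse than a constant
        return flat_fallback()
    return fit


def preprocess(
    session: PhotometrySession,
    bleach_cutoff_hz: float = 0.1,
    final_cutoff_hz: float | None = 5.0,
    min_trial_s: float = 60.0,
    scaled_motion: bool = False,
) -> ZScoreTrace:
    """Full preprocessing chain; returns the concatenated per-trial z-trace.

    ``final_cutoff_hz=None`` skips the last smoothing step (useful to verify
    the exact median-0 / MAD-1 property of step 4).  ``scaled_motion``
    replaces plain reference subtraction with a least-squares-scaled
    subtraction (off by default, matching the unscaled formulation).
    Trials shorter than ``min_trial_s`` are skipped with a warning.
    """
    fs = session.fs
    times: list[np.ndarray] = []
    zs: list[np.ndarray] = []
    slices: list[tuple[int, int]] = []
    stats: list[tuple[float, float]] = []
    n_done = 0
    for (w0, w1) in session.trial_windows:
        mask = (session.time_s >= w0) & (session.time_s < w1)
        n = int(mask.sum())
        if n / fs < min_trial_s:
            warnings.warn(
                f"trial window ({w0}, {w1}) shorter than {min_trial_s} s; skipped",
                stacklevel=2,
            )
            continue
        t = session.time_s[mask]
        sig = session.signal_465[mask]
        ref = session.reference_405[mask]

        sig_fit = fit_bleach(lowpass(sig, fs, bleach_cutoff_hz), t)
        ref_fit = fit_bleach(lowpass(ref, fs, bleach_cutoff_hz), t)
        det_sig = sig - sig_fit.curve(t)
        det_ref = ref - ref_fit.curve(t)
        if scaled_motion:
            denom = float(det_ref @ det_ref)
            beta = float(det_sig @ det_ref) / denom if denom > 0 else 0.0
            corrected = det_sig - beta * det_ref
        else:
            corrected = det_sig - det_ref
        z, med, mad = robust_zscore(corrected)
        if final_cutoff_hz is not None:
            z = lowpass(z, fs, final_cutoff_hz)
        times.append(t)
        zs.append(z)
        slices.append((n_done, n_done + n))
        stats.append((med, mad))
        n_done += n
    if not zs:
        raise DataError("no trial window long enough to preprocess")
    return ZScoreTrace(
        time_s=np.concatenate(times), z=np.concatenate(zs), fs=fs,
        trial_slices=slices, trial_stats=stats,
    )
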