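"""Ca²⁺ transient detection by topographic prominence and per-state statistics.

Transient peaks are local maxima of the z-scored fluorescence gated by a
minimum topographic prominence (0.1 z by default) and a minimum width at
half-prominence (80 ms by default).  Topographic prominence is the peak
value minus the higher of the two lowest saddle levels separating the peak
from the nearest higher samples (or from the trace ends).  Among the
samples of a flat plateau maximum the leftmost is reported as the peak.

Per-state statistics assign each detected peak to the vigilance-state epoch
that contains its clock-mapped peak time; ARTIFACT epochs contribute
neither events nor exposure time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from ._exceptions import DataError, ParameterError
from .photometry import ZScoreTrace
from .sleep import ARTIFACT, STATES, Hypnogram
from .sync import ClockMap


@dataclass
class Transient:
    """One detected Ca²⁺ transient peak."""

    peak_time_s: float
    peak_z: float
    prominence: float
    width_s: float


@dataclass
class TransientSet:
    """Detected transients in one z-trace, ordered by peak time."""

    peak_time_s: np.ndarray
    peak_z: np.ndarray
    prominence: np.ndarray
    width_s: np.ndarray
    trace_duration_s: float
    fs: float

    def __post_init__(self) -> None:
        for name in ("peak_time_s", "peak_z", "prominence", "width_s"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if len(self.peak_time_s) > 1 and np.any(np.diff(self.peak_time_s) <= 0):
            raise DataError("peak times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.peak_time_s)

    def __iter__(self):
        for i in range(len(self)):
            yield Transient(
                peak_time_s=float(self.peak_time_s[i]),
                peak_z=float(self.peak_z[i]),
                prominence=float(self.prominence[i]),
                width_s=float(self.width_s[i]),
            )


def detect_transients(
    z: ZScoreTrace | np.ndarray,
    fs: float | None = None,
    min_width_s: float = 0.08,
    min_prominence: float = 0.1,
) -> TransientSet:
    """Detect transient peaks gated by prominence and half-prominence width.

    Accepts either a :class:`~rhythmarousal.photometry.ZScoreTrace` or a
    bare array plus ``fs``.  Peaks whose prominence falls below
    ``min_prominence`` or whose width at the half-prominence reference
    level (linear interpolation at the crossings) falls below
    ``min_width_s`` are discarded.  Defaults are the 0.1 z / 80 ms operating
    point used for scoring GCaMP transients.
    """
    if isinstance(z, ZScoreTrace):
        x, fs_, time_s = z.z, z.fs, z.time_s
    else:
        if fs is None:
            raise ParameterError("fs is required when passing a bare array")
        x, fs_ = np.asarray(z, dtype=float), float(fs)
        time_s = np.arange(len(x)) / fs_
    if min_width_s <= 0 or min_prominence <= 0:
        raise ParameterError("thresholds must be positive")
    if len(x) == 0:
        return TransientSet(
            peak_time_s=np.array([]), peak_z=np.array([]),
            prominence=np.array([]), width_s=np.array([]),
            trace_duration_s=0.0, fs=fs_,
        )
    peaks, props = signal.find_peaks(x, plateau_size=1)
    if len(peaks) == 0:
        return TransientSet(
            peak_time_s=np.array([]), peak_z=np.array([]),
            prominence=np.array([]), width_s=np.array([]),
            trace_duration_s=len(x) / fs_, fs=fs_,
        )
    prominences, left_bases, right_bases = signal.peak_prominences(x, peaks)
    widths_samples, _, _, _ = signal.peak_widths(
        x, peaks, rel_height=0.5,
        prominence_data=(prominences, left_bases, right_bases),
    )
    widths_s = widths_samples / fs_
    keep = (prominences >= min_prominence) & (widths_s >= min_width_s)
    left_edges = props["left_edges"][keep]  # leftmost plateau sample
    return TransientSet(
        peak_time_s=time_s[left_edges],
        peak_z=x[left_edges],
        prominence=prominences[keep],
        width_s=widths_s[keep],
        trace_duration_s=len(x) / fs_,
        fs=fs_,
    )


def resolvable_dead_time(
    kernel: np.ndarray,
    fs: float,
    threshold_frac: float,
    min_width_s: float = 0.08,
) -> float:
    """Smallest separation at which two equal transients are both detected.

    ``kernel`` is the unit-peak transient waveform; ``threshold_frac`` is
    the detector's prominence gate expressed as a fraction of the event
    amplitude.  Two superimposed kernels closer than the returned dead
    time merge into a single detection (the riding peak's topographic
    prominence falls below the gate), so an observed count underestimates
    a Poisson event rate r paralyzably: m = r·exp(−r·D).  Computed by
    scanning the separation on the sample grid with the detector itself.
    """
    k = np.asarray(kernel, dtype=float)
    pad = len(k) + int(fs)
    lo, hi = 1, len(k)
    # bisect the smallest lag (samples) giving two detections
    def resolved(lag: int) -> bool:
        x = np.zeros(2 * len(k) + lag + 2 * pad)
        x[pad : pad + len(k)] += k
        x[pad + lag : pad + lag + len(k)] += k
        ts = detect_transients(
            x, fs=fs, min_width_s=min_width_s, min_prominence=threshold_frac
        )
        return len(ts) >= 2

    if resolved(lo):
        return lo / fs
    if not resolved(hi):
        return hi / fs
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if resolved(mid):
            hi = mid
        else:
            lo = mid
    return hi / fs


def correct_rate_for_dead_time(observed_rate_per_min: float, dead_time_s: float) -> float:
    """Invert the paralyzable dead-time law m = r·exp(−r·D) (rates per min)."""
    if dead_time_s <= 0 or not np.isfinite(observed_rate_per_min):
        return observed_rate_per_min
    m = observed_rate_per_min / 60.0  # per second
    d = dead_time_s
    if m <= 0:
        return observed_rate_per_min
    peak = 1.0 / (np.e * d)  # maximum observable rate under the law
    if m >= peak:
        return 60.0 / d  # saturated; return the censoring-limited rate
    from scipy.optimize import brentq

    r = brentq(lambda rr: rr * np.exp(-rr * d) - m, m, 1.0 / d, xtol=1e-12)
    return float(r * 60.0)


def _state_exposure_minutes(
    hyp: Hypnogram,
    coverage_eeg_s: list[tuple[float, float]],
) -> dict[str, float]:
    """Minutes of each non-ARTIFACT state overlapping the covered spans."""
    starts = hyp.epoch_starts_s()
    minutes = {s: 0.0 for s in STATES}
    for lab, e0 in zip(hyp.labels, starts):
        if lab == ARTIFACT:
            continue
        e1 = e0 + hyp.epoch_s
        overlap = sum(
            max(0.0, min(e1, c1) - max(e0, c0)) for c0, c1 in coverage_eeg_s
        )
        minutes[lab] += overlap / 60.0
    return minutes


def _assign_states(
    times_phot_s: np.ndarray, hyp: Hypnogram, clock_map: ClockMap | None
) -> np.ndarray:
    cmap = clock_map or ClockMap.identity()
    mapped = cmap.to_eeg(times_phot_s)
    states = hyp.state_at(mapped)
    n_out = int(np.sum([s is None for s in states]))
    if n_out:
        warnings.warn(
            f"{n_out} transient(s) mapped outside the hypnogram span; excluded",
            stacklevel=3,
        )
    return states


def transient_rate_by_state(
    ts: TransientSet,
    hyp: Hypnogram,
    clock_map: ClockMap | None = None,
    coverage_s: list[tuple[float, float]] | None = None,
    dead_time_s: float = 0.0,
) -> dict[str, float]:
    """Transient frequency (events/min) per vigilance state.

    Each peak is assigned to the state of the epoch containing its mapped
    peak time.  The denominator is the state's scored (non-ARTIFACT) time
    within the analyzed coverage — by default the full trace span,
    otherwise the supplied photometry-clock windows (e.g. trial windows).
    States with zero exposure are undefined (NaN).

    A positive ``dead_time_s`` applies the paralyzable dead-time
    correction (see :func:`resolvable_dead_time`) to each state's rate,
    compensating the undercount from transients too close to resolve.
    """
    cmap = clock_map or ClockMap.identity()
    if coverage_s is None:
        coverage_s = [(0.0, ts.trace_duration_s)]
    coverage_eeg = [tuple(cmap.to_eeg(np.array(w))) for w in coverage_s]
    minutes = _state_exposure_minutes(hyp, coverage_eeg)
    states = _assign_states(ts.peak_time_s, hyp, clock_map)
    out: dict[str, float] = {}
    for s in STATES:
        if minutes[s] <= 0:
            out[s] = float("nan")
        else:
            count = int(np.sum(states == s))
            out[s] = correct_rate_for_dead_time(count / minutes[s], dead_time_s)
    return out


def transient_prominence_by_state(
    ts: TransientSet,
    hyp: Hypnogram,
    clock_map: ClockMap | None = None,
) -> dict[str, float]:
    """Mean transient prominence per state; NaN where a state has no event."""
    states = _assign_states(ts.peak_time_s, hyp, clock_map)
    out: dict[str, float] = {}
    for s in STATES:
        mask = states == s
        out[s] = float(np.mean(ts.prominence[mask])) if mask.any() else float("nan")
    return out


def zscore_by_state(
    z: ZScoreTrace,
    hyp: Hypnogram,
    clock_map: ClockMap | None = None,
    per_trial: bool = False,
) -> dict[str, float]:
    """Mean z over all samples in scored epochs of each state.

    With ``per_trial=True`` the mean is computed hierarchically: first
    within each trial segment, then across trials (the per-animal averaging
    unit of six 15 min trials); states absent from a trial contribute
    nothing to that trial.
    """
    cmap = clock_map or ClockMap.identity()
    mapped = cmap.to_eeg(z.time_s)
    idx = hyp.epoch_index(mapped)
    labels = np.empty(len(mapped), dtype=object)
    inside = idx >= 0
    labels[inside] = hyp.labels[idx[inside]]
    labels[~inside] = None

    def segment_means(sl: tuple[int, int]) -> dict[str, float]:
        a, b = sl
        seg_lab, seg_z = labels[a:b], z.z[a:b]
        means = {}
        for s in STATES:
            mask = seg_lab == s
            means[s] = float(np.mean(seg_z[mask])) if mask.any() else float("nan")
        return means

    if not per_trial:
        return segment_means((0, len(z.z)))
    per = [segment_means(sl) for sl in z.trial_slices]
    out: dict[str, float] = {}
    for s in STATES:
        vals = [m[s] for m in per if np.isfinite(m[s])]
        out[s] = float(np.mean(vals)) if vals else float("nan")
    return out
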