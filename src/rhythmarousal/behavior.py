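"""Locomotor-activity summaries and acoustic-startle quantification.

Home-cage locomotion is recorded as infrared beam-break counts in 10 s
bins, summarized as window totals (e.g. CT0–12 vs CT12–24) and as a 24 h
profile averaged across days.  Acoustic startle is quantified as Vavg, the
mean rectified platform voltage over the 100 ms following the tone; trials
with significant vibration in the 100 ms *before* the tone are excluded
(operationalized as pre-window RMS above a multiple of the session
baseline RMS).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._exceptions import DataError, ParameterError


@dataclass
class LocomotorSeries:
    """Beam-break counts on a contiguous 10 s bin grid.

    ``t0_hours`` is the circadian/zeitgeber hour of the first bin (ZT0 =
    lights-on under LD; CT inherited from prior entrainment under DD).
    """

    counts: np.ndarray
    bin_s: float = 10.0
    t0_hours: float = 0.0
    lights: str = "DD"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise DataError("beam-break counts cannot be negative")
        if self.lights not in ("LD", "DD"):
            raise ParameterError("lights must be 'LD' or 'DD'")

    @property
    def bins_per_hour(self) -> int:
        return int(round(3600.0 / self.bin_s))

    @property
    def duration_h(self) -> float:
        return len(self.counts) * self.bin_s / 3600.0

    def bin_hours(self) -> np.ndarray:
        """Clock hour (unwrapped) at the start of each bin."""
        return self.t0_hours + np.arange(len(self.counts)) * self.bin_s / 3600.0


@dataclass
class StartleTrial:
    """One startle trial: platform voltage around a single tone."""

    trace_mv: np.ndarray
    fs: float
    tone_onset_s: float
    tone_db: int = 110
    vavg_mv: float = float("nan")
    excluded: bool = False
    contaminated_truth: bool | None = None  # set by the synthetic generator

    def __post_init__(self) -> None:
        self.trace_mv = np.asarray(self.trace_mv, dtype=float)
        if self.tone_db not in (100, 110, 120):
            raise ParameterError("tone_db must be one of 100, 110, 120")


def locomotor_totals(
    series: LocomotorSeries,
    windows: list[tuple[float, float]],
) -> dict[tuple[float, float], int]:
    """Total beam breaks per (start_h, end_h) window.

    Only bins lying fully inside a window count; a window reaching outside
    the recorded span is an error.
    """
    hours = series.bin_hours()
    bin_h = series.bin_s / 3600.0
    out: dict[tuple[float, float], int] = {}
    for (h0, h1) in windows:
        if h0 < series.t0_hours - 1e-9 or h1 > series.t0_hours + series.duration_h + 1e-9:
            raise ParameterError(f"window ({h0}, {h1}) outside the recorded span")
        mask = (hours >= h0 - 1e-9) & (hours + bin_h <= h1 + 1e-9)
        out[(h0, h1)] = int(np.sum(series.counts[mask]))
    return out


def locomotor_profile(
    series: LocomotorSeries,
    smooth_bins: int = 0,
) -> np.ndarray:
    """Mean 24 h activity profile across recorded days (one value per bin).

    Requires at least 24 h of data; an optional centered moving average of
    ``smooth_bins`` bins smooths the profile (circularly, since clock time
    wraps).
    """
    per_day = series.bins_per_hour * 24
    n_days = len(series.counts) // per_day
    if n_days < 1:
        raise DataError("need at least 24 h of data for a daily profile")
    days = np.asarray(series.counts[: n_days * per_day], dtype=float)
    profile = days.reshape(n_days, per_day).mean(axis=0)
    # rotate so index 0 is hour 0 of the circadian day
    shift = int(round((series.t0_hours % 24.0) * series.bins_per_hour))
    profile = np.roll(profile, shift)
    if smooth_bins and smooth_bins > 1:
        kernel = np.ones(smooth_bins) / smooth_bins
        ext = np.concatenate([profile[-(smooth_bins // 2):], profile,
                              profile[: smooth_bins // 2]])
        profile = np.convolve(ext, kernel, mode="valid")[: per_day]
    return profile


def startle_vavg(
    trial: StartleTrial,
    pre_window_s: float = 0.1,
    response_window_s: float = 0.1,
    exclusion_factor: float = 3.0,
    session_baseline_rms: float | None = None,
) -> tuple[float, bool]:
    """Vavg over the post-tone window plus the pre-tone exclusion flag.

    Vavg is the mean rectified voltage over ``(tone, tone + 0.1 s]``.  The
    trial is excluded when the RMS of the 100 ms pre-tone window exceeds
    ``exclusion_factor`` times the session baseline RMS
    (``session_baseline_rms`` if given, otherwise the RMS of the trace
    before the pre-tone window, falling back to the pre-window itself).
    The trial object is updated in place and (vavg, excluded) returned.
    """
    fs = trial.fs
    i_tone = int(round(trial.tone_onset_s * fs))
    n_pre = int(round(pre_window_s * fs))
    n_post = int(round(response_window_s * fs))
    if i_tone - n_pre < 0 or i_tone + n_post > len(trial.trace_mv):
        raise DataError("trace does not span the pre-tone and response windows")
    pre = trial.trace_mv[i_tone - n_pre : i_tone]
    post = trial.trace_mv[i_tone : i_tone + n_post]
    vavg = float(np.mean(np.abs(post)))
    pre_rms = float(np.sqrt(np.mean(pre**2)))
    if session_baseline_rms is None:
        base = trial.trace_mv[: i_tone - n_pre]
        session_baseline_rms = (
            float(np.sqrt(np.mean(base**2))) if len(base) else pre_rms
        )
    excluded = bool(pre_rms > exclusion_factor * session_baseline_rms)
    trial.vavg_mv = vavg
    trial.excluded = excluded
    return vavg, excluded
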