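"""Patch-clamp firing analysis: spike detection, spontaneous rate, f-I curves.

Current-clamp recordings are sampled at 20 kHz.  The protocol records a
baseline of at least 30 s (used for the spontaneous firing rate) followed
by 100 ms current steps from −10 to 100 pA delivered every 2 s.  Spikes are
detected as upward crossings of a fixed voltage threshold with a 2 ms
refractory window; evoked rates count spikes strictly inside each step.
Population analyses of evoked responses are restricted to spontaneously
firing cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._exceptions import DataError, ProtocolError


@dataclass
class CurrentProtocol:
    """Current-step protocol: which currents, when, and for how long."""

    currents_pa: tuple[float, ...] = tuple(range(-10, 101, 10))
    step_duration_s: float = 0.1
    period_s: float = 2.0
    step_offset_s: float = 0.5  # step onset within each period
    baseline_duration_s: float = 30.0

    def __post_init__(self) -> None:
        if self.step_duration_s <= 0 or self.period_s <= 0:
            raise ProtocolError("step and period durations must be positive")
        if self.step_duration_s > self.period_s:
            raise ProtocolError("step cannot outlast its period")

    def sweep_table(self) -> list[tuple[float, float, float]]:
        """(current_pA, step_start_s, step_duration_s) per sweep, after baseline."""
        return [
            (i_pa, self.baseline_duration_s + k * self.period_s + self.step_offset_s,
             self.step_duration_s)
            for k, i_pa in enumerate(self.currents_pa)
        ]

    @property
    def total_duration_s(self) -> float:
        return self.baseline_duration_s + len(self.currents_pa) * self.period_s


@dataclass
class PatchRecording:
    """One cell's continuous membrane-potential trace plus its sweep table."""

    vm_mv: np.ndarray
    fs: float
    sweeps: list[tuple[float, float, float]] = field(default_factory=list)
    baseline_duration_s: float = 30.0

    def __post_init__(self) -> None:
        self.vm_mv = np.asarray(self.vm_mv, dtype=float)
        if self.fs <= 0:
            raise ProtocolError("sampling rate must be positive")


@dataclass
class SpikeTrain:
    """Strictly increasing spike times honoring the refractory window."""

    spike_times_s: np.ndarray

    def __post_init__(self) -> None:
        self.spike_times_s = np.asarray(self.spike_times_s, dtype=float)
        if len(self.spike_times_s) > 1 and np.any(np.diff(self.spike_times_s) <= 0):
            raise DataError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.spike_times_s)

    def count_in(self, t0_s: float, t1_s: float) -> int:
        t = self.spike_times_s
        return int(np.sum((t >= t0_s) & (t < t1_s)))


@dataclass
class FICurve:
    """Firing rate versus injected current, ordered by current."""

    currents_pa: np.ndarray
    rates_hz: np.ndarray

    def __post_init__(self) -> None:
        self.currents_pa = np.asarray(self.currents_pa, dtype=float)
        self.rates_hz = np.asarray(self.rates_hz, dtype=float)
        if len(self.currents_pa) != len(self.rates_hz):
            raise DataError("currents and rates must share one length")
        if np.any(self.rates_hz < 0):
            raise DataError("firing rates cannot be negative")


def detect_spikes(
    vm_mv: np.ndarray,
    fs: float,
    threshold_mv: float = -20.0,
    refractory_s: float = 0.002,
) -> SpikeTrain:
    """Upward threshold crossings with a refractory window.

    A spike is the first sample at or above ``threshold_mv`` after a
    sub-threshold sample; subsequent crossings within ``refractory_s`` are
    ignored.  Rendered spike waveforms cross the default −20 mV threshold
    comfortably, so the detector is insensitive to its exact value.
    """
    if fs < 1000:
        raise ProtocolError("spike detection requires fs >= 1 kHz")
    v = np.asarray(vm_mv, dtype=float)
    if not np.all(np.isfinite(v)):
        raise DataError("membrane trace contains non-finite samples")
    above = v >= threshold_mv
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if len(above) and above[0]:
        crossings = np.concatenate(([0], crossings))
    kept: list[int] = []
    last = -np.inf
    min_gap = refractory_s * fs
    for c in crossings:
        if c - last >= min_gap:
            kept.append(int(c))
            last = c
    return SpikeTrain(spike_times_s=np.asarray(kept, dtype=float) / fs)


def spontaneous_rate(
    rec: PatchRecording,
    threshold_mv: float = -20.0,
    refractory_s: float = 0.002,
) -> float:
    """Spontaneous firing rate (Hz) over the ≥30 s baseline window."""
    if rec.baseline_duration_s < 30.0:
        raise ProtocolError(
            f"baseline of {rec.baseline_duration_s} s is shorter than the "
            "30 s required to measure spontaneous firing"
        )
    n_base = int(round(rec.baseline_duration_s * rec.fs))
    train = detect_spikes(rec.vm_mv[:n_base], rec.fs, threshold_mv, refractory_s)
    return len(train) / rec.baseline_duration_s


def f_i_curve(
    rec: PatchRecording,
    threshold_mv: float = -20.0,
    refractory_s: float = 0.002,
) -> FICurve:
    """Evoked firing rate per current step (spikes in step ÷ step duration)."""
    if not rec.sweeps:
        raise ProtocolError("recording carries no current-step sweeps")
    ordered_by_time = sorted(rec.sweeps, key=lambda s: s[1])
    for (_, s0, d0), (_, s1, _) in zip(ordered_by_time, ordered_by_time[1:]):
        if s1 < s0 + d0:
            raise ProtocolError("current steps overlap in time")
    train = detect_spikes(rec.vm_mv, rec.fs, threshold_mv, refractory_s)
    rows = sorted(rec.sweeps, key=lambda s: s[0])
    currents = [s[0] for s in rows]
    rates = [train.count_in(s[1], s[1] + s[2]) / s[2] for s in rows]
    return FICurve(currents_pa=np.array(currents), rates_hz=np.array(rates))


def restrict_to_spontaneous(
    cells: list[PatchRecording],
    threshold_mv: float = -20.0,
) -> tuple[list[PatchRecording], float]:
    """Keep cells with spontaneous rate > 0 Hz; report the retained fraction.

    Evoked-response analyses are restricted to this subset, mirroring the
    observation that only a minority of recorded cells fire spontaneously.
    """
    kept = [c for c in cells if spontaneous_rate(c, threshold_mv) > 0]
    fraction = len(kept) / len(cells) if cells else float("nan")
    return kept, fraction
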