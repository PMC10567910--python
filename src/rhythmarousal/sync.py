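"""Clock alignment between the photometry and EEG acquisition systems.

The photometry console emits a 1 s TTL pulse every 3 min which is recorded
by both systems.  Rising edges of that pulse train, detected on each clock,
are matched pairwise and a least-squares affine map

    t_eeg = offset + drift * t_photometry

is fit.  The affine model strictly generalizes a pure offset: with only two
pulses available the drift is held at 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._exceptions import AlignmentError, ParameterError


@dataclass
class ClockMap:
    """Affine map from the photometry clock to the EEG clock."""

    offset_s: float
    drift: float = 1.0
    residual_rms_s: float = 0.0

    def __post_init__(self) -> None:
        if not 0.9 < self.drift < 1.1:
            raise AlignmentError(
                f"implausible clock drift {self.drift}: expected within (0.9, 1.1)"
            )
        if self.residual_rms_s < 0:
            raise AlignmentError("residual RMS cannot be negative")

    def to_eeg(self, t_phot_s):
        """Map photometry-clock seconds onto the EEG clock."""
        return self.offset_s + self.drift * np.asarray(t_phot_s, dtype=float)

    def to_photometry(self, t_eeg_s):
        """Inverse map: EEG-clock seconds back onto the photometry clock."""
        return (np.asarray(t_eeg_s, dtype=float) - self.offset_s) / self.drift

    @classmethod
    def identity(cls) -> "ClockMap":
        return cls(offset_s=0.0, drift=1.0, residual_rms_s=0.0)


def detect_ttl_onsets(
    channel: np.ndarray,
    fs: float,
    min_width_s: float = 0.5,
) -> np.ndarray:
    """Rising-edge times of TTL pulses at least ``min_width_s`` wide.

    The trace is thresholded at half its maximum; contiguous supra-threshold
    runs shorter than ``min_width_s`` are rejected as glitches.  Returns a
    strictly increasing array of onset seconds (empty when no pulse exists).
    """
    if fs <= 2:
        raise ParameterError("sampling rate must exceed 2 Hz")
    x = np.asarray(channel, dtype=float)
    if x.size == 0 or np.max(x) <= 0:
        return np.array([], dtype=float)
    high = x >= 0.5 * np.max(x)
    padded = np.concatenate(([False], high, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, stops = edges[::2], edges[1::2]
    widths_s = (stops - starts) / fs
    onsets = starts[widths_s >= min_width_s] / fs
    return onsets.astype(float)


def _match_pulses(
    onsets_phot: np.ndarray, onsets_eeg: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Greedy nearest-neighbor pairing after coarse offset by first pulses.

    Each photometry pulse claims the nearest unclaimed EEG pulse; ties are
    broken toward the earlier EEG index.
    """
    coarse = onsets_eeg[0] - onsets_phot[0]
    shifted = onsets_phot + coarse
    claimed: dict[int, int] = {}
    for i, t in enumerate(shifted):
        d = np.abs(onsets_eeg - t)
        order = np.argsort(d, kind="stable")  # stable sort -> earlier index on ties
        for j in order:
            if int(j) not in claimed:
                claimed[int(j)] = i
                break
    eeg_idx = np.array(sorted(claimed), dtype=int)
    phot_idx = np.array([claimed[j] for j in eeg_idx], dtype=int)
    return phot_idx, eeg_idx


def fit_clock_map(
    onsets_photometry: np.ndarray, onsets_eeg: np.ndarray
) -> ClockMap:
    """Least-squares affine clock map from matched TTL pulse pairs.

    Requires at least two pulses per train; trains whose pulse counts differ
    by more than one cannot be aligned.  With exactly two matched pulses the
    drift is estimated from the single interval; residual RMS is reported in
    EEG-clock seconds.
    """
    p = np.sort(np.asarray(onsets_photometry, dtype=float))
    e = np.sort(np.asarray(onsets_eeg, dtype=float))
    if len(p) < 2 or len(e) < 2:
        raise AlignmentError("need at least two TTL pulses on each clock")
    if abs(len(p) - len(e)) > 1:
        raise AlignmentError(
            f"pulse counts differ by more than one ({len(p)} vs {len(e)})"
        )
    phot_idx, eeg_idx = _match_pulses(p, e)
    if len(phot_idx) < 2:
        raise AlignmentError("fewer than two matched pulse pairs")
    xp, ye = p[phot_idx], e[eeg_idx]
    drift, offset = np.polyfit(xp, ye, 1)
    residuals = ye - (offset + drift * xp)
    rms = float(np.sqrt(np.mean(residuals**2)))
    return ClockMap(offset_s=float(offset), drift=float(drift), residual_rms_s=rms)
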