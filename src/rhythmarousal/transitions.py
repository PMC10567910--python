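"""Consolidated sleep/wake transitions and transition-triggered photometry.

Four transition kinds are tracked: NREM→WAKE, WAKE→NREM, NREM→REM and
REM→WAKE.  A boundary qualifies only when the flanking 15 s on each side
(rounded up to whole 10 s epochs, i.e. 2 epochs) consist purely of the
source and target state respectively — consolidation excludes fragmented
switching and any ARTIFACT epoch in either flank.

Transition-triggered traces cut the z-scored fluorescence around each
retained boundary (after clock mapping), normalize every event row to its
own maximum, and average across events for heatmap/mean-trace display.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._exceptions import DataError, ParameterError
from .photometry import ZScoreTrace
from .sleep import ARTIFACT, NREM, REM, WAKE, Hypnogram
from .sync import ClockMap

#: transition kinds quantified for arousal analysis, as (source, target)
TRACKED_KINDS: tuple[tuple[str, str], ...] = (
    (NREM, WAKE),
    (WAKE, NREM),
    (NREM, REM),
    (REM, WAKE),
)


def kind_name(kind: tuple[str, str]) -> str:
    return f"{kind[0]}->{kind[1]}"


@dataclass
class TransitionEvent:
    """One retained state boundary (time on the EEG clock)."""

    kind: tuple[str, str]
    time_s: float
    pre_ok: bool = True
    post_ok: bool = True


@dataclass
class TransitionTraceSet:
    """Event-by-sample matrix of max-normalized z rows around transitions."""

    window_s: tuple[float, float]
    offsets_s: np.ndarray
    traces: np.ndarray  # shape (events, samples), each row max-normalized
    mean_trace: np.ndarray
    sem_trace: np.ndarray
    unnormalized_rows: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    n_dropped: int = 0

    @property
    def n_events(self) -> int:
        return self.traces.shape[0]


def find_transitions(
    hyp: Hypnogram,
    consolidation_s: float = 15.0,
    kinds: tuple[tuple[str, str], ...] = TRACKED_KINDS,
    both_sides: bool = True,
) -> list[TransitionEvent]:
    """Retain tracked state boundaries with consolidated flanks.

    The flank length is ``consolidation_s`` rounded **up** to whole epochs
    (15 s on a 10 s grid → 2 epochs per side).  The epochs before the
    boundary must all carry the source state and — unless
    ``both_sides=False`` — the epochs after must all carry the target
    state; an ARTIFACT epoch in a checked flank disqualifies the boundary.
    """
    if consolidation_s <= 0:
        raise ParameterError("consolidation_s must be positive")
    n_flank = math.ceil(consolidation_s / hyp.epoch_s)
    labels = hyp.labels
    events: list[TransitionEvent] = []
    for i in range(1, len(labels)):
        src, tgt = labels[i - 1], labels[i]
        if src == tgt or (src, tgt) not in kinds:
            continue
        if i - n_flank < 0 or i + n_flank > len(labels):
            continue
        pre_ok = bool(np.all(labels[i - n_flank : i] == src))
        post_ok = bool(np.all(labels[i : i + n_flank] == tgt))
        if pre_ok and (post_ok or not both_sides):
            events.append(
                TransitionEvent(
                    kind=(src, tgt),
                    time_s=hyp.t0_s + i * hyp.epoch_s,
                    pre_ok=pre_ok,
                    post_ok=post_ok,
                )
            )
    return events


def transition_triggered(
    z: ZScoreTrace,
    events: list[TransitionEvent],
    clock_map: ClockMap | None = None,
    window_s: tuple[float, float] = (15.0, 15.0),
) -> TransitionTraceSet:
    """Cut, max-normalize and average z-trace windows around transitions.

    Each event time (EEG clock) is mapped back onto the photometry clock
    and snapped to the nearest sample; the window must lie entirely inside
    one contiguous trial segment, otherwise the event is dropped and
    counted in ``n_dropped``.  Rows are divided by their own maximum; rows
    whose maximum is ≤ 0 are left unnormalized and listed in
    ``unnormalized_rows``.  The SEM is NaN when fewer than two events
    survive.
    """
    cmap = clock_map or ClockMap.identity()
    pre_s, post_s = window_s
    if pre_s < 0 or post_s < 0:
        raise ParameterError("window lengths must be non-negative")
    n_pre = int(round(pre_s * z.fs))
    n_post = int(round(post_s * z.fs))
    rows: list[np.ndarray] = []
    unnormalized: list[int] = []
    n_dropped = 0
    for ev in events:
        t_phot = float(cmap.to_photometry(ev.time_s))
        placed = False
        for a, b in z.trial_slices:
            seg_t = z.time_s[a:b]
            if not (seg_t[0] <= t_phot <= seg_t[-1]):
                continue
            center = a + int(round((t_phot - seg_t[0]) * z.fs))
            lo, hi = center - n_pre, center + n_post
            if lo < a or hi > b:
                break  # window exits the trial segment
            row = z.z[lo:hi].astype(float)
            m = row.max()
            if m > 0:
                row = row / m
            else:
                unnormalized.append(len(rows))
            rows.append(row)
            placed = True
            break
        if not placed:
            n_dropped += 1
    offsets = (np.arange(-n_pre, n_post) + 0.5) / z.fs
    if not rows:
        empty = np.zeros((0, n_pre + n_post))
        return TransitionTraceSet(
            window_s=window_s, offsets_s=offsets, traces=empty,
            mean_trace=np.full(n_pre + n_post, np.nan),
            sem_trace=np.full(n_pre + n_post, np.nan),
            n_dropped=n_dropped,
        )
    traces = np.vstack(rows)
    mean = traces.mean(axis=0)
    if traces.shape[0] > 1:
        sem = traces.std(axis=0, ddof=1) / np.sqrt(traces.shape[0])
    else:
        sem = np.full(traces.shape[1], np.nan)
    return TransitionTraceSet(
        window_s=window_s, offsets_s=offsets, traces=traces,
        mean_trace=mean, sem_trace=sem,
        unnormalized_rows=np.array(unnormalized, dtype=int),
        n_dropped=n_dropped,
    )
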