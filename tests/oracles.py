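"""Independent brute-force oracles the analysis code is checked against.

Everything here is written for transparency, not speed: per-peak exhaustive
scans for topographic prominence and width, run-length enumeration for
bouts, direct flank checking for transitions, a sample-by-sample crossing
scan for spikes, and the closed-form leaky integrate-and-fire rate.
"""

from __future__ import annotations

from itertools import groupby

import numpy as np


def brute_peaks(x: np.ndarray) -> list[tuple[int, int]]:
    """All strict local maxima as (left_edge, right_edge) plateau spans."""
    n = len(x)
    peaks = []
    i = 1
    while i < n - 1:
        if x[i] > x[i - 1]:
            j = i
            while j + 1 < n and x[j + 1] == x[i]:
                j += 1
            if j + 1 < n and x[j + 1] < x[i]:
                peaks.append((i, j))
            i = j + 1
        else:
            i += 1
    return peaks


def brute_prominence(x: np.ndarray, i: int) -> float:
    """Exhaustive topographic prominence of the peak at sample ``i``.

    Scan each side to the nearest strictly higher sample (or trace end),
    take the minimum on each side; prominence is the peak value minus the
    higher of the two minima.
    """
    v = x[i]
    higher_left = np.flatnonzero(x[:i] > v)
    lo = higher_left[-1] + 1 if len(higher_left) else 0
    left_min = np.min(x[lo : i + 1])
    higher_right = np.flatnonzero(x[i + 1 :] > v)
    hi = i + 1 + higher_right[0] if len(higher_right) else len(x)
    right_min = np.min(x[i:hi])
    return float(v - max(left_min, right_min))


def brute_width(x: np.ndarray, i: int, prominence: float) -> float:
    """Width (samples) at the half-prominence level by linear interpolation."""
    h = x[i] - 0.5 * prominence
    k = i
    while k > 0 and x[k] >= h:
        k -= 1
    if x[k] >= h:
        left = float(k)
    else:
        left = k + (h - x[k]) / (x[k + 1] - x[k])
    k = i
    while k < len(x) - 1 and x[k] >= h:
        k += 1
    if x[k] >= h:
        right = float(k)
    else:
        right = k - (h - x[k]) / (x[k - 1] - x[k])
    return right - left


def brute_transient_set(
    x: np.ndarray, fs: float, min_width_s: float, min_prominence: float
) -> list[tuple[int, float, float]]:
    """(left-edge index, prominence, width_s) of every gate-passing peak."""
    out = []
    for left, _right in brute_peaks(x):
        prom = brute_prominence(x, left)
        width = brute_width(x, left, prom) / fs
        if prom >= min_prominence and width >= min_width_s:
            out.append((left, prom, width))
    return out


def brute_bouts(labels, epoch_s: float, min_duration_s: float = 30.0):
    """(state, start_epoch, n_epochs) for runs strictly longer than cutoff."""
    out = []
    pos = 0
    for state, grp in groupby(labels):
        n = len(list(grp))
        if state != "ARTIFACT" and n * epoch_s > min_duration_s:
            out.append((state, pos, n))
        pos += n
    return out


def brute_transitions(labels, n_flank: int, kinds) -> list[tuple[int, tuple]]:
    """(boundary epoch index, kind) for boundaries with pure flanks."""
    out = []
    for i in range(1, len(labels)):
        src, tgt = labels[i - 1], labels[i]
        if src == tgt or (src, tgt) not in kinds:
            continue
        if i - n_flank < 0 or i + n_flank > len(labels):
            continue
        if all(labels[j] == src for j in range(i - n_flank, i)) and all(
            labels[j] == tgt for j in range(i, i + n_flank)
        ):
            out.append((i, (src, tgt)))
    return out


def brute_spike_scan(
    vm: np.ndarray, fs: float, threshold: float, refractory_s: float
) -> list[float]:
    """Sample-by-sample upward-crossing scan with a refractory hold-off."""
    out = []
    last = -np.inf
    for i in range(len(vm)):
        above = vm[i] >= threshold
        prev_above = vm[i - 1] >= threshold if i > 0 else False
        if above and not prev_above and (i - last) >= refractory_s * fs:
            out.append(i / fs)
            last = i
    return out


def lif_rate_closed_form(
    i_pa: float, el: float, vth: float, vreset: float,
    tau_s: float, r_gohm: float, t_ref_s: float,
) -> float:
    """Deterministic leaky integrate-and-fire rate under constant current."""
    v_inf = el + r_gohm * i_pa
    if v_inf <= vth:
        return 0.0
    t_isi = t_ref_s + tau_s * np.log((v_inf - vreset) / (v_inf - vth))
    return 1.0 / t_isi
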