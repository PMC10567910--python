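"""CSV/JSON readers and writers for every pipeline artifact.

All artifacts are plain text: photometry sessions, hypnograms, z-traces and
transient tables as CSV; clock maps and ground truth as JSON.  EEG/EMG go
to CSV as well (one row per sample); an EDF reader is available when the
optional ``mne`` dependency is installed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ._exceptions import DataError
from .photometry import PhotometrySession, ZScoreTrace
from .sleep import EEGRecord, Hypnogram
from .sync import ClockMap
from .transients import TransientSet


def write_session_csv(session: PhotometrySession, path: str | Path) -> None:
    """Columns: time_s, sig465, ref405, ttl (binary, 1 s pulses)."""
    ttl = np.zeros(len(session.time_s), dtype=int)
    for onset in session.ttl_onsets_s:
        mask = (session.time_s >= onset) & (session.time_s < onset + 1.0)
        ttl[mask] = 1
    pd.DataFrame(
        {
            "time_s": session.time_s,
            "sig465": session.signal_465,
            "ref405": session.reference_405,
            "ttl": ttl,
        }
    ).to_csv(path, index=False)


def read_session_csv(
    path: str | Path,
    trial_windows: list[tuple[float, float]] | None = None,
) -> PhotometrySession:
    df = pd.read_csv(path)
    required = {"time_s", "sig465", "ref405"}
    if not required.issubset(df.columns):
        raise DataError(f"session CSV must carry columns {sorted(required)}")
    t = df["time_s"].to_numpy()
    if len(t) < 2:
        raise DataError("session CSV too short")
    fs = 1.0 / float(np.median(np.diff(t)))
    onsets = np.array([])
    if "ttl" in df.columns:
        ttl = df["ttl"].to_numpy().astype(float)
        rising = np.flatnonzero((ttl[1:] > 0.5) & (ttl[:-1] <= 0.5)) + 1
        if len(ttl) and ttl[0] > 0.5:
            rising = np.concatenate(([0], rising))
        onsets = t[rising]
    return PhotometrySession(
        time_s=t,
        signal_465=df["sig465"].to_numpy(),
        reference_405=df["ref405"].to_numpy(),
        fs=fs,
        ttl_onsets_s=onsets,
        trial_windows=trial_windows or [],
    )


def write_hypnogram_csv(hyp: Hypnogram, path: str | Path) -> None:
    pd.DataFrame(
        {"epoch_index": np.arange(len(hyp.labels)), "label": hyp.labels}
    ).to_csv(path, index=False)


def read_hypnogram_csv(
    path: str | Path, epoch_s: float = 10.0, t0_s: float = 0.0
) -> Hypnogram:
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise DataError("hypnogram CSV must carry a 'label' column")
    return Hypnogram(
        labels=df["label"].to_numpy(dtype=object), epoch_s=epoch_s, t0_s=t0_s
    )


def write_ztrace_csv(z: ZScoreTrace, path: str | Path) -> None:
    trial = np.zeros(len(z.z), dtype=int)
    for k, (a, b) in enumerate(z.trial_slices):
        trial[a:b] = k
    pd.DataFrame({"time_s": z.time_s, "z": z.z, "trial": trial}).to_csv(
        path, index=False
    )


def read_ztrace_csv(path: str | Path, fs: float | None = None) -> ZScoreTrace:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    if fs is None:
        fs = 1.0 / float(np.median(np.diff(t)))
    slices: list[tuple[int, int]] = []
    if "trial" in df.columns:
        trial = df["trial"].to_numpy()
        for k in np.unique(trial):
            idx = np.flatnonzero(trial == k)
            slices.append((int(idx[0]), int(idx[-1]) + 1))
    return ZScoreTrace(
        time_s=t, z=df["z"].to_numpy(), fs=fs, trial_slices=slices
    )


def write_transients_csv(ts: TransientSet, path: str | Path) -> None:
    pd.DataFrame(
        {
            "peak_time_s": ts.peak_time_s,
            "peak_z": ts.peak_z,
            "prominence": ts.prominence,
            "width_s": ts.width_s,
        }
    ).to_csv(path, index=False)


def write_eeg_csv(rec: EEGRecord, path: str | Path) -> None:
    cols = {"eeg_uv": rec.eeg, "emg_uv": rec.emg}
    if rec.ttl is not None:
        cols["ttl"] = rec.ttl
    pd.DataFrame(cols).to_csv(path, index=False)


def read_eeg_csv(path: str | Path, fs: float = 400.0) -> EEGRecord:
    df = pd.read_csv(path)
    return EEGRecord(
        eeg=df["eeg_uv"].to_numpy(),
        emg=df["emg_uv"].to_numpy(),
        fs=fs,
        ttl=df["ttl"].to_numpy() if "ttl" in df.columns else None,
    )


def read_eeg_edf(
    path: str | Path,
    eeg_channel: str = "EEG",
    emg_channel: str = "EMG",
    ttl_channel: str | None = None,
) -> EEGRecord:
    """Read EEG/EMG (and optionally a TTL channel) from an EDF file.

    Requires the optional ``mne`` dependency.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading EDF requires the optional 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data()

    def pick(name: str) -> np.ndarray:
        matches = [i for i, ch in enumerate(raw.ch_names) if name.lower() in ch.lower()]
        if not matches:
            raise DataError(f"channel {name!r} not found in {raw.ch_names}")
        return data[matches[0]]

    return EEGRecord(
        eeg=pick(eeg_channel) * 1e6,  # volts -> µV
        emg=pick(emg_channel) * 1e6,
        fs=float(raw.info["sfreq"]),
        ttl=pick(ttl_channel) if ttl_channel else None,
    )


def write_clock_map_json(cmap: ClockMap, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "offset_s": cmap.offset_s,
                "drift": cmap.drift,
                "residual_rms_s": cmap.residual_rms_s,
            },
            indent=2,
        )
    )


def read_clock_map_json(path: str | Path) -> ClockMap:
    d = json.loads(Path(path).read_text())
    return ClockMap(**d)
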