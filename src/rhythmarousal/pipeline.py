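"""Config-driven end-to-end run: synth → sync → preprocess → transients →
transitions → sleep summaries, emitting every artifact as CSV/JSON.

The single entry point :func:`run_pipeline` takes a YAML/JSON config file
(or an equivalent dict) whose ``synth`` section holds
:class:`~rhythmarousal.synth.SynthConfig` overrides and whose ``analysis``
section holds detector/consolidation parameters.  Output is deterministic
for a fixed seed: running the same config twice produces byte-identical
files.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .sleep import STATES, Hypnogram, bandpower, emg_epoch_amplitude, find_bouts, \
    percent_state_binned, welch_psd, DELTA_BAND, THETA_BAND
from .sync import detect_ttl_onsets, fit_clock_map
from .photometry import preprocess
from .synth import SynthConfig, generate_eeg_emg, generate_hypnogram, generate_photometry
from .transients import (
    detect_transients,
    transient_prominence_by_state,
    transient_rate_by_state,
    zscore_by_state,
)
from .transitions import TRACKED_KINDS, find_transitions, kind_name, transition_triggered


def load_config(source: str | Path | dict) -> dict:
    if isinstance(source, dict):
        return source
    text = Path(source).read_text()
    return yaml.safe_load(text) or {}


def hypnogram_duration_for(cfg: SynthConfig) -> float:
    """Epoch-aligned EEG-clock duration covering the mapped trial schedule."""
    end_eeg = cfg.true_clock_map().to_eeg(cfg.session_duration_s)
    return math.ceil(end_eeg / cfg.epoch_s + 1) * cfg.epoch_s


def run_pipeline(config: str | Path | dict, out_dir: str | Path) -> dict[str, Path]:
    """Run the full synthetic study and write all artifacts to ``out_dir``.

    Returns a mapping from artifact name to file path.  The ``summary.json``
    artifact gathers the headline numbers (per-state transient rates and
    mean z, transition counts, band powers, EMG amplitudes).
    """
    conf = load_config(config)
    cfg = SynthConfig(**conf.get("synth", {}))
    analysis = conf.get("analysis", {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    hyp = generate_hypnogram(cfg, hypnogram_duration_for(cfg))
    session, truth = generate_photometry(cfg, hyp)
    eeg = generate_eeg_emg(cfg, hyp)

    onsets_eeg = detect_ttl_onsets(eeg.ttl, eeg.fs)
    clock = fit_clock_map(session.ttl_onsets_s, onsets_eeg)

    z = preprocess(session)
    ts = detect_transients(
        z,
        min_width_s=float(analysis.get("min_width_s", 0.08)),
        min_prominence=float(analysis.get("min_prominence", 0.1)),
    )
    rates = transient_rate_by_state(ts, hyp, clock, coverage_s=z.trial_spans_s())
    proms = transient_prominence_by_state(ts, hyp, clock)
    zmeans = zscore_by_state(z, hyp, clock, per_trial=True)

    consolidation_s = float(analysis.get("consolidation_s", 15.0))
    events = find_transitions(hyp, consolidation_s=consolidation_s)
    transition_sets = {}
    for kind in TRACKED_KINDS:
        evs = [e for e in events if e.kind == kind]
        transition_sets[kind] = transition_triggered(z, evs, clock)

    bouts = find_bouts(hyp)
    pct = {
        state: percent_state_binned(hyp, state, float(analysis.get("bin_s", 60.0)))
        for state in STATES
    }
    psd = welch_psd(eeg.eeg, eeg.fs, nfft=int(analysis.get("nfft", 1024)))
    emg_amp = emg_epoch_amplitude(eeg.emg, eeg.fs, hyp)

    # ------------------------------------------------------------------ write
    rio.write_session_csv(session, out / "session.csv")
    rio.write_hypnogram_csv(hyp, out / "hypnogram.csv")
    rio.write_ztrace_csv(z, out / "ztrace.csv")
    rio.write_transients_csv(ts, out / "transients.csv")
    rio.write_eeg_csv(eeg, out / "eeg.csv")
    rio.write_clock_map_json(clock, out / "clock_map.json")
    for name in ("session", "hypnogram", "ztrace", "transients", "eeg", "clock_map"):
        suffix = "json" if name == "clock_map" else "csv"
        paths[name] = out / f"{name}.{suffix}"

    pd.DataFrame(
        {
            "state": list(STATES),
            "rate_per_min": [rates[s] for s in STATES],
            "mean_prominence": [proms[s] for s in STATES],
            "mean_z": [zmeans[s] for s in STATES],
        }
    ).to_csv(out / "state_summary.csv", index=False)
    paths["state_summary"] = out / "state_summary.csv"

    pd.DataFrame(
        [
            {"kind": kind_name(e.kind), "time_s": e.time_s,
             "pre_ok": e.pre_ok, "post_ok": e.post_ok}
            for e in events
        ]
    ).to_csv(out / "transitions.csv", index=False)
    paths["transitions"] = out / "transitions.csv"

    for kind, tset in transition_sets.items():
        tag = f"{kind[0]}_{kind[1]}".lower()
        df = pd.DataFrame(tset.traces, columns=[f"{t:.4f}" for t in tset.offsets_s])
        df.to_csv(out / f"transition_traces_{tag}.csv", index=False)
        paths[f"transition_traces_{tag}"] = out / f"transition_traces_{tag}.csv"

    pd.DataFrame(
        [
            {"state": b.state, "start_s": b.start_s, "end_s": b.end_s,
             "duration_s": b.duration_s}
            for b in bouts
        ]
    ).to_csv(out / "bouts.csv", index=False)
    paths["bouts"] = out / "bouts.csv"

    pd.DataFrame({("pct_" + s.lower()): pct[s] for s in STATES}).to_csv(
        out / "percent_state.csv", index=False
    )
    paths["percent_state"] = out / "percent_state.csv"

    pd.DataFrame({"freq_hz": psd.freqs_hz, "power_uv2_hz": psd.power}).to_csv(
        out / "psd.csv", index=False
    )
    paths["psd"] = out / "psd.csv"

    pd.DataFrame({"epoch_index": np.arange(len(emg_amp)), "emg_rms": emg_amp,
                  "label": hyp.labels}).to_csv(out / "emg_amplitude.csv", index=False)
    paths["emg_amplitude"] = out / "emg_amplitude.csv"

    summary = {
        "n_transients": len(ts),
        "rate_per_min": rates,
        "mean_prominence": proms,
        "mean_z": zmeans,
        "n_transitions": {kind_name(k): int(sum(e.kind == k for e in events))
                          for k in TRACKED_KINDS},
        "n_bouts": len(bouts),
        "delta_power_uv2": bandpower(psd, *DELTA_BAND),
        "theta_power_uv2": bandpower(psd, *THETA_BAND),
        "clock_offset_s": clock.offset_s,
        "clock_drift": clock.drift,
        "true_clock": {"offset_s": truth.clock_map_true[0],
                       "drift_ppm": truth.clock_map_true[1]},
        "n_true_transients": int(len(truth.transient_times_s)),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True,
                                                 allow_nan=True, default=float))
    paths["summary"] = out / "summary.json"

    truth_payload = {
        "transient_times_s": [float(v) for v in truth.transient_times_s],
        "motion_times_s": [float(v) for v in truth.motion_times_s],
        "bleach_params": list(truth.bleach_params),
        "clock_map_true": list(truth.clock_map_true),
    }
    (out / "ground_truth.json").write_text(json.dumps(truth_payload, indent=2))
    paths["ground_truth"] = out / "ground_truth.json"
    return paths
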