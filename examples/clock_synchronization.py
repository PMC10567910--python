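"""TTL-based alignment of the photometry and EEG clocks.

The photometry console pulses a 1 s TTL every 3 min into both systems;
rising edges detected on the EEG channel are matched against the
photometry onsets and an affine clock map (offset + drift) is fit.
"""

import rhythmarousal as ra

cfg = ra.SynthConfig(seed=8, n_trials=2, trial_on_s=900.0, trial_off_s=60.0,
                     clock_offset_s=7.0, clock_drift_ppm=50.0)
hyp = ra.generate_hypnogram(cfg, ra.pipeline.hypnogram_duration_for(cfg))
session, truth = ra.generate_photometry(cfg, hyp)
rec = ra.generate_eeg_emg(cfg, hyp)

onsets_eeg = ra.detect_ttl_onsets(rec.ttl, rec.fs)
cmap = ra.fit_clock_map(session.ttl_onsets_s, onsets_eeg)

print(f"{len(onsets_eeg)} TTL pulses detected on the EEG channel")
print(f"fit:  offset {cmap.offset_s:.4f} s, drift {(cmap.drift - 1) * 1e6:.1f} ppm, "
      f"residual RMS {cmap.residual_rms_s * 1e3:.2f} ms")
print(f"true: offset {truth.clock_map_true[0]:.4f} s, "
      f"drift {truth.clock_map_true[1]:.1f} ppm")
print("Offset is recovered to a few ms (one 400 Hz sample of edge rounding)")
print("and drift to well under 5 ppm over a ~30 min session.")
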