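"""State-dependent Ca2+ transient analysis on a synthetic recording.

Generates a 40 min dual-channel photometry session with known
state-dependent transient rates (WAKE 10, NREM 1, REM 5 events/min),
runs the full preprocessing chain (bleach removal, reference subtraction,
robust z-score, 5 Hz smoothing), detects transients and summarizes them
per vigilance state.
"""

import numpy as np

import rhythmarousal as ra

cfg = ra.SynthConfig(seed=1, n_trials=1, trial_on_s=2400.0, trial_off_s=0.0,
                     motion_rate_per_min=0.0)
hyp = ra.generate_hypnogram(cfg, 2400.0)
session, truth = ra.generate_photometry(cfg, hyp)

z = ra.preprocess(session)
# 2.25 z operating point for this SNR (transients at 5x the raw noise SD);
# the 0.1 z default targets far cleaner lock-in-demodulated recordings
ts = ra.detect_transients(z, min_prominence=2.25)

# transients closer than the detector's resolution merge into one peak;
# correct the counts with the calibrated effective dead time
mad = z.trial_stats[0][1]
amp_z = cfg.transient_amp_z * cfg.noise_sd / mad
sigma_z = np.sqrt(2.0) * cfg.noise_sd / mad
dead = ra.validation.effective_dead_time(
    cfg, amp_z, sigma_z, np.random.default_rng(0))
rates = ra.transient_rate_by_state(ts, hyp)
rates_corr = ra.transient_rate_by_state(ts, hyp, dead_time_s=dead)
proms = ra.transient_prominence_by_state(ts, hyp)
means = ra.zscore_by_state(z, hyp)

print(f"detected {len(ts)} transients ({len(truth.transient_times_s)} generated), "
      f"effective dead time {dead:.2f} s")
print(f"{'state':>6} {'min':>6} {'raw/min':>8} {'corr/min':>9} {'true':>6} "
      f"{'prom':>6} {'mean z':>7}")
for s in ra.STATES:
    minutes = hyp.state_seconds(s) / 60.0
    true_rate = np.sum(truth.transient_states == s) / minutes if minutes else np.nan
    print(f"{s:>6} {minutes:6.1f} {rates[s]:8.2f} {rates_corr[s]:9.2f} "
          f"{true_rate:6.2f} {proms[s]:6.2f} {means[s]:7.3f}")
print("\nDead-time-corrected rates track the generator's per-state event")
print("rates; mean z is highest where transients are frequent (WAKE, REM).")
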