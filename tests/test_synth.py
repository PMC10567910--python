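"""Generator-level checks: determinism, dwell statistics, construction nulls."""

import numpy as np
import pytest

import rhythmarousal as ra
from rhythmarousal import ARTIFACT, NREM, REM, WAKE
from rhythmarousal.synth import transient_kernel


def wake_only_config(seed=0, **kw):
    return ra.SynthConfig(
        seed=seed,
        state_mean_dwell_s={WAKE: 60.0},
        transition_probs={WAKE: {WAKE: 1.0}},
        **kw,
    )


class TestHypnogram:
    def test_absorbing_wake_yields_only_wake(self):
        hyp = ra.generate_hypnogram(wake_only_config(), 60.0)
        assert list(hyp.labels) == [WAKE] * 6

    def test_same_seed_is_bit_identical(self):
        cfg = ra.SynthConfig(seed=42)
        a = ra.generate_hypnogram(cfg, 3600.0)
        b = ra.generate_hypnogram(cfg, 3600.0)
        assert list(a.labels) == list(b.labels)

    def test_different_seeds_differ(self):
        a = ra.generate_hypnogram(ra.SynthConfig(seed=1), 3600.0)
        b = ra.generate_hypnogram(ra.SynthConfig(seed=2), 3600.0)
        assert list(a.labels) != list(b.labels)

    def test_mean_dwell_matches_geometric_law(self):
        """Empirical mean dwell over 50 seeds within 15% of the 60 s target."""
        dwell = {WAKE: 60.0, NREM: 60.0, REM: 60.0}
        durations = []
        for seed in range(50):
            cfg = ra.SynthConfig(seed=seed, state_mean_dwell_s=dwell)
            hyp = ra.generate_hypnogram(cfg, 3 * 3600.0)
            runs = []
            count = 1
            for a, b in zip(hyp.labels, hyp.labels[1:]):
                if a == b:
                    count += 1
                else:
                    runs.append(count)
                    count = 1
            durations.extend(r * cfg.epoch_s for r in runs)
        assert abs(np.mean(durations) - 60.0) / 60.0 < 0.15

    def test_unreachable_state_rejected(self):
        probs = {WAKE: {NREM: 1.0}, NREM: {WAKE: 1.0}, REM: {WAKE: 1.0}}
        with pytest.raises(ra.ConfigError, match="unreachable"):
            ra.SynthConfig(transition_probs=probs)

    def test_rows_must_sum_to_one(self):
        with pytest.raises(ra.ConfigError, match="sum to 1"):
            ra.SynthConfig(transition_probs={WAKE: {NREM: 0.5}, NREM: {WAKE: 1.0}})

    def test_duration_must_align_to_epochs(self):
        with pytest.raises(ra.ConfigError):
            ra.generate_hypnogram(ra.SynthConfig(), 65.0)

    def test_artifact_injection_fraction(self):
        cfg = ra.SynthConfig(seed=3, artifact_fraction=0.25)
        hyp = ra.generate_hypnogram(cfg, 6 * 3600.0)
        frac = np.mean(hyp.labels == ARTIFACT)
        assert 0.18 < frac < 0.32


class TestPhotometry:
    def test_null_construction_signal_equals_reference(self):
        """No transients/noise/motion: both channels carry only the bleach."""
        cfg = wake_only_config(
            n_trials=1, trial_on_s=120.0, trial_off_s=0.0,
            transient_rate_per_min={WAKE: 0.0}, noise_sd=0.0,
            motion_rate_per_min=0.0,
        )
        hyp = ra.generate_hypnogram(cfg, 120.0)
        sess, truth = ra.generate_photometry(cfg, hyp)
        np.testing.assert_array_equal(sess.signal_465, sess.reference_405)
        assert len(truth.transient_times_s) == 0

    def test_poisson_transient_count(self):
        """WAKE-only at 10/min for 15 min: counts within 3*sqrt(150) of 150
        in at least 95% of seeds."""
        ok = 0
        n_seeds = 40
        for seed in range(n_seeds):
            cfg = wake_only_config(
                seed=seed, n_trials=1, trial_on_s=900.0, trial_off_s=0.0,
                transient_rate_per_min={WAKE: 10.0},
            )
            hyp = ra.generate_hypnogram(cfg, 900.0)
            _, truth = ra.generate_photometry(cfg, hyp)
            ok += abs(len(truth.transient_times_s) - 150) <= 3 * np.sqrt(150)
        assert ok / n_seeds >= 0.95

    def test_reference_has_no_transient_energy(self):
        cfg = wake_only_config(
            n_trials=1, trial_on_s=300.0, trial_off_s=0.0,
            transient_rate_per_min={WAKE: 20.0}, noise_sd=0.0,
            motion_rate_per_min=0.0,
        )
        hyp = ra.generate_hypnogram(cfg, 300.0)
        sess, truth = ra.generate_photometry(cfg, hyp)
        assert len(truth.transient_times_s) > 0
        bleach = cfg.bleach_amp * np.exp(-sess.time_s / cfg.bleach_tau_s) + cfg.bleach_offset
        np.testing.assert_allclose(sess.reference_405, bleach, atol=1e-12)

    def test_ground_truth_times_inside_record(self):
        cfg = ra.SynthConfig(seed=5, n_trials=2, trial_on_s=300.0, trial_off_s=60.0)
        hyp = ra.generate_hypnogram(cfg, 720.0)
        sess, truth = ra.generate_photometry(cfg, hyp)
        d = cfg.session_duration_s
        assert np.all((truth.transient_times_s >= 0) & (truth.transient_times_s < d))
        assert np.all((truth.motion_times_s >= 0) & (truth.motion_times_s < d))

    def test_zero_bleach_amplitude_fits_flat(self):
        cfg = wake_only_config(
            n_trials=1, trial_on_s=300.0, trial_off_s=0.0, bleach_amp=0.0,
            transient_rate_per_min={WAKE: 0.0}, noise_sd=0.01,
            motion_rate_per_min=0.0,
        )
        hyp = ra.generate_hypnogram(cfg, 300.0)
        sess, _ = ra.generate_photometry(cfg, hyp)
        fit = ra.fit_bleach(
            ra.lowpass(sess.signal_465, cfg.photometry_fs_hz, 0.1), sess.time_s
        )
        assert abs(fit.amplitude) < 0.05
        assert abs(fit.offset - cfg.bleach_offset) < 0.05

    def test_decay_must_exceed_rise(self):
        with pytest.raises(ra.ConfigError, match="decay"):
            ra.SynthConfig(transient_rise_s=1.0, transient_decay_s=0.5)

    def test_kernel_unit_peak(self):
        cfg = ra.SynthConfig()
        k, t_peak = transient_kernel(cfg, 120.0)
        assert k.max() == pytest.approx(1.0)
        assert abs(np.argmax(k) / 120.0 - t_peak) < 1 / 120.0

    def test_determinism(self):
        cfg = ra.SynthConfig(seed=11, n_trials=1, trial_on_s=120.0, trial_off_s=0.0)
        hyp = ra.generate_hypnogram(cfg, 180.0)
        s1, _ = ra.generate_photometry(cfg, hyp)
        s2, _ = ra.generate_photometry(cfg, hyp)
        np.testing.assert_array_equal(s1.signal_465, s2.signal_465)


class TestEEG:
    def one_state_record(self, state, seed=0, duration=300.0):
        cfg = ra.SynthConfig(
            seed=seed,
            state_mean_dwell_s={state: duration},
            transition_probs={state: {state: 1.0}},
            n_trials=1, trial_on_s=duration, trial_off_s=0.0,
        )
        hyp = ra.generate_hypnogram(cfg, duration)
        return cfg, hyp, ra.generate_eeg_emg(cfg, hyp)

    def test_nrem_is_delta_dominant(self):
        _, _, rec = self.one_state_record(NREM)
        psd = ra.welch_psd(rec.eeg, rec.fs, nfft=1024)
        assert ra.bandpower(psd, 0.5, 4.0) > ra.bandpower(psd, 5.0, 9.0)

    def test_rem_emg_atonic_versus_wake(self):
        _, hyp_r, rec_r = self.one_state_record(REM)
        _, hyp_w, rec_w = self.one_state_record(WAKE)
        from rhythmarousal.sleep import emg_epoch_amplitude

        rms_r = np.nanmean(emg_epoch_amplitude(rec_r.emg, rec_r.fs, hyp_r))
        rms_w = np.nanmean(emg_epoch_amplitude(rec_w.emg, rec_w.fs, hyp_w))
        assert rms_w > rms_r

    def test_ttl_pure_offset_shift(self):
        """With zero drift and a 7 s offset, EEG TTL onsets sit 7 s after
        the photometry onsets."""
        cfg = ra.SynthConfig(
            seed=2, n_trials=1, trial_on_s=600.0, trial_off_s=0.0,
            clock_offset_s=7.0,
        )
        hyp = ra.generate_hypnogram(cfg, 620.0)
        rec = ra.generate_eeg_emg(cfg, hyp)
        onsets_eeg = ra.detect_ttl_onsets(rec.ttl, rec.fs)
        expected = np.arange(0.0, 600.0, 180.0) + 7.0
        np.testing.assert_allclose(onsets_eeg, expected, atol=1.5 / rec.fs)


class TestPatch:
    def test_subthreshold_silent(self):
        cfg = ra.SynthConfig(seed=0)
        protocol = ra.CurrentProtocol(currents_pa=(0.0,), baseline_duration_s=5.0)
        lif = ra.LIFParams(noise_mv=0.0, spontaneous_drive_pa=0.0)
        rec, truth = ra.generate_patch_recording(cfg, protocol, lif)
        assert len(truth.spike_times_s) == 0
        assert np.all(rec.vm_mv < lif.vth_mv + 1e-9)

    def test_fi_monotone_when_rheobase_below_protocol(self):
        cfg = ra.SynthConfig(seed=0)
        protocol = ra.CurrentProtocol(baseline_duration_s=2.0)
        lif = ra.LIFParams(noise_mv=0.0)  # rheobase 40 pA
        rec, _ = ra.generate_patch_recording(cfg, protocol, lif)
        fi = ra.f_i_curve(rec)
        assert np.all(np.diff(fi.rates_hz) >= 0)
        idx100 = np.argmin(np.abs(fi.currents_pa - 100))
        idx50 = np.argmin(np.abs(fi.currents_pa - 50))
        assert fi.rates_hz[idx100] >= fi.rates_hz[idx50] > 0

    def test_no_drive_means_zero_spontaneous_rate(self):
        cfg = ra.SynthConfig(seed=0)
        protocol = ra.CurrentProtocol(currents_pa=(), baseline_duration_s=30.0)
        rec, _ = ra.generate_patch_recording(cfg, protocol, ra.LIFParams())
        assert ra.spontaneous_rate(rec) == 0.0

    def test_spike_waveform_crosses_zero(self):
        cfg = ra.SynthConfig(seed=0)
        protocol = ra.CurrentProtocol(currents_pa=(100.0,), baseline_duration_s=1.0)
        rec, truth = ra.generate_patch_recording(cfg, protocol, ra.LIFParams())
        assert len(truth.spike_times_s) > 0
        assert rec.vm_mv.max() > 0.0


class TestBehavior:
    def test_night_activity_dominates(self):
        wins = 0
        for seed in range(20):
            cfg = ra.SynthConfig(seed=seed, locomotor_day_rate=1.0,
                                 locomotor_night_ratio=3.0, locomotor_days=1)
            series, _ = ra.generate_behavior(cfg)
            totals = ra.locomotor_totals(series, [(0, 12), (12, 24)])
            wins += totals[(12, 24)] > totals[(0, 12)]
        assert wins == 20

    def test_zero_response_amplitude(self):
        cfg = ra.SynthConfig(seed=1, startle_response_mv=0.0)
        _, trials = ra.generate_behavior(cfg)
        tr = trials[0]
        vavg, _ = ra.startle_vavg(tr)
        i_tone = int(tr.tone_onset_s * tr.fs)
        base = np.mean(np.abs(tr.trace_mv[: i_tone - int(0.1 * tr.fs)]))
        assert vavg == pytest.approx(base, rel=0.3)

    def test_contamination_recovered_by_exclusion_rule(self):
        """~20% of trials injected with pre-tone bursts are flagged."""
        cfg = ra.SynthConfig(seed=9, startle_n_trials=100,
                             startle_contamination_fraction=0.2)
        _, trials = ra.generate_behavior(cfg)
        n_injected = sum(t.contaminated_truth for t in trials)
        flagged = [ra.startle_vavg(t)[1] for t in trials]
        assert sum(flagged) == n_injected
        assert all(
            f == t.contaminated_truth for f, t in zip(flagged, trials)
        )
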