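"""Hypnogram analyses, Welch/STFT spectral estimates and EMG normalization."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import rhythmarousal as ra
from rhythmarousal import ARTIFACT, NREM, REM, WAKE

from oracles import brute_bouts

label_lists = st.lists(
    st.sampled_from([WAKE, NREM, REM, ARTIFACT]), min_size=1, max_size=200
)


def hyp(labels, epoch_s=10.0):
    return ra.Hypnogram(labels=np.array(labels, dtype=object), epoch_s=epoch_s)


class TestBouts:
    def test_exactly_30s_is_not_a_bout(self):
        assert ra.find_bouts(hyp([WAKE] * 3)) == []

    def test_hand_enumerated_runs(self):
        bouts = ra.find_bouts(hyp([WAKE] * 4 + [NREM] * 5))
        assert [(b.state, b.duration_s) for b in bouts] == [(WAKE, 40.0), (NREM, 50.0)]

    def test_artifact_breaks_runs(self):
        bouts = ra.find_bouts(hyp([WAKE] * 4 + [ARTIFACT] + [WAKE] * 4))
        assert len(bouts) == 2

    def test_sleep_mode_merges_nrem_rem(self):
        bouts = ra.find_bouts(hyp([NREM] * 3 + [REM] * 2), sleep_mode=True)
        assert [(b.state, b.duration_s) for b in bouts] == [("SLEEP", 50.0)]

    @given(label_lists)
    def test_matches_run_length_oracle(self, labels):
        got = ra.find_bouts(hyp(labels))
        expected = brute_bouts(labels, 10.0)
        assert [(b.state, b.start_s, b.duration_s) for b in got] == [
            (s, p * 10.0, n * 10.0) for s, p, n in expected
        ]

    @given(label_lists)
    def test_bout_durations_are_epoch_multiples(self, labels):
        for b in ra.find_bouts(hyp(labels)):
            assert b.duration_s % 10.0 == 0
            assert b.duration_s <= hyp(labels).state_seconds(b.state)


class TestPercentState:
    def test_pure_and_mixed_bins(self):
        h = hyp([WAKE] * 360)
        assert ra.percent_state_binned(h, WAKE, 3600.0)[0] == 100.0
        h2 = hyp([WAKE] * 30 + [NREM] * 30)
        assert ra.percent_state_binned(h2, WAKE, 600.0)[0] == 50.0

    def test_all_artifact_bin_undefined(self):
        h = hyp([ARTIFACT] * 6 + [WAKE] * 6)
        vals = ra.percent_state_binned(h, WAKE, 60.0)
        assert np.isnan(vals[0]) and vals[1] == 100.0

    @given(label_lists)
    def test_states_partition_to_100_percent(self, labels):
        h = hyp(labels)
        sums = sum(ra.percent_state_binned(h, s, 60.0) for s in ra.STATES)
        has_scored = [
            any(lab != ARTIFACT for lab in labels[i : i + 6])
            for i in range(0, len(labels), 6)
        ]
        for val, scored in zip(sums, has_scored):
            if scored:
                assert val == pytest.approx(100.0)
            else:
                assert np.isnan(val)

    def test_counting_oracle_on_random_labels(self, rng):
        labels = list(rng.choice([WAKE, NREM, REM, ARTIFACT], size=240))
        vals = ra.percent_state_binned(hyp(labels), NREM, 120.0)
        for b in range(len(vals)):
            chunk = labels[b * 12 : (b + 1) * 12]
            scored = [lab for lab in chunk if lab != ARTIFACT]
            if scored:
                assert vals[b] == pytest.approx(
                    100.0 * scored.count(NREM) / len(scored)
                )

    def test_bin_must_align(self):
        with pytest.raises(ra.ParameterError):
            ra.percent_state_binned(hyp([WAKE] * 6), WAKE, 15.0)


class TestLatency:
    def test_boundary_and_mid_epoch_arithmetic(self):
        h = hyp([NREM, WAKE, NREM, NREM])
        assert ra.latency_to_arousal(h, 0.0) == 10.0
        h2 = hyp([NREM, NREM, NREM, WAKE])
        assert ra.latency_to_arousal(h2, 5.0) == 25.0

    def test_stim_during_wake_rejected(self):
        with pytest.raises(ra.TrialRejectedError):
            ra.latency_to_arousal(hyp([WAKE, NREM]), 0.0)

    def test_no_wake_following_is_nan(self):
        assert np.isnan(ra.latency_to_arousal(hyp([NREM] * 5), 0.0))


class TestWelch:
    def test_tone_localized_to_nearest_bin(self):
        fs = 400.0
        t = np.arange(int(60 * fs)) / fs
        psd = ra.welch_psd(np.sin(2 * np.pi * 4.0 * t), fs, nfft=1024)
        peak = psd.freqs_hz[np.argmax(psd.power)]
        nearest = psd.freqs_hz[np.argmin(np.abs(psd.freqs_hz - 4.0))]
        assert peak == nearest

    def test_white_noise_integral_matches_variance(self, rng):
        fs = 400.0
        x = rng.normal(0, 3.0, int(120 * fs))
        psd = ra.welch_psd(x, fs, nfft=1024)
        integral = np.trapezoid(psd.power, psd.freqs_hz)
        assert integral == pytest.approx(np.var(x), rel=0.05)

    def test_zeros_and_invalid_nfft(self):
        assert np.all(ra.welch_psd(np.zeros(2048), 400.0).power == 0)
        with pytest.raises(ra.ParameterError):
            ra.welch_psd(np.zeros(2048), 400.0, nfft=700)
        ra.welch_psd(np.zeros(2048), 400.0, nfft=700, allow_any_nfft=True)


class TestSpectrogram:
    def test_stationary_tone_dominates_every_column(self):
        fs = 400.0
        t = np.arange(int(120 * fs)) / fs
        spec = ra.spectrogram_stft(np.sin(2 * np.pi * 4.0 * t), fs)
        peak_bins = spec.freqs_hz[np.argmax(spec.power, axis=0)]
        assert np.all(np.abs(peak_bins - 4.0) < 0.1)

    def test_frequency_switch_tracked_in_time(self):
        fs = 400.0
        half = int(150 * fs)
        t = np.arange(2 * half) / fs
        x = np.where(t < 150, np.sin(2 * np.pi * 2.0 * t), np.sin(2 * np.pi * 8.0 * t))
        spec = ra.spectrogram_stft(x, fs, smooth_bins=0)
        dominant = spec.freqs_hz[np.argmax(spec.power, axis=0)]
        early = dominant[spec.times_s < 130]
        late = dominant[spec.times_s > 170]
        assert np.all(np.abs(early - 2.0) < 0.5)
        assert np.all(np.abs(late - 8.0) < 0.5)

    def test_time_bin_count_contract(self):
        fs, window_s, overlap = 400.0, 30.0, 0.6
        n = int(200 * fs)
        spec = ra.spectrogram_stft(np.zeros(n), fs, window_s, overlap)
        w = int(window_s * fs)
        hop = int(round(w * (1 - overlap)))
        assert len(spec.times_s) == (n - w) // hop + 1

    def test_invalid_overlap(self):
        with pytest.raises(ra.ParameterError):
            ra.spectrogram_stft(np.zeros(400 * 40), 400.0, overlap=0.99)


class TestBandpower:
    def test_flat_density_integrates_to_band_width(self):
        psd = ra.PSD(freqs_hz=np.linspace(0, 200, 513), power=np.full(513, 2.0), nfft=1024)
        assert ra.bandpower(psd, 0.5, 4.0) == pytest.approx(2.0 * 3.5)

    def test_zero_psd(self):
        psd = ra.PSD(freqs_hz=np.linspace(0, 200, 513), power=np.zeros(513), nfft=1024)
        assert ra.bandpower(psd, 5.0, 9.0) == 0.0

    def test_inverted_band_rejected(self):
        psd = ra.PSD(freqs_hz=np.linspace(0, 200, 513), power=np.zeros(513), nfft=1024)
        with pytest.raises(ra.ParameterError):
            ra.bandpower(psd, 9.0, 5.0)

    def test_synthetic_rem_is_theta_dominant(self):
        cfg = ra.SynthConfig(
            seed=5, state_mean_dwell_s={REM: 300.0},
            transition_probs={REM: {REM: 1.0}},
        )
        h = ra.generate_hypnogram(cfg, 300.0)
        rec = ra.generate_eeg_emg(cfg, h)
        psd = ra.welch_psd(rec.eeg, rec.fs, nfft=1024)
        assert ra.bandpower(psd, 5.0, 9.0) > ra.bandpower(psd, 0.5, 4.0)


class TestRelativeEMG:
    def emg_with_envelope(self, env_per_epoch, fs=400.0, epoch_s=10.0, seed=0):
        rng = np.random.default_rng(seed)
        n = int(len(env_per_epoch) * epoch_s * fs)
        env = np.repeat(env_per_epoch, int(epoch_s * fs))
        return env * rng.normal(0, 1.0, n)

    def test_pre_window_all_nrem_normalizes_to_one(self):
        labels = [NREM] * 6 + [WAKE] * 6
        emg = self.emg_with_envelope([1.0] * 12)
        rel = ra.relative_emg_amplitude(
            emg, 400.0, hyp(labels),
            {"pre": (0.0, 60.0), "stim": (60.0, 120.0)},
        )
        assert rel["pre"] == pytest.approx(1.0)

    def test_doubled_envelope_doubles_relative_amplitude(self):
        labels = [NREM] * 6 + [WAKE] * 6
        emg = self.emg_with_envelope([1.0] * 6 + [2.0] * 6)
        rel = ra.relative_emg_amplitude(
            emg, 400.0, hyp(labels),
            {"pre": (0.0, 60.0), "stim": (60.0, 120.0)},
        )
        assert rel["stim"] == pytest.approx(2.0, rel=0.1)

    def test_no_nrem_baseline_is_undefined(self):
        labels = [WAKE] * 12
        emg = self.emg_with_envelope([1.0] * 12)
        rel = ra.relative_emg_amplitude(
            emg, 400.0, hyp(labels),
            {"pre": (0.0, 60.0), "stim": (60.0, 120.0)},
        )
        assert all(np.isnan(v) for v in rel.values())
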