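"""Transient detector versus the exhaustive prominence oracle, plus
per-state statistics."""

import numpy as np
import pytest

import rhythmarousal as ra
from rhythmarousal import NREM, REM, WAKE
from rhythmarousal.photometry import ZScoreTrace
from rhythmarousal.transients import correct_rate_for_dead_time, resolvable_dead_time

from oracles import brute_transient_set


def ztrace(x, fs=100.0):
    x = np.asarray(x, dtype=float)
    return ZScoreTrace(time_s=np.arange(len(x)) / fs, z=x, fs=fs)


def gaussian_bump(amp=1.0, fwhm_s=0.5, fs=100.0, dur_s=10.0, center_s=5.0):
    t = np.arange(int(dur_s * fs)) / fs
    sigma = fwhm_s / (2 * np.sqrt(2 * np.log(2)))
    return amp * np.exp(-((t - center_s) ** 2) / (2 * sigma**2))


class TestDetector:
    def test_isolated_bump_prominence_equals_height(self):
        ts = ra.detect_transients(ztrace(gaussian_bump(1.0)))
        assert len(ts) == 1
        assert ts.prominence[0] == pytest.approx(1.0, rel=1e-6)
        assert ts.width_s[0] == pytest.approx(0.5, rel=0.02)
        assert ts.peak_time_s[0] == pytest.approx(5.0, abs=0.01)

    def test_bump_below_prominence_gate_dropped(self):
        """An 0.05-amplitude bump fails the 0.1 minimum prominence."""
        ts = ra.detect_transients(ztrace(gaussian_bump(0.05)))
        assert len(ts) == 0

    def test_narrow_peak_fails_width_gate(self):
        x = np.zeros(1000)
        x[500] = 1.0  # single-sample spike: width 1 sample = 10 ms at 100 Hz
        ts = ra.detect_transients(ztrace(x))
        assert len(ts) == 0

    def test_plateau_reports_leftmost_sample(self):
        x = np.zeros(1000)
        x[300:331] = 1.0
        ts = ra.detect_transients(ztrace(x))
        assert len(ts) == 1
        assert ts.peak_time_s[0] == pytest.approx(3.0, abs=1e-9)

    def test_empty_trace(self):
        ts = ra.detect_transients(ztrace([]))
        assert len(ts) == 0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_oracle_on_random_walks(self, seed):
        rng = np.random.default_rng(seed)
        x = np.cumsum(rng.normal(0, 0.3, 3000))
        fs = 100.0
        ts = ra.detect_transients(ztrace(x, fs))
        oracle = brute_transient_set(x, fs, 0.08, 0.1)
        assert len(ts) == len(oracle)
        for k, (idx, prom, width) in enumerate(oracle):
            assert ts.peak_time_s[k] == pytest.approx(idx / fs, abs=1e-12)
            assert ts.prominence[k] == pytest.approx(prom, abs=1e-9)
            assert ts.width_s[k] == pytest.approx(width, abs=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_threshold_monotonicity(self, seed):
        """Raising either gate never adds a transient."""
        rng = np.random.default_rng(100 + seed)
        x = np.cumsum(rng.normal(0, 0.3, 2000))
        z = ztrace(x)
        base = set(ra.detect_transients(z, min_prominence=0.1).peak_time_s)
        for prom in (0.2, 0.5, 1.0):
            tighter = set(ra.detect_transients(z, min_prominence=prom).peak_time_s)
            assert tighter <= base
        for width in (0.1, 0.2):
            tighter = set(ra.detect_transients(z, min_width_s=width).peak_time_s)
            assert tighter <= base


class TestStateStatistics:
    def hyp(self, labels):
        return ra.Hypnogram(labels=np.array(labels, dtype=object), epoch_s=10.0)

    def fake_ts(self, times, proms=None, duration=100.0, fs=100.0):
        times = np.asarray(times, dtype=float)
        proms = np.asarray(proms if proms is not None else np.ones_like(times))
        return ra.TransientSet(
            peak_time_s=times, peak_z=np.ones_like(times), prominence=proms,
            width_s=np.full_like(times, 0.2), trace_duration_s=duration, fs=fs,
        )

    def test_rate_arithmetic(self):
        """10 transients inside 5 min of WAKE: 2.0 events/min."""
        labels = [WAKE] * 30 + [NREM] * 30
        ts = self.fake_ts(np.linspace(5, 295, 10), duration=600.0)
        rates = ra.transient_rate_by_state(ts, self.hyp(labels))
        assert rates[WAKE] == pytest.approx(2.0)
        assert rates[NREM] == pytest.approx(0.0)

    def test_all_artifact_is_undefined(self):
        ts = self.fake_ts([5.0], duration=60.0)
        rates = ra.transient_rate_by_state(ts, self.hyp(["ARTIFACT"] * 6))
        assert all(np.isnan(v) for v in rates.values())

    def test_out_of_span_transient_warns_and_excluded(self):
        ts = self.fake_ts([5.0, 500.0], duration=600.0)
        with pytest.warns(UserWarning, match="outside"):
            rates = ra.transient_rate_by_state(ts, self.hyp([WAKE] * 6))
        assert rates[WAKE] == pytest.approx(1.0)

    def test_prominence_mean_by_state(self):
        labels = [REM] * 6
        ts = self.fake_ts([10.0, 30.0], proms=[0.2, 0.4], duration=60.0)
        proms = ra.transient_prominence_by_state(ts, self.hyp(labels))
        assert proms[REM] == pytest.approx(0.3)
        assert np.isnan(proms[WAKE])

    def test_counts_partition_across_states(self):
        """Summed per-state counts equal all transients in scored time."""
        rng = np.random.default_rng(5)
        labels = list(rng.choice([WAKE, NREM, REM, "ARTIFACT"], size=60))
        times = np.sort(rng.uniform(0, 600, 40))
        times = times[np.diff(np.concatenate(([-1.0], times))) > 1e-6]
        ts = self.fake_ts(times, duration=600.0)
        hyp = self.hyp(labels)
        rates = ra.transient_rate_by_state(ts, hyp)
        total = sum(
            rates[s] * hyp.state_seconds(s) / 60.0
            for s in ra.STATES if not np.isnan(rates[s])
        )
        states = hyp.state_at(times)
        expected = sum(1 for s in states if s in ra.STATES)
        assert total == pytest.approx(expected)

    def test_generator_rate_ordering_recovered(self):
        """WAKE-rich generator: recovered WAKE rate near truth, others low."""
        cfg = ra.SynthConfig(
            seed=3, n_trials=1, trial_on_s=900.0, trial_off_s=0.0,
            transient_rate_per_min={WAKE: 10.0, NREM: 0.0, REM: 0.0},
            motion_rate_per_min=0.0,
        )
        hyp = ra.generate_hypnogram(cfg, 900.0)
        sess, truth = ra.generate_photometry(cfg, hyp)
        z = ra.preprocess(sess)
        ts = ra.detect_transients(z, min_prominence=2.25)
        rates = ra.transient_rate_by_state(ts, hyp)
        n_wake_true = int(np.sum(truth.transient_states == WAKE))
        wake_min = hyp.state_seconds(WAKE) / 60.0
        assert abs(rates[WAKE] - n_wake_true / wake_min) < 3.0
        # other states see only boundary leakage and sparse noise peaks,
        # so the recovered WAKE rate dominates them by a wide margin
        others = [rates[s] for s in (NREM, REM) if not np.isnan(rates[s])]
        assert rates[WAKE] > 4 * max(others)

    def test_zscore_by_state_constant_and_trial_average(self):
        labels = [WAKE] * 3 + [NREM] * 3
        z1 = ZScoreTrace(
            time_s=np.arange(6000) / 100.0, z=np.full(6000, 0.1), fs=100.0,
            trial_slices=[(0, 3000), (3000, 6000)],
        )
        means = ra.zscore_by_state(z1, self.hyp(labels))
        assert means[WAKE] == pytest.approx(0.1)
        z2 = ZScoreTrace(
            time_s=np.arange(6000) / 100.0,
            z=np.concatenate([np.full(3000, 0.1), np.full(3000, 0.3)]),
            fs=100.0, trial_slices=[(0, 3000), (3000, 6000)],
        )
        hier = ra.zscore_by_state(z2, self.hyp([WAKE] * 6), per_trial=True)
        assert hier[WAKE] == pytest.approx(0.2)


class TestDeadTime:
    def test_correction_inverts_paralyzable_law(self):
        for rate in (1.0, 5.0, 10.0):
            d = 1.5
            observed = rate / 60.0 * np.exp(-rate / 60.0 * d) * 60.0
            assert correct_rate_for_dead_time(observed, d) == pytest.approx(rate, rel=1e-9)

    def test_zero_dead_time_is_identity(self):
        assert correct_rate_for_dead_time(7.3, 0.0) == 7.3

    def test_resolvable_dead_time_scales_with_threshold(self):
        from rhythmarousal.synth import transient_kernel

        cfg = ra.SynthConfig()
        k, _ = transient_kernel(cfg, 120.0)
        d_low = resolvable_dead_time(k, 120.0, 0.1)
        d_high = resolvable_dead_time(k, 120.0, 0.5)
        assert 0 < d_low < d_high
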