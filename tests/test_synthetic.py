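"""The generator must have the statistical structure the analysis assumes:
gamma dominance durations, sawtooth OKN gaze, annotated blinks, RT-lagged
keypresses, and a pupil trace that is exactly the sum of its parts."""

import numpy as np
import pytest

from pupilswitch import SimConfig, synthetic
from pupilswitch.synthetic import (
    simulate_condition,
    simulate_gaze,
    simulate_keypresses_and_probes,
    simulate_percept_timeline,
    simulate_pupil,
)


class TestPerceptTimeline:
    def test_near_deterministic_durations_give_expected_episode_count(self):
        # shape -> infinity approximated by 10000: durations ~ mean 3 s,
        # so a 60 s trial holds 20 +/- 1 episodes
        cfg = SimConfig(n_trials=1, trial_len_s=60.0,
                        dominance_gamma_shape=10000.0,
                        dominance_gamma_scale=3.0 / 10000.0)
        tl = simulate_percept_timeline(cfg, np.random.default_rng(0))
        assert 19 <= len(tl.episodes) <= 21

    def test_empirical_mean_duration_matches_gamma_mean(self):
        # law of large numbers vs the analytic gamma mean = shape * scale
        cfg = SimConfig(n_trials=24, trial_len_s=60.0,
                        dominance_gamma_shape=2.0, dominance_gamma_scale=1.5)
        tl = simulate_percept_timeline(cfg, np.random.default_rng(1))
        # exclude episodes truncated at trial ends
        full = [ep.duration_ms for ep in tl.episodes
                if not any(abs(ep.offset_ms - t1) < 1e-9
                           for _, t1 in cfg.trial_bounds_ms())]
        assert np.mean(full) / 1000.0 == pytest.approx(3.0, rel=0.10)

    def test_alternating_states_and_tiling(self, small_cfg, rng):
        tl = simulate_percept_timeline(small_cfg, rng)
        for t0, t1 in small_cfg.trial_bounds_ms():
            eps = [e for e in tl.episodes if t0 <= e.onset_ms < t1]
            assert eps[0].onset_ms == t0 and eps[-1].offset_ms == t1
            for a, b in zip(eps, eps[1:]):
                assert a.offset_ms == b.onset_ms
                assert a.state != b.state

    def test_seed_determinism(self, small_cfg):
        t1 = simulate_percept_timeline(small_cfg, np.random.default_rng(7))
        t2 = simulate_percept_timeline(small_cfg, np.random.default_rng(7))
        assert np.array_equal(t1.switch_times, t2.switch_times)
        assert t1.switch_directions == t2.switch_directions


class TestGaze:
    def test_single_episode_cleaned_slope_sign_constant(self):
        # the raw sawtooth is mean-reverting by construction (quick phases
        # cancel the slow drift); after saccade removal and displacement
        # collation the cleaned signal drifts monotonically in the state's
        # direction, so every windowed slope has the state's sign
        from pupilswitch.gaze_events import clean_gaze
        from pupilswitch.okn import windowed_direction
        from pupilswitch.pipeline import detect_ocular_events
        from pupilswitch import RunConfig

        cfg = SimConfig(n_trials=1, trial_len_s=10.0, gaze_noise_sd=0.01,
                        blink_rate_hz=0.0, dominance_gamma_shape=10000.0,
                        dominance_gamma_scale=60.0 / 10000.0)
        tl = simulate_percept_timeline(cfg, np.random.default_rng(3))
        assert len(tl.switches) == 0
        rec, _ = simulate_gaze(tl, cfg, np.random.default_rng(3))
        sign = 1.0 if tl.episodes[0].state == "A" else -1.0
        sacc, blinks = detect_ocular_events(rec, RunConfig())
        clean = clean_gaze(rec, sacc, blinks)
        series = windowed_direction(
            clean["time_ms"], clean["x"], clean["y"], rec.trials)
        assert np.all(np.sign(series.values) == sign)

    def test_blink_bookkeeping_identity(self, small_cfg, rng):
        tl = simulate_percept_timeline(small_cfg, rng)
        rec, blinks = simulate_gaze(tl, small_cfg, rng)
        dt = rec.dt_ms
        n_expected = sum(
            int(np.searchsorted(rec.time_ms, off)) - int(np.searchsorted(rec.time_ms, on))
            for on, off in blinks)
        assert int(np.isnan(rec.xl).sum()) == n_expected

    def test_seed_determinism(self, small_cfg):
        a = simulate_condition(small_cfg, np.random.default_rng(9))
        b = simulate_condition(small_cfg, np.random.default_rng(9))
        assert np.array_equal(a.recording.xl, b.recording.xl, equal_nan=True)
        assert np.array_equal(a.recording.pl, b.recording.pl, equal_nan=True)


class TestPupil:
    def test_single_switch_noiseless_trace_is_kernel(self):
        cfg = SimConfig(n_trials=1, trial_len_s=20.0, noise_sd=0.0,
                        drift_amp=0.0, covariate_beta=0.0, sample_rate_hz=100.0)
        from pupilswitch.types import Episode, PerceptTimeline, Switch
        tl = PerceptTimeline(
            [Episode("A", 0.0, 8000.0), Episode("B", 8000.0, 20000.0)],
            [Switch(8000.0, "B")])
        t_ms, trace, _ = simulate_pupil(tl, np.empty(0), cfg, np.random.default_rng(0))
        kl, kv = cfg.constriction_kernel()
        kern = synthetic.resample_kernel(kl, kv, cfg.sample_rate_hz)
        i0 = int(round(8000.0 / (1000.0 / cfg.sample_rate_hz)))
        np.testing.assert_allclose(trace[i0:i0 + len(kern)], kern, atol=1e-12)
        assert np.all(trace[:i0] == 0)
        assert np.all(trace[i0 + len(kern):] == 0)

    def test_two_events_superpose_linearly(self):
        cfg = SimConfig(n_trials=1, trial_len_s=20.0, noise_sd=0.0,
                        drift_amp=0.0, sample_rate_hz=100.0)
        from pupilswitch.types import Episode, PerceptTimeline, Switch
        tl1 = PerceptTimeline(
            [Episode("A", 0.0, 5000.0), Episode("B", 5000.0, 20000.0)],
            [Switch(5000.0, "B")])
        tl2 = PerceptTimeline(
            [Episode("A", 0.0, 6000.0), Episode("B", 6000.0, 20000.0)],
            [Switch(6000.0, "B")])
        _, tr1, _ = simulate_pupil(tl1, np.empty(0), cfg, np.random.default_rng(0))
        _, tr2, _ = simulate_pupil(tl2, np.empty(0), cfg, np.random.default_rng(0))
        both = PerceptTimeline(
            [Episode("A", 0.0, 5000.0), Episode("B", 5000.0, 6000.0),
             Episode("A", 6000.0, 20000.0)],
            [Switch(5000.0, "B"), Switch(6000.0, "A")])
        _, tr_both, _ = simulate_pupil(both, np.empty(0), cfg, np.random.default_rng(0))
        np.testing.assert_allclose(tr_both, tr1 + tr2, atol=1e-12)

    def test_amplitudes_track_zscored_log_durations(self, rng):
        cfg = SimConfig(n_trials=4, trial_len_s=30.0, covariate_beta=0.5,
                        sample_rate_hz=100.0, noise_sd=0.0)
        tl = simulate_percept_timeline(cfg, rng)
        _, _, comp = simulate_pupil(tl, np.empty(0), cfg, rng)
        z = synthetic.zscore_log(synthetic.preceding_durations_ms(tl))
        np.testing.assert_allclose(comp["switch_amplitudes"], 1.0 + 0.5 * z)
        assert np.corrcoef(comp["switch_amplitudes"], z)[0, 1] == pytest.approx(1.0)


class TestKeypressesAndProbes:
    def test_degenerate_rt_reproduces_fixed_lag(self, rng):
        cfg = SimConfig(n_trials=2, trial_len_s=30.0, rt_mean_s=0.5, rt_sd_s=0.0)
        tl = simulate_percept_timeline(cfg, rng)
        kp, _ = simulate_keypresses_and_probes(tl, cfg, rng, "report")
        sw = tl.switch_times
        # every press is exactly 500 ms after its switch
        assert all(np.isclose((kp[:, None] - sw[None, :]), 500.0).any(axis=1).tolist())

    def test_probe_gaps_within_configured_range(self, rng):
        cfg = SimConfig(n_trials=4, trial_len_s=60.0)
        probes = synthetic.simulate_probes(cfg, rng)
        for t0, t1 in cfg.trial_bounds_ms():
            in_trial = probes[(probes >= t0) & (probes < t1)]
            gaps = np.diff(in_trial) / 1000.0
            assert np.all(gaps >= 3.0) and np.all(gaps <= 8.0)

    def test_probe_count_matches_renewal_expectation(self):
        cfg = SimConfig(n_trials=12, trial_len_s=60.0)
        probes = synthetic.simulate_probes(cfg, np.random.default_rng(11))
        expected = 720.0 / 5.5  # total stimulus time over the mean gap
        assert len(probes) == pytest.approx(expected, rel=0.2)

    def test_rts_truncated_above_minimum(self, rng):
        cfg = SimConfig(n_trials=2, trial_len_s=30.0, rt_mean_s=0.15, rt_sd_s=0.2)
        tl = simulate_percept_timeline(cfg, rng)
        kp, _ = simulate_keypresses_and_probes(tl, cfg, rng, "report")
        lags = np.array([np.min(k - tl.switch_times[tl.switch_times < k]) for k in kp])
        assert np.all(lags > 100.0)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"sample_rate_hz": 0}, {"dominance_gamma_shape": -1},
        {"probe_interval_range_s": (8.0, 3.0)}, {"n_trials": 0},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)
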