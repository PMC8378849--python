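"""Design-matrix construction and deconvolution: Fourier term counts, exact
kernel recovery, equivalence of the FIR solution with a direct
normal-equations oracle, covariate arithmetic, quantile grouping, and the
event-selection rules for the study designs."""

import numpy as np
import pytest

from pupilswitch import RunConfig
from pupilswitch.glm import (
    Design,
    RegressorSpec,
    build_event_regressors,
    duration_covariate,
    filter_blink_events,
    fir_deconvolve,
    fit_glm,
    fourier_basis,
    lag_grid,
    make_design,
    merge_close_saccades,
    quantile_split,
    unreported_probes,
)
from pupilswitch.types import OcularEvent


class TestFourierBasis:
    @pytest.mark.parametrize("window, n_terms", [
        ((-3.5, 6.5), 21),   # 10 s switch/keypress window
        ((-0.5, 7.5), 17),   # 8 s blink window
        ((-0.5, 4.5), 11),   # 5 s saccade window
    ])
    def test_term_counts_at_one_hz(self, window, n_terms):
        assert fourier_basis(window).shape[1] == n_terms

    def test_too_short_window_degenerates_to_constant(self):
        b = fourier_basis((0.0, 0.5), max_freq_hz=1.0)
        assert b.shape[1] == 1

    def test_lag_grid_spacing(self):
        lags = lag_grid((-3.5, 6.5))
        assert len(lags) == 101
        assert np.allclose(np.diff(lags), 0.1)
        assert lags[0] == -3.5 and lags[-1] == pytest.approx(6.5)


def _simple_trace(n_bins, events_bins, kernel):
    y = np.zeros(n_bins)
    for b in events_bins:
        hi = min(b + len(kernel), n_bins)
        y[b:hi] += kernel[: hi - b]
    return y


class TestFitGLM:
    def test_exact_recovery_of_basis_expressible_kernel(self):
        # kernel built inside the Fourier span -> OLS recovers it to 1e-6
        rng = np.random.default_rng(0)
        window = (0.0, 6.0)
        basis = fourier_basis(window)
        coefs = rng.normal(size=basis.shape[1])
        kernel = basis @ coefs
        n_bins = 3000
        events = np.array([200, 500, 520, 900, 1500, 2200]) * 100.0
        y = _simple_trace(n_bins, (events / 100).astype(int), kernel)
        spec = RegressorSpec("k", events, window)
        fit = fit_glm(y, make_design([spec], n_bins))
        np.testing.assert_allclose(fit.curves["k"].values, kernel, atol=1e-6)

    def test_overlapping_event_types_resolved_where_averaging_fails(self):
        rng = np.random.default_rng(1)
        window = (0.0, 5.0)
        k1 = fourier_basis(window) @ rng.normal(size=11)
        k2 = fourier_basis(window) @ rng.normal(size=11)
        n_bins = 6000
        ev1 = np.sort(rng.choice(np.arange(100, 5800), 80, replace=False)) * 100.0
        # systematic overlap with jittered lags (a constant lag would make
        # the two regressors unidentifiable)
        ev2 = ev1 + rng.integers(3, 15, size=len(ev1)) * 100.0
        y = (_simple_trace(n_bins, (ev1 / 100).astype(int), k1)
             + _simple_trace(n_bins, (ev2 / 100).astype(int), k2))
        specs = [RegressorSpec("a", ev1, window), RegressorSpec("b", ev2, window)]
        fit = fit_glm(y, make_design(specs, n_bins))
        glm_err = np.max(np.abs(fit.curves["a"].values - k1))
        # event-locked averaging is contaminated by the overlapping k2
        avg = np.mean([y[int(b):int(b) + 51] for b in ev1 / 100
                       if b + 51 <= n_bins], axis=0)
        avg_err = np.max(np.abs(avg - k1))
        assert glm_err < 1e-6
        assert avg_err > 10 * max(glm_err, 1e-9)

    def test_zero_trace_zero_coefficients(self):
        spec = RegressorSpec("k", np.array([1000.0, 5000.0]), (0.0, 5.0))
        fit = fit_glm(np.zeros(100), make_design([spec], 100))
        np.testing.assert_allclose(fit.coefficients, 0.0, atol=1e-12)

    def test_curves_invariant_to_regressor_order(self):
        rng = np.random.default_rng(2)
        window = (0.0, 4.0)
        y = rng.normal(size=2000)
        e1 = np.sort(rng.choice(np.arange(50, 1900), 40, replace=False)) * 100.0
        e2 = np.sort(rng.choice(np.arange(50, 1900), 40, replace=False)) * 100.0
        s1 = [RegressorSpec("a", e1, window), RegressorSpec("b", e2, window)]
        s2 = [RegressorSpec("b", e2, window), RegressorSpec("a", e1, window)]
        f1 = fit_glm(y, make_design(s1, 2000))
        f2 = fit_glm(y, make_design(s2, 2000))
        np.testing.assert_allclose(f1.curves["a"].values, f2.curves["a"].values,
                                   atol=1e-8)


class TestFIRDeconvolve:
    def test_isolated_event_recovers_kernel_exactly(self):
        kernel = np.array([0.0, 1.0, 2.0, 1.0, 0.5, 0.0])
        y = _simple_trace(200, [50], kernel)
        curve = fir_deconvolve(y, np.array([5000.0]), (0.0, 0.5))
        np.testing.assert_allclose(curve.values, kernel, atol=1e-9)

    def test_overlapping_events_match_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        kernel = rng.normal(size=8)
        events = np.array([10, 14, 30, 33, 60]) * 100.0
        y = _simple_trace(120, [10, 14, 30, 33, 60], kernel)
        y += rng.normal(0, 0.1, 120)
        curve = fir_deconvolve(y, events, (0.0, 0.7))
        # oracle: build the indicator convolution matrix explicitly
        X = np.zeros((120, 8))
        for b in [10, 14, 30, 33, 60]:
            for l in range(8):
                if b + l < 120:
                    X[b + l, l] += 1.0
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(curve.values, beta, atol=1e-8)

    def test_fir_and_fourier_agree_on_band_limited_data(self):
        rng = np.random.default_rng(4)
        window = (0.0, 6.0)
        basis = fourier_basis(window)  # band-limited by construction
        kernel = basis @ rng.normal(size=13)
        n_bins = 5000
        events = np.sort(rng.choice(np.arange(100, 4900), 60, replace=False)) * 100.0
        y = _simple_trace(n_bins, (events / 100).astype(int), kernel)
        fir = fir_deconvolve(y, events, window)
        four = fit_glm(y, make_design(
            [RegressorSpec("k", events, window)], n_bins)).curves["k"]
        rmse = np.sqrt(np.mean((fir.values - four.values) ** 2))
        assert rmse < 0.05 * np.max(np.abs(kernel))

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError):
            fir_deconvolve(np.zeros(100), np.empty(0), (0.0, 1.0))


class TestDurationCovariate:
    def test_known_values(self):
        z = duration_covariate(np.array([1.0, np.e, np.e ** 2]))
        np.testing.assert_allclose(z, [-1.2247, 0.0, 1.2247], atol=1e-4)

    def test_equal_durations_all_zero(self):
        np.testing.assert_allclose(duration_covariate(np.full(5, 2.0)), 0.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            duration_covariate(np.array([1.0, 0.0]))

    def test_lognormal_sample_approximately_standard_normal(self):
        rng = np.random.default_rng(5)
        z = duration_covariate(rng.lognormal(0.5, 0.7, 5000))
        assert abs(z.mean()) < 1e-12
        assert z.std(ddof=0) == pytest.approx(1.0)
        from scipy import stats
        assert stats.kstest(z, "norm").pvalue > 0.01


class TestQuantileSplit:
    def test_even_split(self):
        t = np.arange(9) * 1000.0
        groups = quantile_split(t, np.arange(1.0, 10.0), 3)
        assert [g.tolist() for g in groups] == [[0, 1, 2], [3, 4, 5], [6, 7, 8]]

    def test_uneven_split_sizes(self):
        groups = quantile_split(np.arange(10) * 1000.0, np.arange(10.0) + 1, 3)
        assert [len(g) for g in groups] == [4, 3, 3]

    def test_ties_broken_by_time(self):
        t = np.array([5000.0, 1000.0, 3000.0])
        groups = quantile_split(t, np.ones(3), 3)
        # equal durations: order follows event time
        assert [t[g[0]] for g in groups] == [1000.0, 3000.0, 5000.0]

    def test_too_many_groups_rejected(self):
        with pytest.raises(ValueError):
            quantile_split(np.arange(2) * 1000.0, np.ones(2), 3)


class TestEventSelectionRules:
    def test_close_saccade_pairs_merged(self):
        evs = [OcularEvent("saccade", 0, 30), OcularEvent("saccade", 110, 140)]
        assert len(merge_close_saccades(evs)) == 1  # 80 ms gap < 100 ms
        evs2 = [OcularEvent("saccade", 0, 30), OcularEvent("saccade", 140, 170)]
        assert len(merge_close_saccades(evs2)) == 2  # 110 ms gap

    def test_blink_duration_bounds(self):
        evs = [OcularEvent("blink", 0, 120), OcularEvent("blink", 0, 130),
               OcularEvent("blink", 0, 900), OcularEvent("blink", 0, 950)]
        kept = filter_blink_events(evs)
        assert [e.duration_ms for e in kept] == [130, 900]

    def test_probe_with_nearby_report_not_unreported(self):
        probes = np.array([1000.0, 10000.0])
        kps = np.array([2500.0])  # 1.5 s after the first probe
        out = unreported_probes(probes, kps)
        assert out.tolist() == [10000.0]

    def test_trial_edge_events_excluded_from_design(self):
        run_cfg = RunConfig()
        trial_map = np.full(1200, -1)
        trial_map[100:700] = 0   # one 60 s trial at 10 Hz
        # event at bin 120: window -3.5 s reaches bin 85 < trial start
        specs = [RegressorSpec("s", np.array([12000.0, 40000.0]), (-3.5, 6.5))]
        d = make_design(specs, 1200, trial_map)
        assert d.kept_events[0].tolist() == [False, True]

    def test_build_event_regressors_designs(self):
        ev = lambda stim, task, kp: {
            "stimulus": stim, "task": task,
            "switch_times_ms": np.array([5000.0, 9000.0]),
            "preceding_dur_ms": np.array([2000.0, 4000.0]),
            "following_dur_ms": np.array([4000.0, 3000.0]),
            "keypress_times_ms": np.array(kp),
            "probe_times_ms": np.array([6000.0] if task == "ignore" else []),
            "saccades": [], "blinks": [],
            "trial_start_ms": np.array([0.0]),
        }
        conds = {
            "rivalry_ignore": ev("rivalry", "ignore", [6500.0]),
            "rivalry_report": ev("rivalry", "report", [5500.0, 9500.0]),
            "onscreen_ignore": ev("onscreen", "ignore", [6500.0]),
            "onscreen_report": ev("onscreen", "report", [5500.0, 9500.0]),
        }
        per = build_event_regressors(conds, "per-condition")
        names = [s.name for s in per]
        assert sum(n.startswith("switch:") for n in names) == 4
        assert "keypress" in names and "trial_start" in names
        pooled = build_event_regressors(conds, "pooled")
        pnames = [s.name for s in pooled]
        assert "switch:rivalry" in pnames and "switch:onscreen" in pnames
        kp_spec = next(s for s in pooled if s.name == "keypress")
        assert len(kp_spec.event_times_ms) == 6  # all conditions pooled
        cov = build_event_regressors(conds, "per-condition",
                                     covariate_side="preceding")
        cnames = [s.name for s in cov]
        assert sum(":dur_preceding" in n for n in cnames) == 4
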