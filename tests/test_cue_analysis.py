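import numpy as np
import pandas as pd
import pytest

from antbridge import (
    EventKind,
    EventStream,
    FlowSeries,
    ModelSpec,
    ParameterError,
    Phase,
    SynthConfig,
    compute_performance,
    event_preceding_mean,
    event_timing_uniformity,
    generate_dataset,
    resample_null,
    tautness_resample,
    trial_performance,
    window_sensitivity,
)
from antbridge.model_params import FitError, NBEventModel
from antbridge.synthetic_data import generate_trial

from conftest import make_interval_trial


def _flow(bridge, fa, fb):
    n = len(bridge)
    return FlowSeries(
        pd.DataFrame(
            {
                "t0": 10.0 * np.arange(n),
                "flow_bridge": bridge,
                "flow_platform_a": fa,
                "flow_platform_b": fb,
            }
        )
    )


def _near_poisson_model():
    vals = {
        (EventKind.JOIN, Phase.EXPANSION): 1.13,
        (EventKind.LEAVE, Phase.EXPANSION): 0.67,
        (EventKind.JOIN, Phase.CONTRACTION): 0.33,
        (EventKind.LEAVE, Phase.CONTRACTION): 1.04,
    }
    return ModelSpec.baseline(
        {
            (k, p): NBEventModel(mu=m, theta=1e5, phase=p, kind=k)
            for (k, p), m in vals.items()
        }
    )


class TestComputePerformance:
    def test_exact_linear_flow_gives_zero_residuals(self):
        rng = np.random.default_rng(0)
        fa = rng.uniform(5, 10, 20)
        fb = rng.uniform(5, 10, 20)
        bridge = 1.0 + 0.5 * (fa + fb)
        perf = compute_performance(_flow(bridge, fa, fb))
        np.testing.assert_allclose(perf.perf["performance"], 0.0, atol=1e-12)

    def test_three_point_leverage_algebra(self):
        # bump one response by c: its residual rises by c * (1 - leverage),
        # verified against the hand-computed hat matrix of a 3-point fit
        fa = np.array([1.0, 2.0, 3.0])
        fb = np.zeros(3)
        base = np.array([2.0, 2.5, 3.0])
        c = 1.5
        x = fa + fb
        X = np.column_stack([np.ones(3), x])
        H = X @ np.linalg.inv(X.T @ X) @ X.T
        bumped = base.copy()
        bumped[1] += c
        import antbridge.cue_analysis as ca

        old_min = ca.MIN_FLOW_INTERVALS
        ca.MIN_FLOW_INTERVALS = 3
        try:
            r0 = compute_performance(_flow(base, fa, fb)).perf["performance"]
            r1 = compute_performance(_flow(bumped, fa, fb)).perf["performance"]
        finally:
            ca.MIN_FLOW_INTERVALS = old_min
        assert r1[1] - r0[1] == pytest.approx(c * (1 - H[1, 1]))

    def test_residuals_sum_to_zero(self, small_dataset):
        trials, _ = small_dataset
        for trial in trials:
            perf = trial_performance(trial)
            assert perf.perf["performance"].sum() == pytest.approx(0.0, abs=1e-8)

    def test_degenerate_predictor_rejected(self):
        with pytest.raises(FitError, match="no variance"):
            compute_performance(_flow(np.arange(12.0), np.full(12, 5.0), np.full(12, 3.0)))

    def test_injected_boost_raises_prejoin_performance(self):
        cfg = SynthConfig(n_trials=3, seed=31, prejoin_perf_boost=4.0)
        trials, _ = generate_dataset(cfg)
        pairs = [(t, trial_performance(t)) for t in trials]
        obs = event_preceding_mean(pairs, "join", "expansion")
        assert obs > 0.5


class TestEventPrecedingMean:
    def _toy(self, values, event_offsets):
        # single 3-interval expansion trial with a crafted per-second cue:
        # use tautness as the cue carrier for hand enumeration
        trial = make_interval_trial(
            gaps=[1, 2, 3], n_starts=[1, 1, 1],
            joins=[0, 0, 0], leaves=[0, 0, 0],
        )
        st = trial.structural.copy()
        st.loc[: len(values) - 1, "tautness"] = values
        trial.structural = st
        ev = pd.DataFrame(
            {"time": event_offsets, "kind": ["leave"] * len(event_offsets)}
        )
        balance = pd.DataFrame(
            {"time": [91.0] * len(event_offsets), "kind": ["join"] * len(event_offsets)}
        )
        trial.events = EventStream(pd.concat([ev, balance]))
        return trial

    def test_constant_cue_single_event(self):
        values = np.full(90, 0.37)
        trial = self._toy(values, [50.0])
        prepared_mean = event_preceding_mean(
            [(trial, None)], "leave", "expansion", window=10
        )
        assert prepared_mean == pytest.approx(0.37)

    def test_hand_enumerated_five_events(self):
        rng = np.random.default_rng(5)
        values = rng.uniform(0, 1, 90)
        times = [12.3, 25.0, 40.0, 61.7, 88.0]
        trial = self._toy(values, times)
        got = event_preceding_mean([(trial, None)], "leave", "expansion", window=10)
        # brute force: mean of the 10 per-second values before each event's second
        per_event = [values[int(t) - 10 : int(t)].mean() for t in times]
        assert got == pytest.approx(np.mean(per_event))

    def test_no_usable_events_rejected(self):
        trial = self._toy(np.full(90, 0.5), [50.0])
        with pytest.raises(ParameterError, match="join"):
            event_preceding_mean([(trial, None)], "join", "expansion")


class TestResampling:
    def test_constant_cue_never_significant(self):
        trial = make_interval_trial(
            gaps=[1, 2, 3, 4], n_starts=[1, 1, 1, 1],
            joins=[0, 1, 1, 0], leaves=[0, 0, 1, 1],
        )
        res = tautness_resample([trial], "expansion", n_resamples=200, seed=0)
        assert np.allclose(res.null_means, 0.5)
        assert res.observed_mean == pytest.approx(0.5)
        assert not res.significant
        assert res.p_two_tailed == 1.0

    def test_seed_reproducible_and_law_of_total_expectation(self, small_dataset):
        trials, _ = small_dataset
        pairs = [(t, trial_performance(t)) for t in trials]
        a = resample_null(pairs, "join", "expansion", n_resamples=500, seed=7)
        b = resample_null(pairs, "join", "expansion", n_resamples=500, seed=7)
        np.testing.assert_array_equal(a.null_means, b.null_means)
        # the null's grand mean approaches the candidate-second mean
        from antbridge.cue_analysis import _prepare

        cands = np.concatenate(
            [
                _prepare(t, p, EventKind.JOIN, Phase.EXPANSION, 10).candidate_W
                for t, p in pairs
            ]
        )
        assert a.null_means.mean() == pytest.approx(cands.mean(), abs=0.05)

    def test_strong_effect_detected_above_upper_tail(self):
        cfg = SynthConfig(n_trials=3, seed=37, prejoin_perf_boost=5.0)
        trials, _ = generate_dataset(cfg)
        pairs = [(t, trial_performance(t)) for t in trials]
        res = resample_null(pairs, "join", "expansion", n_resamples=1000, seed=2)
        assert res.significant
        assert res.observed_mean > np.quantile(res.null_means, 0.975)

    def test_type_one_error_calibrated(self):
        # no injected effect, exchangeable (near-Poisson) event timing:
        # the central-95% rule should reject ~5% of syntheses
        model = _near_poisson_model()
        hits = 0
        reps = 400
        for rep in range(reps):
            cfg = SynthConfig(n_trials=1, seed=50_000 + rep, model=model)
            trials, _ = generate_dataset(cfg)
            pairs = [(t, trial_performance(t)) for t in trials]
            res = resample_null(
                pairs, "join", "expansion", n_resamples=300, seed=rep
            )
            hits += res.significant
        assert 0.03 <= hits / reps <= 0.07

    def test_injected_tautness_drop_detected(self):
        cfg = SynthConfig(n_trials=3, seed=41, preleave_tautness_drop=0.4)
        trials, _ = generate_dataset(cfg)
        res = tautness_resample(trials, "expansion", n_resamples=1000, seed=3)
        assert res.significant
        assert res.observed_mean < np.quantile(res.null_means, 0.025)

    def test_more_events_than_candidates_rejected(self):
        trial = make_interval_trial(
            gaps=[1], n_starts=[1], joins=[40], leaves=[0]
        )
        with pytest.raises(ParameterError, match="candidate"):
            tautness_resample([trial], "expansion", kind="join",
                              n_resamples=10, seed=0, window=1)


class TestWindowSensitivity:
    def test_strong_effect_significant_at_all_windows(self):
        cfg = SynthConfig(n_trials=3, seed=37, prejoin_perf_boost=5.0)
        trials, _ = generate_dataset(cfg)
        pairs = [(t, trial_performance(t)) for t in trials]
        table = window_sensitivity(
            pairs, "join", "expansion", windows=[5, 10, 20],
            n_resamples=400, seed=5,
        )
        assert table["significant"].all()
        assert len(table) == 3

    def test_single_window_matches_resample_null(self, small_dataset):
        trials, _ = small_dataset
        pairs = [(t, trial_performance(t)) for t in trials]
        table = window_sensitivity(
            pairs, "join", "expansion", windows=[10], n_resamples=300, seed=9
        )
        direct = resample_null(
            pairs, "join", "expansion", window=10, n_resamples=300, seed=9
        )
        assert table.loc[0, "observed_mean"] == pytest.approx(direct.observed_mean)
        assert table.loc[0, "p_two_tailed"] == pytest.approx(direct.p_two_tailed)


class TestTimingUniformity:
    def test_uniform_offsets_not_flagged(self):
        rng = np.random.default_rng(13)
        times = np.sort(rng.uniform(0, 1830, 300))
        _, p = event_timing_uniformity(times)
        assert p > 0.01

    def test_interval_locked_events_strongly_flagged(self):
        times = 30.0 * np.arange(60) + 0.01
        _, p = event_timing_uniformity(times)
        assert p < 1e-6

    def test_three_event_statistic_matches_hand_computation(self):
        # offsets 3, 15, 27 in a 30-s interval; KS distance against U(0,30):
        # max deviation between empirical CDF steps and t/30
        times = np.array([33.0, 75.0, 117.0])
        stat, _ = event_timing_uniformity(times)
        offsets = np.sort(times % 30) / 30  # 0.1, 0.5, 0.9
        ecdf_hi = np.arange(1, 4) / 3 - offsets
        ecdf_lo = offsets - np.arange(0, 3) / 3
        assert stat == pytest.approx(max(ecdf_hi.max(), ecdf_lo.max()))

    def test_generated_events_pass_uniformity(self):
        cfg = SynthConfig(n_trials=1, seed=19)
        trial, _ = generate_trial(cfg, 0)
        times = trial.events.times
        times = times[times < 61 * 30]  # exclude the disassembly tail
        _, p = event_timing_uniformity(times)
        assert p > 0.01
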