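import numpy as np
import pytest
from scipy import stats

from antbridge import (
    EventKind,
    FitError,
    NoEquilibriumError,
    ParameterError,
    Phase,
    apply_delay_reassignment,
    estimate_equilibrium_density,
    fit_deficit_regression,
    fit_nb_counts,
    interval_table,
    nb_draw,
)
from antbridge.model_params import THETA_CAP, fit_nb_mle

from conftest import make_interval_trial


class TestNBDraw:
    def test_zero_mean_always_zero(self):
        rng = np.random.default_rng(0)
        assert nb_draw(0.0, 1.0, rng) == 0
        assert nb_draw(0.0, 1.0, rng, size=100).sum() == 0

    def test_moments_match_parameterization(self):
        # variance of NB(mu, theta) is mu + mu^2/theta
        mu, theta = 1.13, 1.33
        draws = nb_draw(mu, theta, np.random.default_rng(1), size=1_000_000)
        expect_var = mu + mu**2 / theta
        assert draws.mean() == pytest.approx(mu, abs=0.01)
        assert draws.var() == pytest.approx(expect_var, rel=0.02)

    def test_pmf_matches_closed_form(self):
        mu, theta = 1.0, 2.0
        n = 200_000
        draws = nb_draw(mu, theta, np.random.default_rng(2), size=n)
        ks = np.arange(11)
        p = theta / (theta + mu)
        expected = stats.nbinom.pmf(ks, theta, p) * n
        observed = np.bincount(np.minimum(draws, 10), minlength=11)[:11]
        observed[10] = n - observed[:10].sum()
        expected[10] = n - expected[:10].sum()
        chi2 = ((observed - expected) ** 2 / expected).sum()
        assert chi2 < stats.chi2.ppf(0.999, df=10)

    def test_invalid_parameters_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ParameterError):
            nb_draw(-1.0, 1.0, rng)
        with pytest.raises(ParameterError):
            nb_draw(1.0, 0.0, rng)


class TestNBFit:
    def test_parameter_recovery_median_of_trials(self):
        # 10 trials x 61 intervals from NB(0.8, 1.5); tolerances from the
        # observed spread of the median-of-fits estimator at this size
        rng = np.random.default_rng(3)
        trials = []
        for i in range(10):
            counts = nb_draw(0.8, 1.5, rng, size=61)
            trials.append(
                make_interval_trial(
                    gaps=np.zeros(61),
                    n_starts=np.zeros(61, dtype=int),
                    joins=list(counts),
                    leaves=[0] * 61,
                    trial_id=f"t{i}",
                )
            )
        model = fit_nb_counts(trials, EventKind.JOIN, Phase.EXPANSION)
        assert model.mu == pytest.approx(0.8, abs=0.15)
        assert 0.9 < model.theta < 3.0

    def test_constant_counts_hit_poisson_boundary(self):
        mu, theta = fit_nb_mle(np.full(40, 3))
        assert mu == 3.0
        assert theta == THETA_CAP

    def test_all_zero_counts_undefined_dispersion(self):
        with pytest.raises(FitError, match="undefined"):
            fit_nb_mle(np.zeros(30))

    def test_all_zero_trial_dropped_with_warning(self):
        active = make_interval_trial(
            gaps=np.zeros(30), n_starts=np.zeros(30, dtype=int),
            joins=[2, 0, 1] * 10, leaves=[0] * 30, trial_id="active",
        )
        silent = make_interval_trial(
            gaps=np.zeros(30), n_starts=np.zeros(30, dtype=int),
            joins=[0] * 30, leaves=[0] * 30, trial_id="silent",
        )
        with pytest.warns(UserWarning, match="silent"):
            model = fit_nb_counts([active, silent], EventKind.JOIN, Phase.EXPANSION)
        assert model.mu == pytest.approx(1.0)

    def test_median_invariant_to_trial_order(self, small_dataset):
        trials, _ = small_dataset
        a = fit_nb_counts(trials, EventKind.JOIN, Phase.EXPANSION)
        b = fit_nb_counts(trials[::-1], EventKind.JOIN, Phase.EXPANSION)
        assert a.mu == b.mu and a.theta == b.theta


class TestDelayReassignment:
    def _trial(self):
        # 4 expansion + 4 contraction intervals; most leaves early in contraction
        return make_interval_trial(
            gaps=[0, 1, 2, 3, 3, 2, 1, 0],
            n_starts=[0, 1, 2, 3, 3, 2, 1, 0],
            joins=[1, 1, 1, 1, 0, 0, 0, 0],
            leaves=[0, 0, 0, 0, 2, 1, 1, 0],
            phases=[Phase.EXPANSION.value] * 4 + [Phase.CONTRACTION.value] * 4,
        )

    def test_delay_out_of_range_rejected(self, small_dataset):
        trials, _ = small_dataset
        for bad in (0, 7, -1):
            with pytest.raises(ParameterError, match="between 1 and 6"):
                apply_delay_reassignment(trials, bad)

    def test_reassigned_mass_moves_between_phases(self):
        trial = self._trial()
        exp_model, con_model = apply_delay_reassignment([trial] * 2, 2)
        # the first two contraction intervals' leaves (2 + 1) now count as
        # expansion events: expansion mean 3/6, contraction mean (1 + 0)/2
        assert exp_model.mu == pytest.approx(3 / 6)
        assert con_model.mu == pytest.approx(1 / 2)

    def test_total_leaves_conserved(self):
        trial = self._trial()
        tab = interval_table(trial)
        usable = tab[~tab["broken"]]
        total = usable["leaves"].sum()
        for d in (1, 2):
            exp_model, con_model = apply_delay_reassignment([trial], d)
            n_exp = 4 + d
            n_con = 4 - d
            recovered = exp_model.mu * n_exp + con_model.mu * n_con
            assert recovered == pytest.approx(total)


class TestEquilibriumDensity:
    def _trials(self, rho0=0.5, k=4.0, a=0.0, n=400, seed=0):
        # occurrence probabilities mirror-symmetric around rho0
        rng = np.random.default_rng(seed)
        gaps = rng.uniform(5, 30, n)
        rho = rng.uniform(0.05, 1.0, n)
        n_starts = np.round(rho * gaps).astype(int)
        rho = n_starts / gaps
        p_join = 1 / (1 + np.exp(-(a - k * (rho - rho0))))
        p_leave = 1 / (1 + np.exp(-(a + k * (rho - rho0))))
        joins = (rng.random(n) < p_join).astype(int)
        leaves = (rng.random(n) < p_leave).astype(int)
        return [
            make_interval_trial(
                gaps=gaps, n_starts=n_starts, joins=list(joins), leaves=list(leaves)
            )
        ]

    def test_symmetric_logits_recover_crossing(self):
        trials = self._trials(rho0=0.5)
        eq = estimate_equilibrium_density(trials)
        assert eq.rho_star == pytest.approx(0.5, abs=0.05)

    def test_probabilities_equal_at_root(self):
        eq = estimate_equilibrium_density(self._trials())
        assert abs(eq.p_join(eq.rho_star) - eq.p_leave(eq.rho_star)) < 1e-6

    def test_root_agrees_with_grid_bruteforce(self):
        trials = self._trials(seed=1)
        eq = estimate_equilibrium_density(trials)
        grid = np.arange(0.05, 1.0, 1e-4)
        diff = np.abs(eq.p_join(grid) - eq.p_leave(grid))
        assert abs(grid[diff.argmin()] - eq.rho_star) < 1e-3

    def test_non_intersecting_curves_reported(self):
        # joining always likelier than leaving: no equilibrium in range
        rng = np.random.default_rng(2)
        n = 200
        gaps = rng.uniform(5, 30, n)
        n_starts = np.round(rng.uniform(0.05, 1.0, n) * gaps).astype(int)
        joins = (rng.random(n) < 0.9).astype(int)
        leaves = (rng.random(n) < 0.05).astype(int)
        trials = [
            make_interval_trial(gaps=gaps, n_starts=n_starts, joins=list(joins),
                                leaves=list(leaves))
        ]
        with pytest.raises(NoEquilibriumError) as err:
            estimate_equilibrium_density(trials)
        assert err.value.join_logit is not None


class TestDeficitRegression:
    def _trials(self, alpha, beta, theta, n, seed, rho_star=0.5):
        rng = np.random.default_rng(seed)
        gaps = rng.uniform(10, 30, n)
        n_starts = np.clip(
            np.round(rho_star * gaps + rng.uniform(-8, 15, n)), 0, None
        ).astype(int)
        delta = rho_star * gaps - n_starts
        counts = np.array(
            [nb_draw(np.exp(alpha + beta * d), theta, rng) for d in delta]
        )
        return [
            make_interval_trial(
                gaps=gaps, n_starts=n_starts, joins=list(counts), leaves=[0] * n
            )
        ]

    @pytest.mark.parametrize("n,tol_beta", [(150, 0.025), (600, 0.012)])
    def test_parameter_recovery_bias_shrinks(self, n, tol_beta):
        ests = []
        for seed in range(4):
            trials = self._trials(0.2, 0.05, 1.0, n, seed)
            reg = fit_deficit_regression(trials, 0.5, EventKind.JOIN)
            ests.append([reg.intercept, reg.slope, reg.theta])
        mean = np.mean(ests, axis=0)
        assert mean[1] == pytest.approx(0.05, abs=tol_beta)
        assert mean[0] == pytest.approx(0.2, abs=0.25)
        assert 0.6 < mean[2] < 1.7

    def test_null_slope_when_counts_independent(self):
        trials = self._trials(0.2, 0.0, 1.0, 600, seed=9)
        reg = fit_deficit_regression(trials, 0.5, EventKind.JOIN)
        assert abs(reg.slope) < 0.02

    def test_degenerate_deficit_rejected(self):
        trial = make_interval_trial(
            gaps=np.full(40, 20.0), n_starts=np.full(40, 10, dtype=int),
            joins=[1] * 40, leaves=[0] * 40,
        )
        with pytest.raises(FitError, match="no variation"):
            fit_deficit_regression([trial], 0.5, EventKind.JOIN)
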