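import math

import numpy as np
import pandas as pd
import pytest

from hale.cohort import default_initial_model, default_true_params
from hale.expectancy import (InitialStateModel, fit_initial_state,
                             le_trajectory, marginal_le, simulate_ci,
                             state_specific_le)
from hale.intensities import GompertzIntensityParams
from hale.panel import PanelDataset


def _gompertz_params():
    return default_true_params(("part",))


class TestStateSpecificLE:
    def test_frozen_state_when_nothing_happens(self):
        p = GompertzIntensityParams.from_rates(
            {t: 1e-14 for t in ((1, 2), (1, 3), (2, 1), (2, 3))})
        E = state_specific_le(p, 60.0, {}, omega_max=100.0, step=0.25)
        assert E[0, 0] == pytest.approx(40.0, abs=1e-6)
        assert E[0, 1] == pytest.approx(0.0, abs=1e-6)

    def test_fundamental_matrix_oracle(self, toy_q_params, toy_q_matrix):
        # time-homogeneous limit: occupancy times are -(Q_LL)^{-1}
        E = state_specific_le(toy_q_params, 60.0, {}, omega_max=2000.0,
                              step=0.25)
        expected = -np.linalg.inv(toy_q_matrix[:2, :2])
        np.testing.assert_allclose(E, expected, atol=0.01)
        assert E[0, 0] == pytest.approx(11.54, abs=0.01)
        assert E[0, 1] == pytest.approx(7.69, abs=0.01)
        assert E[1, 0] == pytest.approx(3.85, abs=0.01)
        assert E[1, 1] == pytest.approx(9.23, abs=0.01)

    def test_step_refinement_below_reporting_precision(self):
        p = _gompertz_params()
        E1 = state_specific_le(p, 60.0, {"part": 1}, step=0.25)
        E2 = state_specific_le(p, 60.0, {"part": 1}, step=0.125)
        assert np.abs(E1 - E2).max() < 0.01

    def test_occupancy_bounded_by_horizon(self):
        p = _gompertz_params()
        E = state_specific_le(p, 60.0, {"part": 0}, omega_max=115.0)
        assert np.all(E >= 0)
        assert E.sum(axis=1).max() <= 55.0

    def test_bad_horizon_rejected(self, toy_q_params):
        with pytest.raises(ValueError, match="omega_max"):
            state_specific_le(toy_q_params, 70.0, {}, omega_max=70.0)


class TestInitialStateModel:
    def _baseline_panel(self, states, ages=None, cov=None):
        n = len(states)
        obs = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n)],
            "age": ages if ages is not None else [65.0] * n,
            "state": states,
        })
        covframe = pd.DataFrame(
            cov if cov is not None else {},
            index=pd.Index([f"s{i}" for i in range(n)]))
        return PanelDataset.from_frames(obs, covframe)

    def test_intercept_only_matches_logit_of_prevalence(self):
        states = [2] * 30 + [1] * 70
        ds = self._baseline_panel(states)
        m = fit_initial_state(ds, covariates=(), include_age=False)
        assert m.coef[0] == pytest.approx(math.log(0.3 / 0.7), abs=1e-4)
        pi1, pi2 = m.predict_pi(65.0, {})
        assert pi2 == pytest.approx(0.3, abs=1e-4)
        assert pi1 + pi2 == pytest.approx(1.0)

    def test_uninformative_covariate_has_null_coefficient(self):
        states = [2] * 40 + [1] * 60
        cov = {"part": [i % 2 for i in range(100)]}
        ds = self._baseline_panel(states, cov=cov)
        m = fit_initial_state(ds, covariates=("part",), include_age=False)
        assert abs(m.coef[-1]) < 0.5

    def test_recovers_known_logit_model(self):
        rng = np.random.default_rng(11)
        n = 5000
        age = rng.uniform(60, 90, n)
        part = (rng.random(n) < 0.4).astype(float)
        eta = -1.5 + 0.05 * (age - 60) - 0.6 * part
        y = rng.random(n) < 1 / (1 + np.exp(-eta))
        ds = self._baseline_panel((y + 1).astype(int).tolist(),
                                  ages=age.tolist(), cov={"part": part})
        m = fit_initial_state(ds, covariates=("part",))
        se = np.sqrt(np.diag(m.cov))
        for est, s, truth in zip(m.coef, se, (-1.5, 0.05, -0.6)):
            assert abs(est - truth) < 3 * s

    def test_complete_separation_reported(self):
        states = [2] * 20 + [1] * 20
        cov = {"part": [1.0] * 20 + [0.0] * 20}
        ds = self._baseline_panel(states, cov=cov)
        with pytest.raises(ValueError, match="separat"):
            fit_initial_state(ds, covariates=("part",), include_age=False)

    def test_dead_baseline_rejected(self):
        ds = self._baseline_panel([1, 3], ages=[60.0, 61.0])
        with pytest.raises(ValueError, match="living"):
            fit_initial_state(ds, covariates=(), include_age=False)


class TestMarginalLE:
    def test_degenerate_weights_reduce_to_state_specific(self):
        p = _gompertz_params()
        # strongly negative intercept: everyone healthy at baseline
        init = InitialStateModel([-25.0], None, (), include_age=False)
        est = marginal_le(p, init, 60.0, {"part": 0})
        E = state_specific_le(p, 60.0, {"part": 0})
        assert est.hle == pytest.approx(E[0, 0], abs=1e-6)
        assert est.ule == pytest.approx(E[0, 1], abs=1e-6)

    def test_even_weights_average_the_rows(self, toy_q_params):
        init = InitialStateModel([0.0], None, (), include_age=False)
        est = marginal_le(toy_q_params, init, 60.0, {}, omega_max=2000.0)
        E = state_specific_le(toy_q_params, 60.0, {}, omega_max=2000.0)
        assert est.hle == pytest.approx(0.5 * (E[0, 0] + E[1, 0]), abs=1e-9)
        assert est.ule == pytest.approx(0.5 * (E[0, 1] + E[1, 1]), abs=1e-9)

    def test_identity_tle_hle_ule(self):
        p = _gompertz_params()
        init = default_initial_model(("part",))
        for age in (60.0, 75.0, 90.0):
            est = marginal_le(p, init, age, {"part": 1})
            assert est.tle == pytest.approx(est.hle + est.ule, abs=1e-8)
            assert est.pct_healthy == pytest.approx(100 * est.hle / est.tle)

    def test_raising_mortality_never_raises_tle(self):
        init = default_initial_model(("part",))
        base = _gompertz_params()
        est0 = marginal_le(base, init, 60.0, {"part": 0})
        bumped = base.copy_with(beta0=base.beta0 + np.array([0, 0.5, 0, 0.5]))
        est1 = marginal_le(bumped, init, 60.0, {"part": 0})
        assert est1.tle <= est0.tle


@pytest.fixture(scope="module")
def fitted():
    from hale.cohort import SimulationConfig, generate_cohort
    from hale.likelihood import fit_mle

    cfg = SimulationConfig(n_subjects=500, seed=31,
                           covariate_prevalences={"part": 0.32})
    ds, _ = generate_cohort(cfg)
    fit = fit_mle(ds, covariates=("part",), h=1.0)
    init = fit_initial_state(ds, ("part",))
    return fit, init


class TestSimulateCI:
    def test_fixed_seed_reproducible(self, fitted):
        fit, init = fitted
        a = simulate_ci(fit, init, 60.0, {"part": 1}, n_sims=50, seed=7)
        b = simulate_ci(fit, init, 60.0, {"part": 1}, n_sims=50, seed=7)
        assert a.ci == b.ci

    def test_zero_covariance_collapses_to_point(self, fitted):
        fit, init = fitted
        import dataclasses

        degenerate = dataclasses.replace(
            fit, covariance=np.zeros_like(fit.covariance))
        init0 = InitialStateModel(init.coef, np.zeros_like(init.cov),
                                  init.covariates, init.include_age,
                                  init.reference_age)
        est = simulate_ci(degenerate, init0, 60.0, {"part": 1}, n_sims=25,
                          seed=1)
        for q in ("tle", "hle", "ule"):
            lo, hi = est.ci[q]
            assert lo == pytest.approx(getattr(est, q), abs=1e-10)
            assert hi == pytest.approx(getattr(est, q), abs=1e-10)

    def test_interval_brackets_point(self, fitted):
        fit, init = fitted
        est = simulate_ci(fit, init, 60.0, {"part": 0}, n_sims=100, seed=3)
        for q in ("tle", "hle", "ule"):
            lo, hi = est.ci[q]
            assert lo <= getattr(est, q) <= hi

    def test_missing_covariance_is_instructive(self, fitted):
        fit, init = fitted
        import dataclasses

        nocov = dataclasses.replace(fit, covariance=None)
        with pytest.raises(ValueError, match="point"):
            simulate_ci(nocov, init, 60.0, {"part": 0})


class TestTrajectory:
    def test_singleton_matches_marginal(self):
        p = _gompertz_params()
        init = default_initial_model(("part",))
        traj = le_trajectory(p, init, [65.0], {"part": 1})
        est = marginal_le(p, init, 65.0, {"part": 1})
        assert traj[0].tle == pytest.approx(est.tle)

    def test_mortality_only_closed_form_and_decreasing(self):
        mu = 0.05
        omega = 115.0
        p = GompertzIntensityParams.from_rates(
            {(1, 2): 1e-14, (1, 3): mu, (2, 1): 1e-14, (2, 3): mu})
        init = InitialStateModel([-25.0], None, (), include_age=False)
        ests = le_trajectory(p, init, [60.0, 70.0, 80.0], {}, omega_max=omega,
                             step=0.05)
        for est in ests:
            closed = (1 - math.exp(-mu * (omega - est.age))) / mu
            assert est.tle == pytest.approx(closed, abs=0.01)
        assert ests[0].tle > ests[1].tle > ests[2].tle

    def test_gompertz_tle_monotone_decreasing(self):
        p = _gompertz_params()
        init = default_initial_model(("part",))
        ests = le_trajectory(p, init, list(range(60, 91)), {"part": 0})
        tles = [e.tle for e in ests]
        assert all(a > b for a, b in zip(tles[:-1], tles[1:]))

    def test_non_increasing_ages_rejected(self):
        p = _gompertz_params()
        init = default_initial_model(("part",))
        with pytest.raises(ValueError, match="increasing"):
            le_trajectory(p, init, [70.0, 70.0], {"part": 0})
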