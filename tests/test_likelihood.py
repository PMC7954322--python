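import math

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import expm

from hale.intensities import GompertzIntensityParams
from hale.likelihood import (crude_init, fit_mle, subject_loglik, total_loglik)
from hale.panel import PanelDataset


def _dataset(rows, cov=None):
    obs = pd.DataFrame(rows, columns=["subject_id", "age", "state"])
    subjects = obs["subject_id"].unique()
    if cov is None:
        cov = pd.DataFrame(index=pd.Index(subjects))
    return PanelDataset.from_frames(obs, cov)


class TestSubjectLoglik:
    def test_single_observation_contributes_zero(self, toy_q_params):
        with pytest.warns(UserWarning, match="single-observation"):
            assert subject_loglik([(60.0, 1)], toy_q_params, {}) == 0.0

    def test_living_pair_equals_matrix_exponential(self, toy_q_params,
                                                   toy_q_matrix):
        ll = subject_loglik([(60.0, 1), (62.0, 1)], toy_q_params, {}, h=2.0)
        expected = math.log(expm(2.0 * toy_q_matrix)[0, 0])
        assert ll == pytest.approx(expected, abs=1e-12)

    def test_exact_death_competing_risk_closed_form(self):
        # mortality-only: density of death at 62 from state 1 at 60 is
        # exp(-2 mu) * mu
        mu = 0.05
        p = GompertzIntensityParams.from_rates(
            {(1, 2): 1e-12, (1, 3): mu, (2, 1): 1e-12, (2, 3): mu})
        ll = subject_loglik([(60.0, 1), (62.0, 3)], p, {}, h=1.0)
        assert ll == pytest.approx(math.log(math.exp(-2 * mu) * mu), abs=1e-6)


class TestTotalLoglik:
    def test_single_subject_dataset(self, toy_q_params):
        ds = _dataset([("a", 60.0, 1), ("a", 62.0, 2)])
        assert total_loglik(ds, toy_q_params, h=1.0) == pytest.approx(
            subject_loglik([(60.0, 1), (62.0, 2)], toy_q_params, {}, h=1.0))

    def test_duplicated_dataset_doubles(self, toy_q_params):
        rows = [("a", 60.0, 1), ("a", 62.0, 2), ("b", 65.0, 2), ("b", 67.0, 3)]
        ds1 = _dataset(rows)
        ds2 = _dataset(rows + [(f"{s}2", a, st) for s, a, st in rows])
        assert total_loglik(ds2, toy_q_params) == pytest.approx(
            2 * total_loglik(ds1, toy_q_params), rel=1e-12)

    def test_matches_per_subject_summation(self, sim_panel):
        ds, _, cfg = sim_panel
        params = cfg.true_params
        naive = 0.0
        for sid, g in ds.obs.groupby("subject_id"):
            if len(g) < 2:
                continue
            z = ds.covariates.loc[sid].to_dict()
            naive += subject_loglik(
                list(zip(g["age"], g["state"])), params, z, h=1.0)
        assert total_loglik(ds, params, h=1.0) == pytest.approx(naive, abs=1e-8)


class TestCrudeInit:
    def test_rate_definition(self):
        ds = _dataset([("a", 60.0, 1), ("a", 70.0, 2)])
        init = crude_init(ds)
        assert init.beta0[0] == pytest.approx(math.log(0.1))

    def test_unobserved_transition_floored(self, caplog):
        import logging

        ds = _dataset([("a", 60.0, 1), ("a", 70.0, 2), ("b", 60.0, 2),
                       ("b", 64.0, 2)])
        with caplog.at_level(logging.INFO, logger="hale.likelihood"):
            init = crude_init(ds)
        # no 2->1 and no deaths observed: floored at 0.5 events / exposure
        assert init.beta0[2] == pytest.approx(math.log(0.5 / 4.0))
        assert any("flooring" in r.message for r in caplog.records)

    def test_zero_person_years_rejected(self):
        # single-observation subjects only: no pairs, no exposure
        ds = _dataset([("a", 60.0, 1), ("b", 70.0, 2)])
        with pytest.raises(ValueError, match="person-years"):
            crude_init(ds)

    def test_within_factor_two_of_truth_on_simulation(self, sim_panel):
        ds, _, cfg = sim_panel
        init = crude_init(ds)
        # crude occupancy rates land near the all-ages average intensity:
        # within a factor ~2 of the age-60 baselines for onset/recovery
        for i in (0, 2):
            assert abs(init.beta0[i] - cfg.true_params.beta0[i]) < math.log(2.5)


@pytest.fixture(scope="module")
def fit_and_data():
    from hale.cohort import SimulationConfig, generate_cohort

    cfg = SimulationConfig(n_subjects=500, seed=99,
                           covariate_prevalences={"part": 0.32})
    ds, _ = generate_cohort(cfg)
    return ds, cfg, fit_mle(ds, covariates=("part",), h=1.0)


class TestFitMLE:
    def test_improves_on_crude_start(self, fit_and_data):
        ds, cfg, fit = fit_and_data
        start = crude_init(ds, ("part",))
        assert fit.loglik >= total_loglik(ds, start, h=1.0)

    def test_refit_from_optimum_is_fixed_point(self, fit_and_data):
        ds, cfg, fit = fit_and_data
        refit = fit_mle(ds, covariates=("part",), h=1.0, init=fit.params,
                        compute_covariance=False)
        assert refit.loglik == pytest.approx(fit.loglik, abs=1e-4)

    def test_score_near_zero_at_optimum(self, fit_and_data):
        ds, cfg, fit = fit_and_data
        x = fit.param_vector()
        grads = []
        for i in range(len(x)):
            e = np.zeros_like(x)
            e[i] = 1e-5
            from hale.likelihood import _PreparedPanel, _unflatten

            prep = _PreparedPanel(ds, ("part",), 1.0, 60.0)
            mask = fit._mask()
            up = prep.loglik(_unflatten(x + e, fit.params, mask))
            dn = prep.loglik(_unflatten(x - e, fit.params, mask))
            grads.append((up - dn) / 2e-5)
        # relative score: gradient scaled by the loglik magnitude
        assert np.linalg.norm(grads) / abs(fit.loglik) < 1e-4

    def test_age_shift_invariance(self, fit_and_data):
        ds, cfg, fit = fit_and_data
        shifted_obs = ds.obs.copy()
        shifted_obs["age"] += 7.0
        shifted = PanelDataset.from_frames(shifted_obs, ds.covariates,
                                           min_age=None)
        ll = total_loglik(ds, fit.params, h=1.0)
        ll_shift = total_loglik(
            shifted, fit.params.copy_with(
                reference_age=fit.params.reference_age + 7.0), h=1.0)
        assert ll_shift == pytest.approx(ll, abs=1e-8)

    def test_covariance_symmetric_psd(self, fit_and_data):
        _, _, fit = fit_and_data
        cov = fit.covariance
        np.testing.assert_allclose(cov, cov.T, atol=1e-12)
        assert np.linalg.eigvalsh(cov).min() > -1e-8

    def test_no_deaths_boundary(self):
        from hale.cohort import SimulationConfig, generate_cohort

        cfg = SimulationConfig(n_subjects=150, seed=5,
                               covariate_prevalences={"part": 0.3})
        ds, _ = generate_cohort(cfg)
        alive = ds.obs[ds.obs["state"] != 3]
        keep = alive.groupby("subject_id").size()
        keep = keep[keep >= 2].index
        alive = alive[alive["subject_id"].isin(keep)]
        ds2 = PanelDataset.from_frames(alive, ds.covariates.loc[keep],
                                       min_age=None)
        fit = fit_mle(ds2, h=1.0, compute_covariance=False, max_iter=300)
        # death intensities pushed toward the small-rate boundary
        assert fit.params.beta0[1] < math.log(0.01)
        assert isinstance(fit.converged, bool)

    def test_zero_probability_pair_is_reported(self):
        # absurd mortality: surviving two years has probability that
        # underflows to exactly zero, which must be reported, not -inf
        p = GompertzIntensityParams.from_rates(
            {(1, 2): 1e-12, (1, 3): 1e26, (2, 1): 1e-12, (2, 3): 1e26})
        with pytest.raises(ValueError, match="zero-probability"):
            subject_loglik([(60.0, 1), (62.0, 1)], p, {})
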