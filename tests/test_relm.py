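"""Mixed-model fitting and empirical-Bayes (BLUP) prediction."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from benefitqq import (
    RELMFit,
    RELMSpec,
    ScenarioConfig,
    conditional_residuals,
    fit_relm,
    predict_random_effects,
    simulate_dataset,
)
from benefitqq.relm import _design

from conftest import toy_dataset


def brute_force_loglik(fit, data):
    """Independent oracle: per-patient multivariate-normal density with
    V_omega = Z Sigma Z' + sigma2 I assembled explicitly."""
    X, Z, y, _ = _design(data, fit.spec)
    pid = data.table["patient_id"].to_numpy()
    ll = 0.0
    for p in data.patient_ids:
        m = pid == p
        V = Z[m] @ fit.Sigma_hat @ Z[m].T + fit.sigma2_eps_hat * np.eye(m.sum())
        ll += multivariate_normal.logpdf(y[m], mean=X[m] @ fit.psi_hat, cov=V)
    return ll


def _manual_fit(psi, Sigma, sigma2, spec, covcols=("x",), n_patients=2):
    names = ("intercept",) + tuple(covcols) + tuple(
        f"t^{i}" if i > 1 else "t" for i in range(1, spec.poly_degree_fixed + 1)
    )
    return RELMFit(
        psi_hat=np.asarray(psi, float),
        psi_names=names,
        Sigma_hat=np.asarray(Sigma, float),
        sigma2_eps_hat=float(sigma2),
        loglik=0.0,
        converged=True,
        spec=spec,
        covariate_columns=tuple(covcols),
        n_patients=n_patients,
    )


class TestFit:
    def test_ml_loglik_matches_density_oracle_on_toy(self):
        rng = np.random.default_rng(3)
        times = [[0, 0, 1, 4]] * 3
        ys = [(20 + rng.normal(0, 3, 4)).tolist() for _ in range(3)]
        data = toy_dataset(times, ys)
        spec = RELMSpec(poly_degree_fixed=2, random_terms=(0, 1), estimation="ml")
        fit = fit_relm(data, spec)
        assert fit.loglik == pytest.approx(brute_force_loglik(fit, data), abs=1e-6)

    def test_ml_objective_beats_generating_parameters(self, model1_data):
        spec = RELMSpec(estimation="ml")
        fit = fit_relm(model1_data, spec)
        truth = _manual_fit(
            [21, 2, -5, 0.5], [[1, 0.9], [0.9, 2.0]], 10.0, spec, n_patients=80
        )
        assert brute_force_loglik(fit, model1_data) >= brute_force_loglik(
            truth, model1_data
        )

    def test_noise_free_limit_recovers_fixed_effects(self):
        # sigma2_eps ~ 1e-6 and no random effects: deterministic regression limit
        rng = np.random.default_rng(9)
        psi = np.array([21.0, 2.0, -5.0, 0.5])
        times = np.array([0.0, 0.0, 1.0, 2.0, 3.0, 4.0])
        data = toy_dataset(
            [times] * 6,
            [
                psi[0] + psi[1] * x + psi[2] * times + psi[3] * times**2
                + rng.normal(0, 1e-5, 6)
                for x in (1, 0, 1, 1, 0, 0)
            ],
            covs_by_patient=[1, 0, 1, 1, 0, 0],
        )
        fit = fit_relm(data, RELMSpec())
        assert np.allclose(fit.psi_hat, psi, atol=1e-4)

    def test_reml_default_and_flags(self, model1_fit):
        assert model1_fit.spec.estimation == "reml"
        assert model1_fit.converged
        assert model1_fit.sigma2_eps_hat > 0
        evals = np.linalg.eigvalsh(model1_fit.Sigma_hat)
        assert evals.min() >= -1e-8

    def test_rank_deficient_design_names_columns(self):
        times = [[0, 0, 1, 4]] * 4
        ys = [[20, 21, 15, 9]] * 4
        data = toy_dataset(times, ys, covs_by_patient=[1, 1, 1, 1])
        # constant covariate duplicates the intercept column
        with pytest.raises(ValueError, match="collinear"):
            fit_relm(data, RELMSpec())

    def test_too_few_patients_rejected(self):
        data = toy_dataset([[0, 0, 1, 4]], [[20, 21, 15, 9]])
        with pytest.raises(ValueError, match="2 patients"):
            fit_relm(data, RELMSpec())

    def test_spec_validation(self):
        with pytest.raises(ValueError, match="intercept"):
            RELMSpec(random_terms=(1,))
        with pytest.raises(ValueError, match="subset"):
            RELMSpec(poly_degree_fixed=1, random_terms=(0, 2))
        with pytest.raises(ValueError, match="estimation"):
            RELMSpec(estimation="map")


class TestBLUP:
    def test_matches_hand_matrix_algebra(self):
        # 2 patients, q = 2; oracle written out with explicit inverses
        spec = RELMSpec(poly_degree_fixed=2, random_terms=(0, 1))
        psi = np.array([20.0, 3.0, -4.0, 0.3])
        Sigma = np.array([[2.0, 0.5], [0.5, 1.5]])
        s2 = 4.0
        fit = _manual_fit(psi, Sigma, s2, spec)
        times = [np.array([0.0, 0.0, 1.0, 4.0]), np.array([0.0, 0.0, 2.0, 4.0])]
        ys = [np.array([24.0, 26.0, 18.0, 10.0]), np.array([19.0, 21.0, 14.0, 12.0])]
        xs = [1, 0]
        data = toy_dataset(times, ys, covs_by_patient=xs)
        eb = predict_random_effects(fit, data)
        for i, (t, y, x) in enumerate(zip(times, ys, xs)):
            X = np.column_stack([np.ones(4), np.full(4, x), t, t**2])
            Z = np.column_stack([np.ones(4), t])
            V = Z @ Sigma @ Z.T + s2 * np.eye(4)
            tau = Sigma @ Z.T @ np.linalg.inv(V) @ (y - X @ psi)
            assert np.allclose(eb.tau_hat[i], tau, atol=1e-10)
            assert eb.lambda_hat[i] == pytest.approx(psi[0] + tau[0] + psi[1] * x)

    def test_zero_covariance_shrinks_to_zero(self, model1_data):
        fit0 = _manual_fit(
            [21, 2, -5, 0.5], np.zeros((2, 2)), 10.0, RELMSpec(), n_patients=80
        )
        eb = predict_random_effects(fit0, model1_data)
        assert np.allclose(eb.tau_hat, 0.0)

    def test_agrees_with_statsmodels_posterior_means(self, model1_fit, model1_data):
        # independent route: statsmodels' own EB random-effect predictions
        import warnings

        from statsmodels.regression.mixed_linear_model import MixedLM

        X, Z, y, _ = _design(model1_data, model1_fit.spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = MixedLM(
                y, X, groups=model1_data.table["patient_id"].to_numpy(), exog_re=Z
            ).fit(reml=True, method="lbfgs", maxiter=500)
        ours = predict_random_effects(model1_fit, model1_data)
        theirs = res.random_effects
        for i, pid in enumerate(model1_data.patient_ids):
            assert np.allclose(ours.tau_hat[i], theirs[pid].to_numpy(), atol=1e-4)

    def test_shrinkage_and_predictive_correlation(self):
        cfg = ScenarioConfig(scenario=1, param=1.0, N=300, n=6, seed=77)
        data = simulate_dataset(cfg, np.random.default_rng(123), arm="reference")
        fit = fit_relm(data, cfg.relm_spec)
        eb = predict_random_effects(fit, data)
        # shrinkage: predictions no wilder than the data-generating spread
        assert np.mean(np.abs(eb.tau_hat[:, 1])) <= np.sqrt(2.0) * 2
        # association with the patient-level slopes implied by the data
        slopes = (
            data.table[data.table.time > 0]
            .groupby("patient_id", sort=False)
            .apply(
                lambda d: np.polyfit(d["time"], d["response"], 1)[0],
                include_groups=False,
            )
            .loc[data.patient_ids]
            .to_numpy()
        )
        r = np.corrcoef(eb.tau_hat[:, 1], slopes)[0, 1]
        assert r > 0.5

    def test_blup_centering_invariant(self, model1_eb):
        # weighted mean of tau-hat across patients is near zero
        scale = np.sqrt(np.diag(model1_eb.fit.Sigma_hat)) + 1e-12
        centered = np.abs(model1_eb.tau_hat.mean(axis=0)) / scale
        assert np.all(centered < 0.5)

    def test_mismatched_covariates_rejected(self, model1_fit):
        data = toy_dataset([[0, 0, 1, 4]] * 2, [[20, 21, 15, 9]] * 2)
        with pytest.raises(ValueError, match="covariates"):
            predict_random_effects(model1_fit, data)


class TestResiduals:
    def test_noise_free_residuals_vanish(self):
        psi = np.array([21.0, 2.0, -5.0, 0.5])
        times = np.array([0.0, 0.0, 1.0, 4.0])
        data = toy_dataset(
            [times] * 3,
            [psi[0] + psi[1] * x + psi[2] * times + psi[3] * times**2 for x in (1, 0, 1)],
            covs_by_patient=[1, 0, 1],
        )
        fit = _manual_fit(psi, np.zeros((2, 2)), 1e-6, RELMSpec(), n_patients=3)
        eb = predict_random_effects(fit, data)
        res = conditional_residuals(fit, eb, data)
        assert np.allclose(res["residual"], 0.0, atol=1e-8)

    def test_residual_variance_tracks_error_variance(self, model1_fit, model1_data, model1_eb):
        res = conditional_residuals(model1_fit, model1_eb, model1_data)
        ratio = res["residual"].var() / model1_fit.sigma2_eps_hat
        assert 0.8 < ratio < 1.1  # EB fitting absorbs a little noise

    def test_per_patient_locality(self, model1_fit, model1_data, model1_eb):
        res_all = conditional_residuals(model1_fit, model1_eb, model1_data)
        drop = model1_data.patient_ids[0]
        keep_tab = model1_data.table[model1_data.table.patient_id != drop]
        sub = type(model1_data)(keep_tab, model1_data.covariate_columns)
        eb_sub = predict_random_effects(model1_fit, sub)
        res_sub = conditional_residuals(model1_fit, eb_sub, sub)
        merged = res_all[res_all.patient_id != drop].reset_index(drop=True)
        assert np.allclose(merged["residual"], res_sub["residual"], atol=1e-10)
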