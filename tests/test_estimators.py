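import numpy as np
import pytest
from scipy.stats import norm

from hlik.core import ELIM_U, ParameterState, adjusted_profile_loglik, h_gradient
from hlik.model import (
    GLMM,
    fit_hl01,
    fit_hl11,
    fit_ml_laplace,
    refit_random_effects,
    standard_errors,
)
from hlik.quadrature import agh_fit, agh_marginal_loglik, gaussian_lmm_closed_form

from conftest import glmm_data_from_arrays, random_poisson_instance


def simulated_gaussian_lmm(seed=0, n_groups=25, obs_per_group=6):
    rng = np.random.default_rng(seed)
    n = n_groups * obs_per_group
    idx = np.repeat(np.arange(n_groups), obs_per_group)
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    u = rng.normal(scale=0.8, size=n_groups)
    y = X @ np.array([1.0, -0.5]) + u[idx] + rng.normal(scale=1.2, size=n)
    return glmm_data_from_arrays(y, X, {"g": idx}, family="gaussian")


class TestGaussianClosedFormEquivalence:
    def test_balanced_oneway_reml_values(self, balanced_oneway_gaussian):
        res = fit_hl11(balanced_oneway_gaussian)
        assert res.params[0] == pytest.approx(2.5, abs=1e-6)
        assert res.vc_sd[0] ** 2 == pytest.approx(1.75, rel=1e-5)
        assert res.phi == pytest.approx(0.5, rel=1e-5)

    def test_hl11_matches_reml_oracle_on_simulated_lmm(self):
        data = simulated_gaussian_lmm(seed=3)
        res = fit_hl11(data)
        beta_o, sig_o, phi_o, _ = gaussian_lmm_closed_form(data, "REML")
        np.testing.assert_allclose(res.params, beta_o, rtol=1e-6)
        np.testing.assert_allclose(res.vc_sd, sig_o, rtol=1e-6)
        assert res.phi == pytest.approx(phi_o, rel=1e-6)

    def test_ml_matches_ml_oracle_and_sits_below_reml(self):
        data = simulated_gaussian_lmm(seed=4)
        res = fit_ml_laplace(data)
        beta_o, sig_o, phi_o, _ = gaussian_lmm_closed_form(data, "ML")
        np.testing.assert_allclose(res.params, beta_o, rtol=1e-5)
        np.testing.assert_allclose(res.vc_sd, sig_o, rtol=1e-4)
        reml = fit_hl11(data, options={"compute_se": False})
        assert res.vc_sd[0] <= reml.vc_sd[0] + 1e-8

    def test_balanced_oneway_ml_below_reml(self, balanced_oneway_gaussian):
        ml = fit_ml_laplace(balanced_oneway_gaussian, options={"compute_se": False})
        reml = fit_hl11(balanced_oneway_gaussian, options={"compute_se": False})
        assert ml.vc_sd[0] ** 2 <= reml.vc_sd[0] ** 2 + 1e-8


class TestStageConsistency:
    def test_variance_components_identical_hl11_hl01(self):
        rng = np.random.default_rng(31)
        data, *_ = random_poisson_instance(rng, n_groups=20, obs_per_group=5)
        r11 = fit_hl11(data, options={"compute_se": False})
        r01 = fit_hl01(data, options={"compute_se": False})
        # shared stage 1: identical optimizer trace, bit-for-bit estimates
        np.testing.assert_array_equal(r11.vc_sd, r01.vc_sd)
        assert r11.stage1_objective == r01.stage1_objective

    def test_gaussian_joint_mode_equals_two_stage_beta(self):
        data = simulated_gaussian_lmm(seed=9)
        r11 = fit_hl11(data, options={"compute_se": False})
        r01 = fit_hl01(data, options={"compute_se": False})
        np.testing.assert_allclose(r01.params, r11.params, atol=1e-6)
        np.testing.assert_allclose(r01.random_effects, r11.random_effects, atol=1e-6)

    def test_deterministic_refit(self):
        rng = np.random.default_rng(77)
        data, *_ = random_poisson_instance(rng, n_groups=15, obs_per_group=4)
        a = fit_hl11(data, options={"compute_se": False})
        b = fit_hl11(data, options={"compute_se": False})
        np.testing.assert_array_equal(a.params, b.params)
        np.testing.assert_array_equal(a.vc_sd, b.vc_sd)


class TestQuadratureConsistency:
    def test_ml_objective_equals_agh1_at_optimum(self):
        rng = np.random.default_rng(15)
        data, *_ = random_poisson_instance(rng, n_groups=10, obs_per_group=3)
        res = fit_ml_laplace(data, options={"compute_se": False})
        agh1 = agh_marginal_loglik(data, "poisson", (res.params, res.vc_sd, 1.0), m=1)
        assert res.stage2_objective == pytest.approx(agh1, abs=1e-8)

    def test_hl11_close_to_agh25_in_se_units(self):
        rng = np.random.default_rng(55)
        data, *_ = random_poisson_instance(rng, n_groups=50, obs_per_group=5, p=2, sigma=0.6)
        res = fit_hl11(data)
        beta_agh, sigma_agh, _, ok = agh_fit(data, "poisson", m=25, start_beta=res.params,
                                             start_sigma=res.vc_sd[0])
        assert ok
        rel = np.abs(res.params - beta_agh) / res.bse
        assert np.max(rel) <= 0.05

    def test_ml_and_reml_sigma_both_well_defined_on_sparse_binary(self):
        # On sparse binary data the ML-Laplace and REML variance estimates
        # diverge noticeably (unlike the gaussian case, the ordering is not
        # guaranteed draw by draw); both must stay finite and positive.
        rng = np.random.default_rng(23)
        n_groups, obs = 60, 3
        idx = np.repeat(np.arange(n_groups), obs)
        u = rng.normal(scale=1.0, size=n_groups)
        eta = -2.0 + u[idx]
        y = rng.binomial(1, 1 / (1 + np.exp(-eta))).astype(float)
        data = glmm_data_from_arrays(y, np.ones((n_groups * obs, 1)), {"g": idx},
                                     family="bernoulli")
        ml = fit_ml_laplace(data, options={"compute_se": False})
        reml = fit_hl11(data, options={"compute_se": False})
        for res in (ml, reml):
            assert np.isfinite(res.vc_sd[0]) and res.vc_sd[0] > 0
        assert abs(ml.vc_sd[0] - reml.vc_sd[0]) > 1e-4


class TestRandomEffectRefit:
    def test_gaussian_third_stage_equals_stage2(self):
        data = simulated_gaussian_lmm(seed=13)
        res = fit_hl11(data, options={"compute_se": False})
        u3 = refit_random_effects(data, "gaussian", res)
        np.testing.assert_allclose(u3, res.random_effects, atol=1e-7)

    def test_poisson_third_stage_close_and_stationary(self):
        rng = np.random.default_rng(41)
        data, *_ = random_poisson_instance(rng, n_groups=25, obs_per_group=5)
        res = fit_hl11(data, options={"compute_se": False})
        u3 = refit_random_effects(data, "poisson", res)
        # stationarity of h at the refit
        theta = ParameterState(res.params, u3, res.vc_sd, res.phi)
        grad = h_gradient(data, "poisson", theta, ELIM_U)
        assert np.max(np.abs(grad)) <= 1e-8
        # modes are close relative to the spread of the predictions
        gap = np.max(np.abs(u3 - res.random_effects))
        assert gap < 0.2 * np.std(res.random_effects)


class TestStandardErrors:
    def test_gaussian_curvature_closed_form(self):
        objective = lambda b: float(norm.logpdf(b[0], scale=2.0))
        se, cov = standard_errors(objective, np.array([0.0]))
        assert se[0] == pytest.approx(2.0, rel=1e-5)

    def test_delta_method_identity(self):
        # SE on SD scale = sigma * SE(log sigma) at the optimum
        objective = lambda x: float(norm.logpdf(x[0], loc=np.log(1.5), scale=0.3))
        se_nat, _ = standard_errors(objective, np.array([np.log(1.5)]))
        se_sd, _ = standard_errors(objective, np.array([np.log(1.5)]), scale="log")
        assert se_sd[0] == pytest.approx(1.5 * se_nat[0], rel=1e-8)

    def test_beta_se_matches_gls_closed_form(self):
        data = simulated_gaussian_lmm(seed=19, n_groups=12, obs_per_group=5)
        sigma, phi = 0.8, 1.44
        model = GLMM(data)
        obj = model._stage2_objective(np.array([sigma]), phi)
        from scipy.optimize import minimize

        res = minimize(obj.negative, np.zeros(2), jac=obj.negative_grad, method="BFGS")
        se, _ = standard_errors(obj, res.x)
        Z = data.Z.toarray()
        V = phi * np.eye(data.n_obs) + sigma**2 * Z @ Z.T
        cov = np.linalg.inv(data.X.T @ np.linalg.solve(V, data.X))
        np.testing.assert_allclose(se, np.sqrt(np.diag(cov)), rtol=1e-5)

    def test_reported_ses_positive_when_converged(self):
        rng = np.random.default_rng(61)
        data, *_ = random_poisson_instance(rng, n_groups=20, obs_per_group=5)
        res = fit_hl11(data)
        assert res.converged
        assert np.all(res.bse > 0) and np.all(np.isfinite(res.bse))
        assert np.all(res.vc_sd_se > 0)


class TestOffsetContract:
    def test_scaling_exposure_shifts_only_intercept(self):
        rng = np.random.default_rng(71)
        data, *_ = random_poisson_instance(rng, n_groups=30, obs_per_group=5)
        c = 3.7
        data_scaled = glmm_data_from_arrays(
            data.y, data.X,
            {"g": np.repeat(np.arange(30), 5)},
            offset=data.offset + np.log(c),
            family="poisson",
        )
        r0 = fit_hl11(data, options={"compute_se": False})
        r1 = fit_hl11(data_scaled, options={"compute_se": False})
        assert r1.params[0] == pytest.approx(r0.params[0] - np.log(c), abs=1e-5)
        np.testing.assert_allclose(r1.params[1:], r0.params[1:], atol=1e-5)
        np.testing.assert_allclose(r1.vc_sd, r0.vc_sd, atol=1e-5)


class TestResultsObject:
    def test_summary_and_serialization(self, balanced_oneway_gaussian, tmp_path):
        res = fit_hl11(balanced_oneway_gaussian)
        text = res.summary()
        assert "HL11" in text and "random effect" in text
        payload = res.to_dict()
        assert payload["method"] == "HL11"
        assert len(payload["coefficients"]) == 1
        assert len(payload["variance_components"]) == 1
        res.save_json(tmp_path / "fit.json")
        res.save_random_effects(tmp_path / "re.csv")
        lines = (tmp_path / "re.csv").read_text().strip().splitlines()
        assert lines[0] == "factor,level,estimate"
        assert len(lines) == 1 + balanced_oneway_gaussian.n_random

    def test_unknown_method_rejected(self, balanced_oneway_gaussian):
        with pytest.raises(ValueError, match="unknown method"):
            GLMM(balanced_oneway_gaussian).fit("reml")
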