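import numpy as np
import pytest
from scipy import sparse
from scipy.integrate import quad
from scipy.stats import norm
from scipy.stats import poisson as poisson_dist

from hlik.core import (
    ELIM_BETA_U,
    ELIM_U,
    ParameterState,
    adjusted_profile_loglik,
    h_gradient,
    h_hessian_sparse,
    h_loglik,
    inner_mode,
    linear_predictor,
    logdet_spd,
)
from hlik.families import bernoulli, gaussian, get_family, poisson

from conftest import glmm_data_from_arrays, random_poisson_instance


def unit_state(p=1, q=1, sigma=1.0, phi=1.0, beta=None, u=None):
    return ParameterState(
        beta=np.zeros(p) if beta is None else beta,
        u=np.zeros(q) if u is None else u,
        sigmas=[sigma],
        phi=phi,
    )


class TestFamilies:
    @pytest.mark.parametrize("family", [poisson, bernoulli, gaussian])
    def test_link_inverse_round_trip(self, family):
        mu = np.array([0.1, 0.5, 0.9]) if family.name == "bernoulli" else np.array([0.2, 1.0, 7.3])
        np.testing.assert_allclose(family.inverse_link(family.link(mu)), mu, atol=1e-12)

    @pytest.mark.parametrize("family", [poisson, bernoulli])
    def test_dispersion_known_families(self, family):
        assert family.dispersion_known

    @pytest.mark.parametrize("family", [poisson, bernoulli, gaussian])
    def test_score_and_weight_match_numerical_derivatives(self, family):
        y = np.array([1.0]) if family.name != "gaussian" else np.array([0.7])
        eta, h = np.array([0.3]), 1e-6
        f = lambda e: family.log_density(y, np.array([e]), 1.0)[0]
        d1 = (f(0.3 + h) - f(0.3 - h)) / (2 * h)
        d2 = (f(0.3 + h) - 2 * f(0.3) + f(0.3 - h)) / h**2
        assert family.score_eta(y, eta)[0] == pytest.approx(d1, abs=1e-6)
        assert family.weight(eta)[0] == pytest.approx(-d2, rel=1e-3)


class TestHLoglik:
    def test_linear_predictor_arithmetic(self):
        data = glmm_data_from_arrays(
            [1.0], [[1.0]], {"g": [0]}, offset=[np.log(10.0)], family="poisson"
        )
        eta = linear_predictor(data, unit_state(beta=[2.0], u=[-1.0]))
        assert eta[0] == pytest.approx(1.0 + np.log(10.0), abs=1e-12)

    def test_linearity_in_u(self):
        rng = np.random.default_rng(1)
        data, *_ = random_poisson_instance(rng)
        u = rng.normal(size=data.n_random)
        base = linear_predictor(data, ParameterState(np.zeros(data.n_fixed), np.zeros(data.n_random), [1.0]))
        one = linear_predictor(data, ParameterState(np.zeros(data.n_fixed), u, [1.0]))
        two = linear_predictor(data, ParameterState(np.zeros(data.n_fixed), 2 * u, [1.0]))
        np.testing.assert_allclose(two - base, 2 * (one - base), atol=1e-12)

    def test_gaussian_standard_normal_value(self):
        data = glmm_data_from_arrays([0.0], [[1.0]], {"g": [0]}, family="gaussian")
        h = h_loglik(data, gaussian, unit_state())
        assert h == pytest.approx(-np.log(2 * np.pi), abs=1e-12)

    def test_poisson_closed_form_value(self, single_obs_poisson):
        h = h_loglik(single_obs_poisson, poisson, unit_state())
        assert h == pytest.approx(-1.0 - 0.5 * np.log(2 * np.pi), abs=1e-12)

    def test_bernoulli_closed_form_value(self):
        data = glmm_data_from_arrays([1.0], [[1.0]], {"g": [0]}, family="bernoulli")
        h = h_loglik(data, bernoulli, unit_state(sigma=2.0))
        expected = np.log(0.5) - 0.5 * np.log(2 * np.pi * 4.0)
        assert h == pytest.approx(expected, abs=1e-9)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            unit_state(sigma=0.0)


class TestDerivativeOracles:
    @pytest.mark.parametrize("elim", [ELIM_U, ELIM_BETA_U], ids=["u", "beta_u"])
    @pytest.mark.parametrize("family_tag", ["poisson", "bernoulli", "gaussian"])
    def test_gradient_matches_finite_differences(self, family_tag, elim):
        rng = np.random.default_rng(11)
        data, *_ = random_poisson_instance(rng, n_groups=5, obs_per_group=3, p=2)
        data.family_tag = family_tag
        if family_tag == "bernoulli":
            data.y = (data.y > 0).astype(float)
        family = get_family(family_tag)
        params = ParameterState(
            beta=rng.normal(size=2) * 0.3,
            u=rng.normal(size=data.n_random) * 0.5,
            sigmas=[0.8],
            phi=1.3 if family_tag == "gaussian" else 1.0,
        )
        grad = h_gradient(data, family, params, elim)
        w0 = params.w(elim)
        step = 1e-6
        for i in range(len(w0)):
            e = np.zeros_like(w0)
            e[i] = step
            hp = h_loglik(data, family, params.with_w(data, elim, w0 + e))
            hm = h_loglik(data, family, params.with_w(data, elim, w0 - e))
            fd = (hp - hm) / (2 * step)
            assert grad[i] == pytest.approx(fd, rel=1e-5, abs=1e-6)

    @pytest.mark.parametrize("elim", [ELIM_U, ELIM_BETA_U], ids=["u", "beta_u"])
    def test_sparse_hessian_matches_dense_finite_differences(self, elim):
        rng = np.random.default_rng(4)
        data, *_ = random_poisson_instance(rng, n_groups=10, obs_per_group=3, p=2)
        family = poisson
        params = ParameterState(
            beta=rng.normal(size=2) * 0.3, u=rng.normal(size=10) * 0.4, sigmas=[0.9]
        )
        negH = h_hessian_sparse(data, family, params, elim).toarray()
        w0 = params.w(elim)
        step = 1e-5
        dense = np.zeros_like(negH)
        for i in range(len(w0)):
            e = np.zeros_like(w0)
            e[i] = step
            gp = h_gradient(data, family, params.with_w(data, elim, w0 + e), elim)
            gm = h_gradient(data, family, params.with_w(data, elim, w0 - e), elim)
            dense[i] = -(gp - gm) / (2 * step)
        np.testing.assert_allclose(negH, dense, atol=1e-5)

    def test_single_obs_poisson_curvature(self, single_obs_poisson):
        negH = h_hessian_sparse(single_obs_poisson, poisson, unit_state(), ELIM_U)
        np.testing.assert_allclose(negH.toarray(), [[2.0]], atol=1e-12)

    def test_disjoint_groups_structurally_uncoupled(self):
        # two patients in different facilities: no (u_p1, u_p2) coupling
        data = glmm_data_from_arrays(
            [0.0, 1.0], np.ones((2, 1)), {"ip": [0, 1], "hcf": [0, 1]}, family="poisson"
        )
        params = ParameterState([0.0], np.zeros(4), [1.0, 1.0])
        negH = h_hessian_sparse(data, poisson, params, ELIM_U)
        coo = negH.tocoo()
        stored = set(zip(coo.row.tolist(), coo.col.tolist()))
        assert (0, 1) not in stored  # structurally zero, not just numerically


class TestLogDet:
    def test_identity_and_diagonal(self):
        assert logdet_spd(sparse.eye(7, format="csc")) == pytest.approx(0.0, abs=1e-12)
        assert logdet_spd(sparse.diags([2.0, 2.0], format="csc")) == pytest.approx(
            2 * np.log(2.0), abs=1e-12
        )

    def test_matches_dense_eigenvalue_oracle(self):
        rng = np.random.default_rng(3)
        B = sparse.random(200, 200, density=0.02, random_state=3, format="csc")
        M = (B.T @ B + sparse.eye(200)).tocsc()
        expected = float(np.sum(np.log(np.linalg.eigvalsh(M.toarray()))))
        assert logdet_spd(M) == pytest.approx(expected, rel=1e-8)

    def test_non_pd_rejected(self):
        M = sparse.diags([1.0, -1.0], format="csc")
        with pytest.raises(np.linalg.LinAlgError):
            logdet_spd(M)


class TestInnerMode:
    def test_gaussian_ridge_shrinkage(self):
        data = glmm_data_from_arrays([2.0], [[1.0]], {"g": [0]}, family="gaussian")
        sol = inner_mode(data, gaussian, unit_state(), ELIM_U)
        assert sol.converged
        assert sol.w_hat[0] == pytest.approx(1.0, abs=1e-8)  # sigma^2/(sigma^2+phi) * y

    def test_poisson_mode_at_zero(self, single_obs_poisson):
        sol = inner_mode(single_obs_poisson, poisson, unit_state(), ELIM_U)
        assert sol.converged
        assert sol.w_hat[0] == pytest.approx(0.0, abs=1e-10)

    def test_gradient_vanishes_at_mode(self):
        rng = np.random.default_rng(9)
        data, _, sigma = random_poisson_instance(rng, n_groups=12, obs_per_group=5)
        theta = ParameterState(np.array([0.2, -0.1]), np.zeros(12), [sigma])
        sol = inner_mode(data, poisson, theta, ELIM_BETA_U)
        grad = h_gradient(data, poisson, theta.with_w(data, ELIM_BETA_U, sol.w_hat), ELIM_BETA_U)
        assert np.max(np.abs(grad)) <= 1e-8


class TestAdjustedProfile:
    def test_gaussian_single_obs_exact_marginal(self):
        data = glmm_data_from_arrays([1.0], [[1.0]], {"g": [0]}, family="gaussian")
        value, _ = adjusted_profile_loglik(data, gaussian, unit_state(), ELIM_U)
        expected = norm.logpdf(1.0, loc=0.0, scale=np.sqrt(2.0))
        assert value == pytest.approx(expected, abs=1e-10)
        assert expected == pytest.approx(-0.5 * np.log(4 * np.pi) - 0.25, abs=1e-9)

    def test_poisson_single_obs_closed_form_assembly(self, single_obs_poisson):
        value, _ = adjusted_profile_loglik(single_obs_poisson, poisson, unit_state(), ELIM_U)
        expected = (-1.0 - 0.5 * np.log(2 * np.pi)) - 0.5 * np.log(2.0 / (2 * np.pi))
        assert value == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(-1.346574, abs=1e-6)

    def test_laplace_close_to_adaptive_quadrature(self, single_obs_poisson):
        value, _ = adjusted_profile_loglik(single_obs_poisson, poisson, unit_state(), ELIM_U)
        integrand = lambda u: poisson_dist.pmf(1, np.exp(u)) * norm.pdf(u)
        truth = np.log(quad(integrand, -12, 12)[0])
        # tolerance established by the oracle: LA error here is ~5e-3
        assert abs(value - truth) < 0.01

    def test_gaussian_exactness_general_shape(self):
        rng = np.random.default_rng(21)
        n, q = 30, 6
        idx = rng.integers(0, q, n)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        data = glmm_data_from_arrays(y, X, {"g": idx}, family="gaussian")
        sigma, phi = 0.8, 1.3
        beta = np.array([0.3, -0.2])
        value, _ = adjusted_profile_loglik(
            data, gaussian,
            ParameterState(beta, np.zeros(q), [sigma], phi), ELIM_U,
        )
        Z = data.Z.toarray()
        V = phi * np.eye(n) + sigma**2 * Z @ Z.T
        resid = y - X @ beta
        sign, logdetV = np.linalg.slogdet(V)
        expected = -0.5 * (logdetV + resid @ np.linalg.solve(V, resid) + n * np.log(2 * np.pi))
        assert value == pytest.approx(expected, rel=1e-8)

    def test_warm_start_consistency(self):
        rng = np.random.default_rng(13)
        data, _, sigma = random_poisson_instance(rng, n_groups=15, obs_per_group=4)
        theta = ParameterState(np.array([0.1, 0.2]), np.zeros(15), [sigma])
        cold, sol = adjusted_profile_loglik(data, poisson, theta, ELIM_U)
        warm, _ = adjusted_profile_loglik(
            data, poisson, theta, ELIM_U, init=sol.w_hat + rng.normal(scale=0.05, size=15)
        )
        assert warm == pytest.approx(cold, abs=1e-9)

    def test_inner_iterations_monotone_in_h(self):
        # the line-search contract: re-run Newton manually and track h
        rng = np.random.default_rng(17)
        data, _, sigma = random_poisson_instance(rng, n_groups=10, obs_per_group=4)
        theta = ParameterState(np.array([0.5, -0.4]), np.zeros(10), [sigma])
        from hlik.core import h_hessian_sparse as hess, _factorize_spd

        w = rng.normal(scale=0.5, size=10)
        params = theta.with_w(data, ELIM_U, w)
        h_prev = h_loglik(data, poisson, params)
        for _ in range(20):
            grad = h_gradient(data, poisson, params, ELIM_U)
            if np.max(np.abs(grad)) < 1e-10:
                break
            lu, _ = _factorize_spd(hess(data, poisson, params, ELIM_U))
            step = lu.solve(grad)
            scale = 1.0
            while True:
                cand = theta.with_w(data, ELIM_U, w + scale * step)
                h_new = h_loglik(data, poisson, cand)
                if h_new >= h_prev - 1e-12 * abs(h_prev):
                    break
                scale /= 2
            assert h_new >= h_prev - 1e-12 * abs(h_prev)
            w, params, h_prev = w + scale * step, cand, h_new
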