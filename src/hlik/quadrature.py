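"""Independent marginal-likelihood evaluations for verification.

Three oracles, ordered by generality:

* adaptive Gauss–Hermite quadrature (AGH) for single-grouping-factor models,
  where the marginal likelihood factorizes into per-group univariate
  integrals; an order-1 rule reproduces the Laplace approximation exactly;
* the exact gaussian linear mixed model marginal (dense algebra, small N),
  with ML and REML criteria;
* a tensor-product Gauss–Hermite grid over all random effects jointly for
  tiny crossed structures (q <= 4), converging to the true marginal as the
  per-dimension order grows.

These never stand in for the estimators; they are the cross-checks.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import product

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy import optimize
from scipy.special import logsumexp

from .core import ELIM_U, ParameterState, inner_mode
from .data import GLMMData
from .families import FamilySpec, get_family

__all__ = [
    "agh_marginal_loglik",
    "agh_fit",
    "gaussian_lmm_closed_form",
    "bruteforce_marginal_loglik",
]

BRUTEFORCE_MAX_Q = 4
ORACLE_N_CAP = 2000


@lru_cache(maxsize=None)
def _gh_rule(m: int):
    # physicists' convention: integrates f(x) e^{-x^2} dx
    nodes, weights = hermgauss(m)
    return nodes, weights


def _group_rows(data: GLMMData):
    """Row index lists per level of the single grouping factor."""
    (name, (start, stop)), = data.group_blocks.items()
    Zc = data.Z.tocsc()
    rows = []
    for j in range(start, stop):
        rows.append(Zc.indices[Zc.indptr[j]:Zc.indptr[j + 1]])
    return rows


def agh_marginal_loglik(data: GLMMData, family, params, m: int) -> float:
    """Adaptive Gauss–Hermite marginal log-likelihood, single grouping factor.

    ``params`` is ``(beta, sigma, phi)`` (or a :class:`ParameterState`).
    Each group's integral is centered at its univariate conditional mode and
    scaled by the curvature there; ``m = 1`` reproduces the Laplace
    approximation exactly.
    """
    family = get_family(family) if isinstance(family, str) else family
    if len(data.group_blocks) != 1:
        raise ValueError(
            "AGH factorization requires exactly one grouping factor; "
            f"got {data.group_names}"
        )
    if m < 1:
        raise ValueError(f"quadrature order must be >= 1, got {m}")
    if isinstance(params, ParameterState):
        beta, sigma, phi = params.beta, float(params.sigmas[0]), params.phi
    else:
        beta, sigma, phi = params
        sigma = float(np.atleast_1d(sigma)[0])
    beta = np.asarray(beta, dtype=float)

    eta_fixed = data.X @ beta + data.offset
    nodes, weights = _gh_rule(m)
    total = 0.0
    for g, rows in enumerate(_group_rows(data)):
        y_g = data.y[rows]
        eta0 = eta_fixed[rows]

        def h_g(u):
            return (
                float(np.sum(family.log_density(y_g, eta0 + u, phi)))
                - 0.5 * u**2 / sigma**2
                - 0.5 * np.log(2.0 * np.pi * sigma**2)
            )

        def grad_g(u):
            return float(np.sum(family.score_eta(y_g, eta0 + u, phi))) - u / sigma**2

        def curv_g(u):
            return float(np.sum(family.weight(eta0 + u, phi))) + 1.0 / sigma**2

        # univariate Newton for the conditional mode
        u = 0.0
        for _ in range(100):
            step = grad_g(u) / curv_g(u)
            u += step
            if abs(step) < 1e-12:
                break
        s = 1.0 / np.sqrt(curv_g(u))
        if m == 1:
            # exactly the Laplace approximation for this group
            total += h_g(u) + 0.5 * np.log(2.0 * np.pi * s**2)
            continue
        log_terms = np.array(
            [np.log(w) + x**2 + h_g(u + np.sqrt(2.0) * s * x) for x, w in zip(nodes, weights)]
        )
        total += logsumexp(log_terms) + 0.5 * np.log(2.0) + np.log(s)
    if not np.isfinite(total):
        raise FloatingPointError("non-finite AGH integrand")
    return float(total)


def agh_fit(data: GLMMData, family, m: int, start_beta=None, start_sigma=1.0):
    """Maximum likelihood by order-m AGH for single-grouping-factor models.

    Verification fitter (the glmer-style route): maximizes the AGH marginal
    over ``(beta, log sigma)`` by quasi-Newton.  Returns
    ``(beta_hat, sigma_hat, loglik, converged)``.
    """
    family = get_family(family) if isinstance(family, str) else family
    p = data.n_fixed
    beta0 = np.zeros(p) if start_beta is None else np.asarray(start_beta, float)

    def neg(x):
        return -agh_marginal_loglik(data, family, (x[:p], np.exp(x[p:]), 1.0), m)

    x0 = np.concatenate([beta0, [np.log(start_sigma)]])
    res = optimize.minimize(
        neg, x0, method="L-BFGS-B",
        bounds=[(None, None)] * p + [(np.log(1e-4), None)],
        options={"ftol": 1e-12, "gtol": 1e-7, "maxiter": 500},
    )
    return res.x[:p], float(np.exp(res.x[p])), float(-res.fun), bool(res.success)


def _gaussian_marginal_loglik(data: GLMMData, sigmas, phi, criterion="ML"):
    """Exact gaussian LMM log-likelihood with V = phi I + Z G Z' (dense)."""
    n = data.n_obs
    Z = data.Z.toarray()
    sd2 = np.empty(data.n_random)
    for k, (start, stop) in enumerate(data.group_blocks.values()):
        sd2[start:stop] = sigmas[k] ** 2
    V = phi * np.eye(n) + (Z * sd2) @ Z.T
    Vinv = np.linalg.inv(V)
    X, y = data.X, data.y - data.offset
    XtVi = X.T @ Vinv
    A = XtVi @ X
    beta = np.linalg.solve(A, XtVi @ y)
    r = y - X @ beta
    sign, logdetV = np.linalg.slogdet(V)
    ll = -0.5 * (logdetV + r @ Vinv @ r + n * np.log(2.0 * np.pi))
    if criterion.upper() == "REML":
        signA, logdetA = np.linalg.slogdet(A / (2.0 * np.pi))
        ll -= 0.5 * logdetA
    return ll, beta


def gaussian_lmm_closed_form(data: GLMMData, criterion: str = "REML"):
    """Exact ML/REML fit of a gaussian LMM by dense marginal maximization.

    Test oracle only: refuses N > 2000.  Returns
    ``(beta_hat, sigmas_hat, phi_hat, loglik)``; variance components at the
    boundary are clamped at 1e-6.
    """
    if data.family_tag != "gaussian":
        raise ValueError("closed-form oracle is for gaussian models")
    if data.n_obs > ORACLE_N_CAP:
        raise ValueError(f"oracle limited to N <= {ORACLE_N_CAP}, got {data.n_obs}")
    r = len(data.group_blocks)

    def neg(x):
        sig = np.exp(x[:r])
        phi = np.exp(x[r])
        ll, _ = _gaussian_marginal_loglik(data, sig, phi, criterion)
        return -ll

    x0 = np.zeros(r + 1)
    res = optimize.minimize(
        neg, x0, method="L-BFGS-B",
        bounds=[(np.log(1e-6), 12.0)] * (r + 1),
        options={"ftol": 1e-15, "gtol": 1e-9, "maxiter": 1000},
    )
    sig = np.exp(res.x[:r])
    phi = float(np.exp(res.x[r]))
    ll, beta = _gaussian_marginal_loglik(data, sig, phi, criterion)
    return beta, sig, phi, float(ll)


def bruteforce_marginal_loglik(data: GLMMData, family, params, nodes_per_dim: int) -> float:
    """Tensor-grid Gauss–Hermite marginal over all random effects jointly.

    Centered at the joint inner mode and scaled by the Cholesky factor of the
    inverse curvature; exact in the limit of many nodes.  Only for q <= 4.
    """
    family = get_family(family) if isinstance(family, str) else family
    q = data.n_random
    if q > BRUTEFORCE_MAX_Q:
        raise ValueError(f"tensor grid limited to q <= {BRUTEFORCE_MAX_Q}, got q = {q}")
    if isinstance(params, ParameterState):
        theta = params
    else:
        beta, sigmas, phi = params
        theta = ParameterState(
            beta=np.asarray(beta, float), u=np.zeros(q),
            sigmas=np.atleast_1d(sigmas), phi=phi,
        )
    sol = inner_mode(data, family, theta, ELIM_U)
    negH = sol.neg_hessian.toarray()
    cov = np.linalg.inv(negH)
    L = np.linalg.cholesky(cov)
    nodes, weights = _gh_rule(nodes_per_dim)
    logw = np.log(weights)

    # full tensor grid, evaluated in vectorized blocks
    grid_idx = np.array(list(product(range(nodes_per_dim), repeat=q)))  # (M, q)
    sd = np.empty(q)
    for k, (start, stop) in enumerate(data.group_blocks.values()):
        sd[start:stop] = np.atleast_1d(theta.sigmas)[k]
    eta_fixed = data.X @ theta.beta + data.offset
    log_terms = np.empty(len(grid_idx))
    block = 65536
    for s in range(0, len(grid_idx), block):
        idx = grid_idx[s : s + block]
        x = nodes[idx]  # (B, q)
        u = sol.w_hat + np.sqrt(2.0) * (x @ L.T)  # (B, q)
        eta = eta_fixed[None, :] + u @ np.asarray(data.Z.todense()).T  # (B, n)
        ll_data = np.sum(family.log_density(data.y[None, :], eta, theta.phi), axis=1)
        ll_u = (
            -0.5 * np.sum((u / sd) ** 2, axis=1)
            - np.sum(np.log(sd))
            - 0.5 * q * np.log(2.0 * np.pi)
        )
        log_terms[s : s + block] = (
            ll_data + ll_u + np.sum(x**2, axis=1) + np.sum(logw[idx], axis=1)
        )
    sign, logdetL = np.linalg.slogdet(L)
    return float(logsumexp(log_terms) + 0.5 * q * np.log(2.0) + logdetL)
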