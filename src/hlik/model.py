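"""Staged hierarchical-likelihood estimators for GLMMs.

Three estimation routes are offered, all built on the Laplace-approximate
adjusted profile likelihoods in :mod:`hlik.core`:

``HL(1,1)`` (two-stage REML)
    Stage 1 maximizes p_{beta,u}(h) over the variance components (and the
    dispersion for gaussian models), eliminating fixed and random effects
    jointly — REML estimation of the variance components.  Stage 2 fixes
    those estimates and maximizes p_u(h) over beta.  Random-effect
    predictions are read from the stage-2 inner mode.

``HL(0,1)`` (joint shortcut)
    Stage 1 only; beta and u are read from the final inner optimization of
    p_{beta,u}(h).  Cheap, but biased for sparse binary outcomes.

``ML`` (Laplace maximum likelihood)
    Maximizes p_u(h) jointly over beta and the variance components — what a
    single-quadrature-node (AGH1) marginal-likelihood fit computes.

Outer optimizations use bound-constrained quasi-Newton (L-BFGS-B) on the
log-SD scale with central finite-difference gradients and warm-started
inner Newton solves; standard errors come from central-difference numerical
Hessians of the relevant adjusted profile at its optimum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .core import (
    ELIM_BETA_U,
    ELIM_U,
    ParameterState,
    adjusted_profile_loglik,
    inner_mode,
)
from .data import GLMMData
from .families import FamilySpec, get_family

__all__ = [
    "GLMM",
    "GLMMResults",
    "fit_hl11",
    "fit_hl01",
    "fit_ml_laplace",
    "refit_random_effects",
    "standard_errors",
    "numerical_hessian",
]

SIGMA_FLOOR = 1e-4
_FD_STEP = 3e-5
_OUTER_FTOL = 1e-12
_OUTER_GTOL = 2e-6


def numerical_hessian(objective, x, step=_FD_STEP):
    """Central-difference Hessian of a scalar function at ``x``."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    h = step * np.maximum(1.0, np.abs(x))
    H = np.empty((n, n))
    f0 = objective(x)

    def f(v):
        return objective(v)

    for i in range(n):
        ei = np.zeros(n)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h[i] ** 2
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def standard_errors(objective, optimum, scale="natural", step=_FD_STEP):
    """Standard errors from the numerical Hessian of a maximized objective.

    ``scale="log"`` applies the delta method, returning SEs on the natural
    (e.g. SD) scale for parameters optimized on the log scale.  A numerical
    Hessian that is not negative definite yields NaN SEs (flagged upstream).
    """
    optimum = np.asarray(optimum, dtype=float)
    H = numerical_hessian(objective, optimum, step=step)
    try:
        cov = np.linalg.inv(-H)
        se = np.sqrt(np.diag(cov))
        if not np.all(np.isfinite(se)):
            raise np.linalg.LinAlgError
    except (np.linalg.LinAlgError, FloatingPointError):
        return np.full(len(optimum), np.nan), None
    if scale == "log":
        se = np.exp(optimum) * se
    return se, cov


class _WarmStartObjective:
    """Wrap an adjusted-profile evaluation with inner-mode warm starting.

    ``grad_fn(x, sol)``, when given, supplies an analytic outer gradient
    (used for gaussian stage 2, where the log-determinant adjustment does
    not depend on beta); otherwise central finite differences are used.
    """

    def __init__(self, evaluate, grad_fn=None):
        self._evaluate = evaluate  # (x, init) -> (value, InnerSolution)
        self.grad_fn = grad_fn
        self.w = None
        self.last_solution = None
        self.n_evals = 0

    def __call__(self, x):
        value, sol = self._evaluate(x, self.w)
        self.w = sol.w_hat
        self.last_solution = sol
        self.n_evals += 1
        return value

    def negative(self, x):
        return -self(x)

    def negative_grad(self, x, step=_FD_STEP):
        if self.grad_fn is not None:
            self(x)
            return -self.grad_fn(x, self.last_solution)
        g = np.empty_like(x)
        for i in range(len(x)):
            e = np.zeros_like(x)
            e[i] = step
            g[i] = (self(x + e) - self(x - e)) / (2.0 * step)
        return -g


def _irls_glm(data: GLMMData, family: FamilySpec, max_iter=25, tol=1e-8):
    """Unpenalized fixed-effects-only GLM fit, used to initialize beta."""
    p = data.n_fixed
    beta = np.zeros(p)
    if family.name == "gaussian":
        beta, *_ = np.linalg.lstsq(data.X, data.y - data.offset, rcond=None)
        return beta
    for _ in range(max_iter):
        eta = data.X @ beta + data.offset
        score = data.X.T @ family.score_eta(data.y, eta)
        w = family.weight(eta)
        fisher = data.X.T @ (data.X * w[:, None]) + 1e-10 * np.eye(p)
        step = np.linalg.solve(fisher, score)
        # dampen: cap the step to keep eta in a sane range early on
        norm = np.max(np.abs(step))
        if norm > 5.0:
            step *= 5.0 / norm
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


@dataclass
class StageDiagnostics:
    converged: bool
    n_outer_iterations: int
    n_evaluations: int
    objective: float
    message: str = ""


@dataclass
class GLMMResults:
    """Fit results: estimates, uncertainties, predictions and diagnostics."""

    model: "GLMM"
    method: str
    params: np.ndarray
    bse: np.ndarray
    vc_sd: np.ndarray
    vc_sd_se: np.ndarray
    random_effects: np.ndarray
    phi: float = 1.0
    phi_se: float = np.nan
    stage1_objective: float = np.nan
    stage2_objective: float = np.nan
    converged: bool = True
    boundary: bool = False
    diagnostics: dict = field(default_factory=dict)
    cov_params_: np.ndarray | None = None

    @property
    def param_names(self):
        return self.model.data.x_names

    @property
    def group_names(self):
        return self.model.data.group_names

    def cov_params(self):
        return self.cov_params_

    def random_effects_by_group(self):
        """dict factor -> pandas-free mapping of level label -> prediction."""
        data = self.model.data
        out = {}
        for name, (start, stop) in data.group_blocks.items():
            out[name] = dict(zip(data.group_levels[name], self.random_effects[start:stop]))
        return out

    def summary(self) -> str:
        lines = [
            f"GLMM fit by hierarchical likelihood [{self.method}]",
            f"family: {self.model.family.name}   N = {self.model.data.n_obs}   "
            f"p = {self.model.data.n_fixed}   q = {self.model.data.n_random}",
            f"stage-1 objective p_bu(h) = {self.stage1_objective:.6f}",
        ]
        if np.isfinite(self.stage2_objective):
            lines.append(f"stage-2 objective p_u(h)  = {self.stage2_objective:.6f}")
        lines.append("")
        lines.append(f"{'coefficient':<24}{'estimate':>12}{'std.err':>12}")
        for name, est, se in zip(self.param_names, self.params, self.bse):
            lines.append(f"{name:<24}{est:>12.4f}{se:>12.4f}")
        lines.append("")
        lines.append(f"{'random effect (SD)':<24}{'estimate':>12}{'std.err':>12}")
        for name, sd, se in zip(self.group_names, self.vc_sd, self.vc_sd_se):
            lines.append(f"{name:<24}{sd:>12.4f}{se:>12.4f}")
        if self.model.family.name == "gaussian":
            lines.append(f"{'residual SD (sqrt phi)':<24}{np.sqrt(self.phi):>12.4f}")
        if self.boundary:
            lines.append("warning: a variance component is at its lower bound; "
                         "its SE is unreliable")
        if not self.converged:
            lines.append("WARNING: fit did not converge; see .diagnostics")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "coefficients": [
                {"name": n, "estimate": float(e), "se": float(s)}
                for n, e, s in zip(self.param_names, self.params, self.bse)
            ],
            "variance_components": [
                {"factor": n, "sd": float(sd), "se": float(se)}
                for n, sd, se in zip(self.group_names, self.vc_sd, self.vc_sd_se)
            ],
            "dispersion": float(self.phi),
            "objectives": {
                "stage1_p_bu_h": float(self.stage1_objective),
                "stage2_p_u_h": float(self.stage2_objective),
            },
            "converged": bool(self.converged),
            "boundary": bool(self.boundary),
            "diagnostics": {k: str(v) for k, v in self.diagnostics.items()},
        }

    def save_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def save_random_effects(self, path):
        with open(path, "w") as fh:
            fh.write("factor,level,estimate\n")
            for factor, mapping in self.random_effects_by_group().items():
                for level, est in mapping.items():
                    fh.write(f"{factor},{level},{est!r}\n")


class GLMM:
    """A generalized linear mixed model with random intercepts.

    Parameters
    ----------
    data : GLMMData
        Response, designs, offset and grouping structure
        (see :func:`hlik.data.build_design`).
    family : FamilySpec or str, optional
        Defaults to the family tag recorded in ``data``.
    """

    def __init__(self, data: GLMMData, family: FamilySpec | str | None = None):
        self.data = data
        if family is None:
            family = data.family_tag
        self.family = get_family(family) if isinstance(family, str) else family

    @classmethod
    def from_long_table(cls, table, model_config: dict) -> "GLMM":
        from .data import build_design

        data = build_design(table, model_config)
        return cls(data, model_config.get("family", data.family_tag))

    # -- objective plumbing -------------------------------------------------

    def _theta_names(self):
        names = [f"log_sd[{g}]" for g in self.data.group_names]
        if self.family.name == "gaussian":
            names.append("log_phi")
        return names

    def _unpack_theta(self, x):
        r = len(self.data.group_blocks)
        sigmas = np.exp(x[:r])
        phi = float(np.exp(x[r])) if self.family.name == "gaussian" else 1.0
        return sigmas, phi

    def _stage1_objective(self, beta0):
        data, family = self.data, self.family

        def evaluate(x, init):
            sigmas, phi = self._unpack_theta(x)
            theta = ParameterState(
                beta=np.zeros(data.n_fixed), u=np.zeros(data.n_random),
                sigmas=sigmas, phi=phi,
            )
            if init is None:
                init = np.concatenate([beta0, np.zeros(data.n_random)])
            return adjusted_profile_loglik(data, family, theta, ELIM_BETA_U, init=init)

        return _WarmStartObjective(evaluate)

    def _stage2_objective(self, sigmas, phi):
        data, family = self.data, self.family

        def evaluate(beta, init):
            theta = ParameterState(
                beta=np.asarray(beta, dtype=float), u=np.zeros(data.n_random),
                sigmas=sigmas, phi=phi,
            )
            return adjusted_profile_loglik(data, family, theta, ELIM_U, init=init)

        grad_fn = None
        if family.name == "gaussian":
            # identity link: the curvature (hence the log-det adjustment) is
            # free of beta, so dp_u/dbeta is the exact profiled GLS score
            def grad_fn(beta, sol):
                resid = data.y - data.X @ beta - data.Z @ sol.w_hat - data.offset
                return data.X.T @ resid / phi

        return _WarmStartObjective(evaluate, grad_fn=grad_fn)

    def _ml_objective(self):
        data, family = self.data, self.family
        p = data.n_fixed

        def evaluate(x, init):
            beta = x[:p]
            sigmas, phi = self._unpack_theta(x[p:])
            theta = ParameterState(
                beta=beta, u=np.zeros(data.n_random), sigmas=sigmas, phi=phi
            )
            return adjusted_profile_loglik(data, family, theta, ELIM_U, init=init)

        return _WarmStartObjective(evaluate)

    def _maximize(self, objective, x0, bounds, ftol=_OUTER_FTOL):
        res = optimize.minimize(
            objective.negative,
            x0,
            jac=objective.negative_grad,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": ftol, "gtol": _OUTER_GTOL, "maxiter": 200},
        )
        return res

    def _theta_bounds(self, n_theta):
        return [(np.log(SIGMA_FLOOR), None)] * n_theta

    # -- fitting ------------------------------------------------------------

    def fit(self, method: str = "hl11", start_sigmas=None, compute_se: bool = True,
            se_step: float = _FD_STEP) -> GLMMResults:
        """Fit the model.

        Parameters
        ----------
        method : {"hl11", "hl01", "ml"}
            Estimation route (see the module docstring).
        start_sigmas : array-like, optional
            Starting SDs, one per grouping factor (default 1.0 each).
        compute_se : bool
            Skip the numerical-Hessian standard errors when False (useful in
            simulation harnesses where only point estimates are needed).
        """
        method = method.lower()
        if method in ("hl11", "hl(1,1)"):
            return self._fit_hl11(start_sigmas, compute_se, se_step)
        if method in ("hl01", "hl(0,1)"):
            return self._fit_hl01(start_sigmas, compute_se, se_step)
        if method in ("ml", "ml-laplace", "agh1"):
            return self._fit_ml(start_sigmas, compute_se, se_step)
        raise ValueError(f"unknown method {method!r}; expected hl11, hl01 or ml")

    def _start_theta(self, start_sigmas):
        r = len(self.data.group_blocks)
        sig = np.full(r, 1.0) if start_sigmas is None else np.asarray(start_sigmas, float)
        x0 = list(np.log(sig))
        if self.family.name == "gaussian":
            resid = self.data.y - self.data.offset
            x0.append(np.log(max(np.var(resid), 1e-3)))
        return np.array(x0)

    def _run_stage1(self, start_sigmas):
        beta0 = _irls_glm(self.data, self.family)
        obj = self._stage1_objective(beta0)
        x0 = self._start_theta(start_sigmas)
        res = self._maximize(obj, x0, self._theta_bounds(len(x0)))
        # re-evaluate at the optimum so the cached inner solution matches it
        value = obj(res.x)
        return obj, res, value

    def _fit_hl11(self, start_sigmas, compute_se, se_step) -> GLMMResults:
        data, family = self.data, self.family
        obj1, res1, val1 = self._run_stage1(start_sigmas)
        sigmas, phi = self._unpack_theta(res1.x)
        boundary = bool(np.any(res1.x[: len(sigmas)] <= np.log(SIGMA_FLOOR) + 1e-9))

        r = len(sigmas)
        if compute_se:
            theta_se, _ = standard_errors(obj1, res1.x, scale="log", step=se_step)
        else:
            theta_se = np.full(len(res1.x), np.nan)
        vc_sd_se = theta_se[:r]
        phi_se = theta_se[-1] if family.name == "gaussian" else np.nan

        # stage 2: fixed effects against p_u(h) at the REML variance components
        p = data.n_fixed
        beta_start = obj1.last_solution.w_hat[:p]
        u_start = obj1.last_solution.w_hat[p:]
        obj2 = self._stage2_objective(sigmas, phi)
        obj2.w = u_start
        res2 = self._maximize(obj2, beta_start, [(None, None)] * p, ftol=1e-15)
        val2 = obj2(res2.x)
        beta_hat = res2.x
        u_hat = obj2.last_solution.w_hat
        if compute_se:
            bse, cov = standard_errors(obj2, beta_hat, step=se_step)
        else:
            bse, cov = np.full(p, np.nan), None

        conv = bool(res1.success and res2.success and obj2.last_solution.converged)
        return GLMMResults(
            model=self, method="HL11", params=beta_hat, bse=bse,
            vc_sd=sigmas, vc_sd_se=vc_sd_se, random_effects=u_hat,
            phi=phi, phi_se=phi_se,
            stage1_objective=val1, stage2_objective=val2,
            converged=conv, boundary=boundary,
            diagnostics={
                "stage1": StageDiagnostics(res1.success, res1.nit, obj1.n_evals, val1, str(res1.message)),
                "stage2": StageDiagnostics(res2.success, res2.nit, obj2.n_evals, val2, str(res2.message)),
            },
            cov_params_=cov,
        )

    def _fit_hl01(self, start_sigmas, compute_se, se_step) -> GLMMResults:
        data, family = self.data, self.family
        obj1, res1, val1 = self._run_stage1(start_sigmas)
        sigmas, phi = self._unpack_theta(res1.x)
        boundary = bool(np.any(res1.x[: len(sigmas)] <= np.log(SIGMA_FLOOR) + 1e-9))
        r = len(sigmas)
        if compute_se:
            theta_se, _ = standard_errors(obj1, res1.x, scale="log", step=se_step)
        else:
            theta_se = np.full(len(res1.x), np.nan)
        phi_se = theta_se[-1] if family.name == "gaussian" and np.isfinite(theta_se[-1]) else np.nan

        sol = obj1.last_solution
        p = data.n_fixed
        beta_hat = sol.w_hat[:p]
        u_hat = sol.w_hat[p:]
        if compute_se:
            # beta block of the inverse joint curvature at the inner mode
            cols = np.zeros((sol.neg_hessian.shape[0], p))
            cols[:p, :] = np.eye(p)
            inv_block = np.column_stack([sol.factor.solve(cols[:, j]) for j in range(p)])[:p, :]
            cov = 0.5 * (inv_block + inv_block.T)
            bse = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        else:
            bse, cov = np.full(p, np.nan), None

        return GLMMResults(
            model=self, method="HL01", params=beta_hat, bse=bse,
            vc_sd=sigmas, vc_sd_se=theta_se[:r], random_effects=u_hat,
            phi=phi, phi_se=phi_se,
            stage1_objective=val1, stage2_objective=np.nan,
            converged=bool(res1.success and sol.converged), boundary=boundary,
            diagnostics={
                "stage1": StageDiagnostics(res1.success, res1.nit, obj1.n_evals, val1, str(res1.message)),
            },
            cov_params_=cov,
        )

    def _fit_ml(self, start_sigmas, compute_se, se_step) -> GLMMResults:
        data, family = self.data, self.family
        p = data.n_fixed
        beta0 = _irls_glm(data, family)
        obj = self._ml_objective()
        x0 = np.concatenate([beta0, self._start_theta(start_sigmas)])
        n_theta = len(x0) - p
        bounds = [(None, None)] * p + self._theta_bounds(n_theta)
        res = self._maximize(obj, x0, bounds)
        val = obj(res.x)
        sigmas, phi = self._unpack_theta(res.x[p:])
        boundary = bool(np.any(res.x[p : p + len(sigmas)] <= np.log(SIGMA_FLOOR) + 1e-9))
        u_hat = obj.last_solution.w_hat

        if compute_se:
            se_all, cov = standard_errors(obj, res.x, step=se_step)
            bse = se_all[:p]
            vc_sd_se = sigmas * se_all[p : p + len(sigmas)]
            phi_se = phi * se_all[-1] if family.name == "gaussian" else np.nan
        else:
            bse, cov = np.full(p, np.nan), None
            vc_sd_se = np.full(len(sigmas), np.nan)
            phi_se = np.nan

        return GLMMResults(
            model=self, method="ML", params=res.x[:p], bse=bse,
            vc_sd=sigmas, vc_sd_se=vc_sd_se, random_effects=u_hat,
            phi=phi, phi_se=phi_se,
            stage1_objective=np.nan, stage2_objective=val,
            converged=bool(res.success and obj.last_solution.converged),
            boundary=boundary,
            diagnostics={
                "joint": StageDiagnostics(res.success, res.nit, obj.n_evals, val, str(res.message)),
            },
            cov_params_=cov,
        )


def refit_random_effects(data: GLMMData, family, fit: GLMMResults) -> np.ndarray:
    """Third-stage refit: maximize h(beta_hat, u, gamma_hat, phi_hat) over u.

    The staged estimators skip this, reading u from the stage-2 (or joint)
    inner mode; this function exposes the full three-optimization procedure
    for checking how close those modes are.
    """
    family = get_family(family) if isinstance(family, str) else family
    theta = ParameterState(
        beta=fit.params, u=np.zeros(data.n_random), sigmas=fit.vc_sd, phi=fit.phi
    )
    sol = inner_mode(data, family, theta, ELIM_U, init=fit.random_effects)
    return sol.w_hat


def fit_hl11(data: GLMMData, family=None, options=None) -> GLMMResults:
    """Two-stage HL(1,1) REML fit (functional wrapper around :class:`GLMM`)."""
    return GLMM(data, family).fit("hl11", **(options or {}))


def fit_hl01(data: GLMMData, family=None, options=None) -> GLMMResults:
    """HL(0,1) joint-shortcut fit."""
    return GLMM(data, family).fit("hl01", **(options or {}))


def fit_ml_laplace(data: GLMMData, family=None, options=None) -> GLMMResults:
    """Laplace maximum-likelihood (AGH1-equivalent) fit."""
    return GLMM(data, family).fit("ml", **(options or {}))
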