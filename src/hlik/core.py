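"""Hierarchical log-likelihood evaluation and Laplace-approximate profiles.

The hierarchical (joint) log-likelihood of a GLMM is

    h(beta, u, gamma, phi) = sum_ij log f(y_ij | eta_ij, phi)
                           + log f(u | gamma),

with eta = X beta + Z u + offset and u ~ MVN(0, G(gamma)), G block-diagonal
with sigma_k^2 I within grouping factor k.  Eliminating an argument block w
(the random effects u, or jointly (beta, u)) by profiling and adjusting with
the curvature at the mode gives the adjusted profile log-likelihood

    p_w(h) = [ h - 1/2 log | -H(h, w) / (2 pi) | ]  at  w = w_hat(theta),

which is the Laplace approximation to the log of the integral of exp(h)
over w.  The inner mode w_hat solves the score equations dh/dw = 0 by a
sparse Newton method; the Hessian's sparsity comes directly from the
random-intercept grouping structure.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

from .data import GLMMData
from .families import FamilySpec, get_family

__all__ = [
    "ParameterState",
    "EliminationSet",
    "InnerSolution",
    "linear_predictor",
    "h_loglik",
    "h_gradient",
    "h_hessian_sparse",
    "inner_mode",
    "logdet_spd",
    "adjusted_profile_loglik",
]

INNER_TOL = 1e-8
INNER_MAX_ITER = 100
MAX_HALVINGS = 30


@dataclass(frozen=True)
class ParameterState:
    """Full GLMM parameter vector: beta, u, per-factor SDs, dispersion."""

    beta: np.ndarray
    u: np.ndarray
    sigmas: np.ndarray  # one SD per grouping factor, > 0
    phi: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "beta", np.asarray(self.beta, dtype=float))
        object.__setattr__(self, "u", np.asarray(self.u, dtype=float))
        object.__setattr__(self, "sigmas", np.asarray(self.sigmas, dtype=float))
        if np.any(self.sigmas <= 0):
            raise ValueError(f"variance-component SDs must be > 0, got {self.sigmas}")
        if self.phi <= 0:
            raise ValueError(f"dispersion must be > 0, got {self.phi}")

    def with_w(self, data: GLMMData, elim: "EliminationSet", w: np.ndarray) -> "ParameterState":
        """Return a copy with the elimination-set coordinates replaced by w."""
        if elim.include_beta:
            p = data.n_fixed
            return replace(self, beta=w[:p], u=w[p:])
        return replace(self, u=w)

    def w(self, elim: "EliminationSet") -> np.ndarray:
        return np.concatenate([self.beta, self.u]) if elim.include_beta else self.u


@dataclass(frozen=True)
class EliminationSet:
    """Which arguments are profiled out: u alone, or (beta, u) jointly."""

    include_beta: bool = False

    def dim(self, data: GLMMData) -> int:
        return data.n_random + (data.n_fixed if self.include_beta else 0)


ELIM_U = EliminationSet(include_beta=False)
ELIM_BETA_U = EliminationSet(include_beta=True)


@dataclass
class InnerSolution:
    """Converged (or diagnosed) inner Newton solution for the eliminated block."""

    w_hat: np.ndarray
    logdet: float
    grad_norm: float
    iterations: int
    converged: bool
    h_value: float
    factor: object = None  # factorization of -H at the mode (has .solve)
    _hessian_builder: object = None
    _neg_hessian: object = None

    @property
    def neg_hessian(self) -> sparse.csc_matrix:
        """-H at the mode as an explicit sparse matrix (built on demand)."""
        if self._neg_hessian is None:
            self._neg_hessian = self._hessian_builder()
        return self._neg_hessian


def _sigma_per_column(data: GLMMData, sigmas: np.ndarray) -> np.ndarray:
    out = np.empty(data.n_random)
    for k, (start, stop) in enumerate(data.group_blocks.values()):
        out[start:stop] = sigmas[k]
    return out


def linear_predictor(data: GLMMData, params: ParameterState) -> np.ndarray:
    """eta = X beta + Z u + offset."""
    if len(params.beta) != data.n_fixed or len(params.u) != data.n_random:
        raise ValueError(
            f"dimension mismatch: beta has {len(params.beta)} (need {data.n_fixed}), "
            f"u has {len(params.u)} (need {data.n_random})"
        )
    return data.X @ params.beta + data.Z @ params.u + data.offset


def h_loglik(data: GLMMData, family: FamilySpec, params: ParameterState) -> float:
    """The hierarchical log-likelihood h = log f(y | beta, u) + log f(u | gamma)."""
    family = get_family(family) if isinstance(family, str) else family
    eta = linear_predictor(data, params)
    ll_data = float(np.sum(family.log_density(data.y, eta, params.phi)))
    sd = _sigma_per_column(data, params.sigmas)
    ll_u = float(
        -0.5 * np.sum(params.u**2 / sd**2)
        - np.sum(np.log(sd))
        - 0.5 * data.n_random * np.log(2.0 * np.pi)
    )
    return ll_data + ll_u


def h_gradient(
    data: GLMMData, family: FamilySpec, params: ParameterState, elim: EliminationSet
) -> np.ndarray:
    """Analytic gradient of h with respect to the elimination-set coordinates."""
    family = get_family(family) if isinstance(family, str) else family
    eta = linear_predictor(data, params)
    score = family.score_eta(data.y, eta, params.phi)
    sd = _sigma_per_column(data, params.sigmas)
    grad_u = data.Z.T @ score - params.u / sd**2
    if elim.include_beta:
        return np.concatenate([data.X.T @ score, grad_u])
    return grad_u


def h_hessian_sparse(
    data: GLMMData, family: FamilySpec, params: ParameterState, elim: EliminationSet
) -> sparse.csc_matrix:
    """Negative Hessian -H(h, w) as a sparse SPD matrix.

    -H = A' diag(weights) A + blockdiag(0_p, G^{-1}) with A the elimination-set
    design; the sparsity pattern follows from the grouping structure alone.
    """
    family = get_family(family) if isinstance(family, str) else family
    eta = linear_predictor(data, params)
    w = family.weight(eta, params.phi)
    sd = _sigma_per_column(data, params.sigmas)
    Zw = data.Z.multiply(w[:, None]).tocsc()
    ZWZ = (data.Z.T @ Zw).tocsc()
    Ginv = sparse.diags(1.0 / sd**2, format="csc")
    if not elim.include_beta:
        return (ZWZ + Ginv).tocsc()
    XWX = data.X.T @ (data.X * w[:, None])
    XWZ = data.X.T @ Zw  # dense p x q — p is small
    top = sparse.hstack([sparse.csc_matrix(XWX), sparse.csc_matrix(XWZ)])
    bot = sparse.hstack([sparse.csc_matrix(XWZ.T), ZWZ + Ginv])
    return sparse.vstack([top, bot]).tocsc()


def _factorize_spd(mat: sparse.csc_matrix):
    """Sparse symmetric factorization; raises if the matrix is not PD."""
    lu = splu(
        mat.tocsc(),
        permc_spec="MMD_AT_PLUS_A",
        diag_pivot_thresh=0.0,
        options={"SymmetricMode": True},
    )
    diag = lu.U.diagonal()
    if np.any(diag <= 0) or not np.all(np.isfinite(diag)):
        raise np.linalg.LinAlgError("matrix is not positive definite")
    return lu, float(np.sum(np.log(diag)))


def logdet_spd(mat) -> float:
    """Log-determinant of a sparse SPD matrix via a sparse factorization."""
    _, ld = _factorize_spd(sparse.csc_matrix(mat))
    return ld


# -- structured factorization of the random-intercept Hessian ---------------
#
# For random-intercept models each grouping factor's own block of Z'WZ is
# diagonal (every row of Z hits one level per factor).  Eliminating the
# largest factor's diagonal block by a Schur complement leaves a small dense
# system over (beta and) the remaining factors' levels.  This is an exact
# factorization of the same matrix splu would factor, just ordered to
# exploit the structure.

_DENSE_REST_CAP = 600


def _row_level_indices(data: GLMMData) -> dict:
    """Per-factor level index of each observation row (cached on the data)."""
    cache = getattr(data, "_row_idx_cache", None)
    if cache is not None:
        return cache
    out = {}
    for name, (start, stop) in data.group_blocks.items():
        blk = data.Z[:, start:stop].tocoo()
        idx = np.empty(data.n_obs, dtype=np.intp)
        idx[blk.row] = blk.col
        out[name] = idx
    data._row_idx_cache = out
    return out


class _SchurFactor:
    """Solve/logdet for -H with the dominant factor's block eliminated."""

    def __init__(self, d_diag, T, R, diag_idx, rest_idx, dim):
        if np.any(d_diag <= 0) or not np.all(np.isfinite(d_diag)):
            raise np.linalg.LinAlgError("matrix is not positive definite")
        self.d = d_diag
        self.T = T
        self.diag_idx = diag_idx
        self.rest_idx = rest_idx
        self.dim = dim
        if T is not None and T.shape[1]:
            U = T / d_diag[:, None]
            S = R - T.T @ U
            try:
                self.chol = np.linalg.cholesky(S)
            except np.linalg.LinAlgError:
                raise np.linalg.LinAlgError("matrix is not positive definite") from None
            self.logdet = float(np.sum(np.log(d_diag)) + 2.0 * np.sum(np.log(np.diag(self.chol))))
        else:
            self.chol = None
            self.logdet = float(np.sum(np.log(d_diag)))

    def _solve_rest(self, rhs):
        z = np.linalg.solve(self.chol, rhs)
        return np.linalg.solve(self.chol.T, z)

    def solve(self, b):
        b = np.asarray(b, dtype=float)
        out = np.empty(self.dim)
        b1 = b[self.diag_idx]
        if self.chol is None:
            out[self.diag_idx] = b1 / self.d
            return out
        b2 = b[self.rest_idx]
        y2 = self._solve_rest(b2 - self.T.T @ (b1 / self.d))
        out[self.diag_idx] = (b1 - self.T @ y2) / self.d
        out[self.rest_idx] = y2
        return out


def _structured_factor(data, family, params, elim, eta):
    """Build the Schur factorization of -H, or None if unsuitable."""
    names = list(data.group_blocks)
    sizes = data.block_sizes()
    big = max(names, key=lambda k: sizes[k])
    others = [k for k in names if k != big]
    p = data.n_fixed if elim.include_beta else 0
    m = p + sum(sizes[k] for k in others)
    if m > _DENSE_REST_CAP:
        return None
    w = family.weight(eta, params.phi)
    idx = _row_level_indices(data)
    sd = _sigma_per_column(data, params.sigmas)
    dim = elim.dim(data)

    q_big = sizes[big]
    start_big, stop_big = data.group_blocks[big]
    sigma_big = params.sigmas[names.index(big)]
    d_diag = np.bincount(idx[big], weights=w, minlength=q_big) + 1.0 / sigma_big**2

    # positions of each coordinate in the elimination vector [beta?, u]
    positions = {
        name: np.arange(p + start, p + stop)
        for name, (start, stop) in data.group_blocks.items()
    }
    diag_idx = positions[big]
    rest_parts = ([np.arange(p)] if p else []) + [positions[k] for k in others]
    rest_idx = np.concatenate(rest_parts) if rest_parts else np.array([], dtype=np.intp)

    if m == 0:
        return _SchurFactor(d_diag, None, None, diag_idx, rest_idx, dim)

    # coupling T (q_big x m) and dense rest block R (m x m)
    T = np.zeros((q_big, m))
    R = np.zeros((m, m))
    col = 0
    cols = {}
    if p:
        Xw = data.X * w[:, None]
        R[:p, :p] = data.X.T @ Xw
        for j in range(p):
            T[:, j] = np.bincount(idx[big], weights=Xw[:, j], minlength=q_big)
        cols["(beta)"] = (0, p)
        col = p
    for k in others:
        q_k = sizes[k]
        sigma_k = params.sigmas[names.index(k)]
        sl = slice(col, col + q_k)
        cols[k] = (col, col + q_k)
        # own diagonal block
        d_k = np.bincount(idx[k], weights=w, minlength=q_k) + 1.0 / sigma_k**2
        R[sl, sl] += np.diag(d_k)
        # coupling with the eliminated factor
        C = sparse.coo_matrix((w, (idx[big], idx[k])), shape=(q_big, q_k))
        T[:, sl] = C.toarray()
        if p:
            for j in range(p):
                R[j, sl] = np.bincount(idx[k], weights=Xw[:, j], minlength=q_k)
                R[sl, j] = R[j, sl]
        col += q_k
    # cross-couplings among the non-eliminated factors
    for a in range(len(others)):
        for b in range(a + 1, len(others)):
            ka, kb = others[a], others[b]
            (ca0, ca1), (cb0, cb1) = cols[ka], cols[kb]
            Cab = sparse.coo_matrix(
                (w, (idx[ka], idx[kb])), shape=(sizes[ka], sizes[kb])
            ).toarray()
            R[ca0:ca1, cb0:cb1] = Cab
            R[cb0:cb1, ca0:ca1] = Cab.T
    return _SchurFactor(d_diag, T, R, diag_idx, rest_idx, dim)


def inner_mode(
    data: GLMMData,
    family: FamilySpec,
    theta: ParameterState,
    elim: EliminationSet,
    init: np.ndarray | None = None,
) -> InnerSolution:
    """Maximize h over the elimination set by Newton with step halving.

    Converged means the sup-norm of the score is at most ``INNER_TOL``; a
    non-converged solve is returned flagged, never silently.
    """
    family = get_family(family) if isinstance(family, str) else family
    dim = elim.dim(data)
    w = np.zeros(dim) if init is None else np.asarray(init, dtype=float).copy()
    if len(w) != dim:
        raise ValueError(f"init has length {len(w)}, elimination set has dim {dim}")
    params = theta.with_w(data, elim, w)
    h = h_loglik(data, family, params)

    def factorize(prm):
        eta = linear_predictor(data, prm)
        fac = _structured_factor(data, family, prm, elim, eta)
        if fac is not None:
            return fac, fac.logdet
        return _factorize_spd(h_hessian_sparse(data, family, prm, elim))

    lu = None
    grad = h_gradient(data, family, params, elim)
    it = 0
    while True:
        gnorm = float(np.max(np.abs(grad))) if dim else 0.0
        if gnorm <= INNER_TOL or it >= INNER_MAX_ITER:
            break
        try:
            lu, _ = factorize(params)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"inner Newton: non-PD negative Hessian at iteration {it} "
                f"(grad norm {gnorm:.3e}); with fixed effects in the "
                "elimination set this often signals (quasi-)separation of a "
                "sparse dummy covariate"
            ) from exc
        step = lu.solve(grad)
        # step halving: accept the first step that does not decrease h
        scale, accepted = 1.0, False
        for _ in range(MAX_HALVINGS + 1):
            w_new = w + scale * step
            params_new = theta.with_w(data, elim, w_new)
            h_new = h_loglik(data, family, params_new)
            if np.isfinite(h_new) and h_new >= h - 1e-12 * max(1.0, abs(h)):
                accepted = True
                break
            scale *= 0.5
        if not accepted:
            raise np.linalg.LinAlgError(
                f"inner Newton: line search failed at iteration {it} "
                f"(grad norm {gnorm:.3e}, h {h:.6e})"
            )
        w, params, h = w_new, params_new, h_new
        grad = h_gradient(data, family, params, elim)
        it += 1
    # curvature at the final point (recompute so the factor matches w)
    lu, ld = factorize(params)
    gnorm = float(np.max(np.abs(grad))) if dim else 0.0
    params_final = params
    return InnerSolution(
        w_hat=w,
        logdet=ld,
        grad_norm=gnorm,
        iterations=it,
        converged=gnorm <= INNER_TOL,
        h_value=h,
        factor=lu,
        _hessian_builder=lambda: h_hessian_sparse(data, family, params_final, elim),
    )


def adjusted_profile_loglik(
    data: GLMMData,
    family: FamilySpec,
    theta: ParameterState,
    elim: EliminationSet,
    init: np.ndarray | None = None,
):
    """Laplace approximation p_w(h) = h(w_hat) - 1/2 log|-H/(2 pi)|.

    Returns ``(value, InnerSolution)``; pass a previous mode as ``init`` to
    warm-start the inner Newton solve.
    """
    sol = inner_mode(data, family, theta, elim, init=init)
    dim = elim.dim(data)
    value = sol.h_value - 0.5 * sol.logdet + 0.5 * dim * np.log(2.0 * np.pi)
    return value, sol
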