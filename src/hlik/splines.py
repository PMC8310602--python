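"""Natural cubic spline bases for non-linear covariate effects.

Natural cubic regression splines constrain the fitted curve to be linear
beyond the boundary knots, which stabilises tail behaviour where data are
thin — the standard choice when modelling dose-response-like relationships
such as log relative risk against serum potassium.

The basis is the textbook truncated-power construction: for knots
xi_1 < ... < xi_K define

    d_k(x) = [ (x - xi_k)_+^3 - (x - xi_K)_+^3 ] / (xi_K - xi_k)

and take the K - 1 non-constant functions  x,  d_1 - d_{K-1}, ...,
d_{K-2} - d_{K-1}.  With df basis columns, K = df + 1 knots are used:
two boundary knots plus df - 1 interior knots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NaturalCubicSplineBasis", "natural_cubic_spline_basis"]


@dataclass(frozen=True)
class NaturalCubicSplineBasis:
    """A natural cubic spline basis with fixed knots.

    Evaluation is deterministic given the knot set; the basis excludes the
    intercept (pair it with a model intercept).
    """

    df: int
    boundary_knots: tuple
    internal_knots: tuple

    @property
    def knots(self) -> np.ndarray:
        """All knots, sorted: lower boundary, interior, upper boundary."""
        return np.concatenate(
            [[self.boundary_knots[0]], self.internal_knots, [self.boundary_knots[1]]]
        )

    def __call__(self, x) -> np.ndarray:
        """Evaluate the basis at ``x``; returns an (n, df) matrix."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        knots = self.knots
        K = len(knots)
        xiK, xiK1 = knots[-1], knots[-2]

        # the d_k differences carry units of x^2 relative to the linear
        # column; dividing by the squared boundary span keeps the design
        # well conditioned on wide covariate scales (age, eGFR) without
        # changing the spanned function space
        span2 = (knots[-1] - knots[0]) ** 2

        def d(k):
            num = np.maximum(x - knots[k], 0.0) ** 3 - np.maximum(x - xiK, 0.0) ** 3
            return num / (xiK - knots[k])

        cols = [x]
        dK1 = d(K - 2)
        for k in range(K - 2):
            cols.append((d(k) - dK1) / span2)
        return np.column_stack(cols)

    def derivative2(self, x, h: float = 1e-5) -> np.ndarray:
        """Central second difference of each basis column (diagnostic)."""
        return (self(x + h) - 2.0 * self(x) + self(x - h)) / h**2


def natural_cubic_spline_basis(values, df: int, boundary=None):
    """Build a natural cubic spline basis from data and evaluate it.

    Knots are placed at quantiles of ``values``: boundary knots at the
    1st/99th percentiles (unless ``boundary`` is given) and ``df - 1``
    interior knots at equally spaced quantiles between them.

    Parameters
    ----------
    values : array-like
        Observed covariate values used both to place knots and to evaluate.
    df : int
        Number of basis columns (>= 1; df = 1 gives the linear basis).
    boundary : (low, high), optional
        Explicit boundary knots overriding the percentile rule.

    Returns
    -------
    basis : NaturalCubicSplineBasis
    design : ndarray of shape (len(values), df)

    Raises
    ------
    ValueError
        If ``df < 1`` or there are too few distinct values to place knots.
    """
    values = np.asarray(values, dtype=float)
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    n_distinct = len(np.unique(values))
    if n_distinct < df + 1:
        raise ValueError(
            f"need at least {df + 1} distinct values for a df={df} natural "
            f"spline, got {n_distinct}"
        )
    if boundary is None:
        lo, hi = np.percentile(values, [1.0, 99.0])
    else:
        lo, hi = map(float, boundary)
    if not lo < hi:
        raise ValueError(f"degenerate boundary knots ({lo}, {hi})")
    # df-1 interior knots at equally spaced quantiles of the in-boundary mass
    inner = values[(values >= lo) & (values <= hi)]
    probs = np.linspace(0.0, 100.0, df + 1)[1:-1]
    internal = np.quantile(inner, probs / 100.0) if df > 1 else np.array([])
    internal = np.unique(internal)
    if len(internal) != df - 1 or np.any(internal <= lo) or np.any(internal >= hi):
        raise ValueError(
            "could not place distinct interior knots strictly inside the "
            "boundary; too few distinct covariate values"
        )
    basis = NaturalCubicSplineBasis(
        df=df, boundary_knots=(lo, hi), internal_knots=tuple(internal)
    )
    return basis, basis(values)
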