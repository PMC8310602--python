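"""Method-comparison metrics and relative-risk curve construction.

Standardized bias follows the simulation-study convention of scaling the
raw bias by the empirical replicate-to-replicate SD of the estimates,
reported in percent:

    100 * | mean(estimates) - truth | / SD(estimates)

MSE is the plain mean squared deviation from truth.  Random-effect
agreement between two fits of the same dataset is summarized numerically in
Bland-Altman style: correlation, mean difference and 1.96-SD limits of
agreement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "standardized_bias",
    "mse",
    "MethodComparison",
    "compare_methods",
    "rr_curve",
]


def standardized_bias(estimates, truth: float) -> float:
    """Absolute standardized bias in percent: 100 |mean - truth| / SD."""
    estimates = np.asarray(estimates, dtype=float)
    if len(estimates) < 2:
        raise ValueError("standardized bias needs at least 2 replicates")
    sd = float(np.std(estimates, ddof=1))
    if sd == 0.0:
        raise ValueError("undefined metric: zero empirical SD across replicates")
    return 100.0 * abs(float(np.mean(estimates)) - truth) / sd


def mse(estimates, truth: float) -> float:
    """Mean squared error of replicate estimates against the truth."""
    estimates = np.asarray(estimates, dtype=float)
    if len(estimates) == 0:
        raise ValueError("mse needs at least one replicate")
    return float(np.mean((estimates - truth) ** 2))


@dataclass
class MethodComparison:
    """Per-parameter bias/MSE per method plus pairwise and agreement summaries."""

    parameters: list
    methods: list
    bias: dict        # method -> {parameter: %}
    mse: dict         # method -> {parameter: value}
    pairwise_max_bias_diff: dict  # (m1, m2) -> max over parameters of |bias diff|
    agreement: dict   # (m1, m2) -> {correlation, mean_difference, loa_low, loa_high}

    def max_pairwise_bias_difference(self) -> float:
        return max(self.pairwise_max_bias_diff.values()) if self.pairwise_max_bias_diff else 0.0

    def to_rows(self):
        rows = []
        for m in self.methods:
            for p in self.parameters:
                rows.append(
                    {"method": m, "parameter": p,
                     "standardized_bias_pct": self.bias[m][p],
                     "mse": self.mse[m][p]}
                )
        return rows


def _random_effect_agreement(u1, u2):
    u1, u2 = np.asarray(u1, float), np.asarray(u2, float)
    diff = u1 - u2
    sd = float(np.std(diff, ddof=1)) if len(diff) > 1 else 0.0
    if np.std(u1) == 0 or np.std(u2) == 0:
        corr = 1.0 if np.allclose(u1, u2) else np.nan
    else:
        corr = float(np.corrcoef(u1, u2)[0, 1])
    md = float(np.mean(diff))
    return {"correlation": corr, "mean_difference": md,
            "loa_low": md - 1.96 * sd, "loa_high": md + 1.96 * sd}


def compare_methods(fits: dict, truth: dict) -> MethodComparison:
    """Compare estimation methods over a common set of replicate fits.

    Parameters
    ----------
    fits : dict
        method name -> list of :class:`~hlik.model.GLMMResults`, all fitted
        to the same replicate datasets in the same order.
    truth : dict
        ``{"beta": [...], "coefficients": [names], "sigma_ip": s, "sigma_hcf": s}``
        (the ``truth`` payload of the scenario simulators).
    """
    methods = list(fits)
    lengths = {m: len(v) for m, v in fits.items()}
    if len(set(lengths.values())) != 1:
        raise ValueError(f"mismatched replicate sets: {lengths}")
    names = list(truth["coefficients"])
    true_beta = np.asarray(truth["beta"], float)
    params = names + ["sd_ip", "sd_hcf"]
    true_vals = dict(zip(names, true_beta))
    true_vals["sd_ip"] = truth["sigma_ip"]
    true_vals["sd_hcf"] = truth["sigma_hcf"]

    bias, mses = {}, {}
    for m in methods:
        est = {p: [] for p in params}
        for fit in fits[m]:
            for name, value in zip(names, fit.params):
                est[name].append(value)
            est["sd_ip"].append(fit.vc_sd[0])
            est["sd_hcf"].append(fit.vc_sd[1])
        bias[m] = {p: standardized_bias(est[p], true_vals[p]) for p in params}
        mses[m] = {p: mse(est[p], true_vals[p]) for p in params}

    pairwise, agreement = {}, {}
    for i, m1 in enumerate(methods):
        for m2 in methods[i:]:
            key = (m1, m2)
            pairwise[key] = max(abs(bias[m1][p] - bias[m2][p]) for p in params)
            agreement[key] = _random_effect_agreement(
                fits[m1][0].random_effects, fits[m2][0].random_effects
            )
    return MethodComparison(
        parameters=params, methods=methods, bias=bias, mse=mses,
        pairwise_max_bias_diff=pairwise, agreement=agreement,
    )


def rr_curve(fit, var: str, grid, reference: float = 4.0):
    """Relative-risk curve for a spline-modelled covariate.

    log RR(v) = [B(v) - B(ref)] . beta_spline; pointwise 95% bands by the
    delta method from the spline block of the coefficient covariance.
    RR(reference) is exactly 1 with a zero-width band.

    Returns a list of ``(value, rr, lower, upper)`` tuples.
    """
    data = fit.model.data
    if var not in data.spline_bases:
        raise ValueError(f"{var!r} is not a spline term in this fit")
    basis = data.spline_bases[var]
    idx = [i for i, n in enumerate(fit.param_names) if n.startswith(f"{var}.ns")]
    beta_s = fit.params[idx]
    cov = fit.cov_params()
    cov_s = cov[np.ix_(idx, idx)] if cov is not None else None

    grid = np.asarray(grid, dtype=float)
    lo, hi = basis.boundary_knots
    if np.any(grid < lo) or np.any(grid > hi):
        import warnings

        warnings.warn(
            f"grid extends beyond the spline boundary [{lo:.3g}, {hi:.3g}]; "
            "the curve is linear out there", stacklevel=2)
    B = basis(grid) - basis(reference)
    log_rr = B @ beta_s
    if cov_s is not None:
        var_log = np.einsum("ij,jk,ik->i", B, cov_s, B)
        half = 1.96 * np.sqrt(np.clip(var_log, 0.0, None))
    else:
        half = np.zeros_like(log_rr)
    return [
        (float(v), float(np.exp(l)), float(np.exp(l - h)), float(np.exp(l + h)))
        for v, l, h in zip(grid, log_rr, half)
    ]
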