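"""Exponential-family specifications for GLMM likelihood evaluation.

Each family bundles the canonical link, the unit log-density, and the two
ingredients the hierarchical-likelihood machinery needs on the linear
predictor scale: the score d log f / d eta and the curvature weight
-d^2 log f / d eta^2.  All three supported families use their canonical
link, so the score is (y - mu) / phi and the weight is V(mu) / phi.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import special

__all__ = ["FamilySpec", "poisson", "bernoulli", "gaussian", "get_family"]

# Clip linear predictors on the logit scale; expit saturates past ~36 anyway.
_ETA_MAX = 30.0


@dataclass(frozen=True)
class FamilySpec:
    """A one-parameter exponential family with its canonical link.

    Attributes
    ----------
    name : str
        Family tag: ``"poisson"``, ``"bernoulli"`` or ``"gaussian"``.
    link : callable
        g(mu) -> eta.
    inverse_link : callable
        g^{-1}(eta) -> mu.
    dispersion_known : bool
        True when phi is fixed at 1 (poisson, bernoulli).
    """

    name: str
    link: Callable[[np.ndarray], np.ndarray]
    inverse_link: Callable[[np.ndarray], np.ndarray]
    dispersion_known: bool
    _logpdf: Callable[..., np.ndarray] = field(repr=False, default=None)
    _weight: Callable[..., np.ndarray] = field(repr=False, default=None)

    def log_density(self, y: np.ndarray, eta: np.ndarray, phi: float = 1.0) -> np.ndarray:
        """Per-observation log f(y | eta, phi)."""
        return self._logpdf(y, eta, phi)

    def mean(self, eta: np.ndarray) -> np.ndarray:
        return self.inverse_link(eta)

    def score_eta(self, y: np.ndarray, eta: np.ndarray, phi: float = 1.0) -> np.ndarray:
        """d log f / d eta, elementwise; (y - mu)/phi under the canonical link."""
        return (y - self.inverse_link(eta)) / phi

    def weight(self, eta: np.ndarray, phi: float = 1.0) -> np.ndarray:
        """-d^2 log f / d eta^2, elementwise (the GLM working weight)."""
        return self._weight(eta, phi)


def _poisson_logpdf(y, eta, phi):
    # phi is fixed at 1; log f = y*eta - e^eta - log(y!)
    return y * eta - np.exp(eta) - special.gammaln(y + 1.0)


def _poisson_weight(eta, phi):
    return np.exp(eta)


def _bernoulli_logpdf(y, eta, phi):
    eta = np.clip(eta, -_ETA_MAX, _ETA_MAX)
    # y*eta - log(1 + e^eta), numerically stable via log1p(exp(-|eta|))
    return y * eta - (np.logaddexp(0.0, eta))


def _bernoulli_weight(eta, phi):
    mu = special.expit(eta)
    return mu * (1.0 - mu)


def _gaussian_logpdf(y, eta, phi):
    return -0.5 * ((y - eta) ** 2 / phi + np.log(2.0 * np.pi * phi))


def _gaussian_weight(eta, phi):
    return np.full_like(np.asarray(eta, dtype=float), 1.0 / phi)


poisson = FamilySpec(
    name="poisson",
    link=np.log,
    inverse_link=np.exp,
    dispersion_known=True,
    _logpdf=_poisson_logpdf,
    _weight=_poisson_weight,
)

bernoulli = FamilySpec(
    name="bernoulli",
    link=special.logit,
    inverse_link=special.expit,
    dispersion_known=True,
    _logpdf=_bernoulli_logpdf,
    _weight=_bernoulli_weight,
)

gaussian = FamilySpec(
    name="gaussian",
    link=lambda mu: mu,
    inverse_link=lambda eta: eta,
    dispersion_known=False,
    _logpdf=_gaussian_logpdf,
    _weight=_gaussian_weight,
)

_FAMILIES = {"poisson": poisson, "bernoulli": bernoulli, "gaussian": gaussian}


def get_family(tag: str) -> FamilySpec:
    try:
        return _FAMILIES[tag]
    except KeyError:
        raise ValueError(f"unknown family {tag!r}; expected one of {sorted(_FAMILIES)}") from None
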