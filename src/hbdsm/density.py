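"""Linking population density to expected group counts per cell.

The number of groups detected in a surveyed cell is Poisson,
``n_i ~ Pois(lambda_i)``, with

    lambda_i = 2 * w_i * L_i * d_i * g0 / S

where ``w_i`` is the cell's effective strip half-width (km), ``L_i`` its
trackline effort (km), ``d_i`` the population density (individuals km^-2),
``g0`` the probability of detecting a group directly on the trackline, and
``S`` the mean group size (individuals per group).  ``2*w_i*L_i`` is the area
effectively sampled; dividing the individual density by the mean group size
converts it to a group density.

``g0`` is not identifiable from single-platform survey data; it carries an
informative Beta prior whose shape parameters are derived from a published
mean and coefficient of variation (from double-observer experiments).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special

__all__ = ["G0Prior", "g0_prior", "expected_group_count", "count_loglik"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class G0Prior:
    """Beta prior on the trackline detection probability g(0)."""

    mean: float
    cv: float
    a: float
    b: float

    @property
    def concentration(self) -> float:
        return self.a + self.b

    @property
    def sd(self) -> float:
        c = self.concentration
        return float(np.sqrt(self.a * self.b / (c**2 * (c + 1.0))))

    def logpdf(self, g0) -> np.ndarray:
        g0 = np.asarray(g0, dtype=float)
        out = np.where(
            (g0 > 0) & (g0 < 1),
            (self.a - 1.0) * np.log(np.clip(g0, 1e-300, None))
            + (self.b - 1.0) * np.log1p(-np.clip(g0, None, 1.0 - 1e-16))
            - special.betaln(self.a, self.b),
            -np.inf,
        )
        return out


def g0_prior(mu_g0: float, cv_g0: float) -> G0Prior:
    """Build the Beta prior for g(0) from its mean and CV.

    With variance ``v = (mu*cv)^2`` the moment-matched Beta shape parameters
    are ``a = c*mu`` and ``b = c*(1-mu)`` where ``c = mu*(1-mu)/v - 1``.
    """
    if not 0.0 < mu_g0 < 1.0:
        raise ValueError("mu_g0 must lie in (0, 1)")
    if cv_g0 <= 0:
        raise ValueError("cv_g0 must be > 0")
    var = (mu_g0 * cv_g0) ** 2
    if var >= mu_g0 * (1.0 - mu_g0):
        raise ValueError(
            "no Beta distribution has this mean and CV "
            f"(variance {var:.3g} >= mu*(1-mu) = {mu_g0 * (1 - mu_g0):.3g})"
        )
    c = mu_g0 * (1.0 - mu_g0) / var - 1.0
    return G0Prior(mean=mu_g0, cv=cv_g0, a=c * mu_g0, b=c * (1.0 - mu_g0))


def expected_group_count(w, effort_km, density, g0, mean_size):
    """Expected number of groups in a cell: ``2*w*L*d*g0 / mean_size``."""
    w = np.asarray(w, dtype=float)
    effort_km = np.asarray(effort_km, dtype=float)
    density = np.asarray(density, dtype=float)
    mean_size = np.asarray(mean_size, dtype=float)
    if np.any(w < 0) or np.any(effort_km < 0) or np.any(density < 0):
        raise ValueError("w, effort and density must be >= 0")
    if np.any(np.asarray(g0) <= 0) or np.any(np.asarray(g0) > 1):
        raise ValueError("g0 must lie in (0, 1]")
    if np.any(mean_size < 1):
        raise ValueError("mean group size must be >= 1")
    return 2.0 * w * effort_km * density * g0 / mean_size


def count_loglik(n, lam):
    """Poisson log-pmf of observed group counts.

    ``lam = 0`` with ``n = 0`` yields log-probability 0; ``lam = 0`` with
    ``n > 0`` is impossible and returns the most negative representable
    float (with a warning) rather than -inf, so that optimisers and
    samplers receive a finite ordering.
    """
    n = np.asarray(n)
    if np.any(n < 0) or not np.allclose(n, np.round(n)):
        raise ValueError("counts must be non-negative integers")
    n = np.round(np.asarray(n, dtype=float))
    lam = np.asarray(lam, dtype=float)
    if np.any(lam < 0):
        raise ValueError("lambda must be >= 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = n * np.log(lam) - lam - special.gammaln(n + 1.0)
    ll = np.where((lam == 0) & (n == 0), 0.0, ll)
    bad = (lam == 0) & (n > 0)
    if np.any(bad):
        warnings.warn(
            "observed groups in cells with zero expected count; "
            "log-likelihood floored", RuntimeWarning, stacklevel=2,
        )
        ll = np.where(bad, np.finfo(float).min, ll)
    return ll
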