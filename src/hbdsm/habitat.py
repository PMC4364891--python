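"""Habitat response: density as a log-polynomial in dynamic topography.

Population density responds unimodally to absolute dynamic topography (ADT):
both very low ADT (core of upwelling/eddy features) and very high ADT (deep
pycnocline, oligotrophic water) are poor habitat.  Density is modelled as

* 2nd order:  ``d = exp(w0 + w1*z + w2*z^2 + eps2)``
* 3rd order:  ``d = exp(t0 + t1*z + t2*z^2 + t3*z^3 + eps2)``
* average:    ``d = vartheta*d_2nd + (1 - vartheta)*d_3rd``

where ``z = (ADT_cm - reference_mean)/100`` is the rescaled ADT (centering and
shrinking the covariate improves MCMC mixing without changing the model) and
``eps2`` is a per-cell normal residual on the log scale.  With ``w2 < 0`` the
2nd-order curve has an interior maximum at ``z* = -w1/(2*w2)`` — the optimum
habitat in ADT terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "HabitatParams",
    "rescale_adt",
    "unscale_adt",
    "density_poly2",
    "density_poly3",
    "density_average",
    "optimum_adt",
    "shift_reference",
    "HABITAT_FORMS",
]

HABITAT_FORMS = ("poly2", "poly3", "average")


@dataclass
class HabitatParams:
    """Habitat-response coefficients.

    ``omega`` are the 2nd-order coefficients, ``theta`` the 3rd-order ones,
    ``vartheta`` the mixing weight of the model average, ``sigma_eps2`` the
    SD of the per-cell log-scale residual, and ``adt_reference_mean`` the
    centering constant (cm) that defines the rescaled covariate.
    """

    omega: tuple = (0.0, 0.0, 0.0)
    theta: tuple = (0.0, 0.0, 0.0, 0.0)
    vartheta: float = 0.5
    sigma_eps2: float = 0.0
    adt_reference_mean: float = 0.0

    def __post_init__(self) -> None:
        if len(self.omega) != 3 or len(self.theta) != 4:
            raise ValueError("omega must have 3 coefficients and theta 4")
        if not 0.0 <= self.vartheta <= 1.0:
            raise ValueError("vartheta must lie in [0, 1]")
        if self.sigma_eps2 < 0:
            raise ValueError("sigma_eps2 must be >= 0")
        if not np.isfinite(self.adt_reference_mean):
            raise ValueError("adt_reference_mean must be finite")

    def density(self, scaled_adt, form: str, eps2=0.0):
        if form == "poly2":
            return density_poly2(self.omega, scaled_adt, eps2)
        if form == "poly3":
            return density_poly3(self.theta, scaled_adt, eps2)
        if form == "average":
            return density_average(
                self.vartheta,
                density_poly2(self.omega, scaled_adt, eps2),
                density_poly3(self.theta, scaled_adt, eps2),
            )
        raise ValueError(f"unknown habitat form {form!r}; expected one of {HABITAT_FORMS}")


def rescale_adt(adt_cm, reference_mean: float):
    """``z = (ADT - reference_mean) / 100``."""
    return (np.asarray(adt_cm, dtype=float) - reference_mean) / 100.0


def unscale_adt(scaled, reference_mean: float):
    """Inverse of :func:`rescale_adt`."""
    return np.asarray(scaled, dtype=float) * 100.0 + reference_mean


def density_poly2(omega, scaled_adt, eps2=0.0):
    """2nd-order log-polynomial density (individuals km^-2)."""
    w0, w1, w2 = omega
    z = np.asarray(scaled_adt, dtype=float)
    return np.exp(w0 + w1 * z + w2 * z**2 + np.asarray(eps2))


def density_poly3(theta, scaled_adt, eps2=0.0):
    """3rd-order log-polynomial density (individuals km^-2)."""
    t0, t1, t2, t3 = theta
    z = np.asarray(scaled_adt, dtype=float)
    return np.exp(t0 + t1 * z + t2 * z**2 + t3 * z**3 + np.asarray(eps2))


def density_average(vartheta, d_2nd, d_3rd):
    """Convex combination of the two polynomial densities."""
    vartheta = np.asarray(vartheta, dtype=float)
    if np.any(vartheta < 0) or np.any(vartheta > 1):
        raise ValueError("vartheta must lie in [0, 1]")
    return vartheta * np.asarray(d_2nd) + (1.0 - vartheta) * np.asarray(d_3rd)


def optimum_adt(omega, reference_mean: float):
    """Optimum habitat of the 2nd-order model.

    Returns ``(scaled_optimum, optimum_cm, max_density)`` where the scaled
    optimum is the vertex ``-w1/(2*w2)`` of the quadratic exponent.  Requires
    ``w2 < 0`` (an interior maximum).
    """
    w0, w1, w2 = omega
    if w2 >= 0:
        raise ValueError("no interior maximum: omega2 must be < 0")
    z_opt = -w1 / (2.0 * w2)
    return (
        float(z_opt),
        float(unscale_adt(z_opt, reference_mean)),
        float(density_poly2(omega, z_opt)),
    )


def shift_reference(omega, old_mean: float, new_mean: float):
    """Re-express 2nd-order coefficients under a different centering constant.

    Under the new reference mean the covariate is ``z' = z - delta`` with
    ``delta = (new_mean - old_mean)/100``; the curve is unchanged when
    ``w2' = w2``, ``w1' = w1 + 2*w2*delta``, ``w0' = w0 + w1*delta + w2*delta^2``.
    Useful for comparing fits whose centering constants differ (e.g. fitted
    vs. generative truth).
    """
    w0, w1, w2 = omega
    delta = (new_mean - old_mean) / 100.0
    return (
        w0 + w1 * delta + w2 * delta**2,
        w1 + 2.0 * w2 * delta,
        w2,
    )
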