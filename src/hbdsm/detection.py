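"""Half-normal detection model and effective strip half-width (ESW).

Line-transect distance sampling assumes that the probability of detecting a
group declines with its perpendicular distance ``x`` from the trackline.  Here
the detection function is half-normal, ``g(x) = exp(-x^2 / (2 sigma^2))``, and
the effective strip half-width ``w = integral_0^inf g(x) dx = sigma*sqrt(pi/2)``
is modelled log-linearly in Beaufort sea state and group size, with a normal
random effect on the log scale:

* sighting level:  ``w_j = exp(a0 + a1*b_j + a2*c(s_j) + eps0_j)``
* cell level:      ``w_i = exp(a0 + a1*B_i + a2*c_bar + eps1_i)``

where the group-size covariate ``c`` is the raw size for whale-like species
(small Poisson groups) and ``ln(s)`` for dolphin-like species (large,
log-normally distributed groups); ``c_bar`` is the corresponding predicted
mean on the same scale (the Poisson mean, or the log-scale mean
``mu + sigma^2/2`` of the log-normal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DetectionParams",
    "sigma_from_esw",
    "esw_from_sigma",
    "esw_sighting",
    "esw_cell",
    "distance_loglik",
    "WHALE_LIKE",
    "DOLPHIN_LIKE",
]

WHALE_LIKE = "whale_like"
DOLPHIN_LIKE = "dolphin_like"

#: sqrt(2/pi): ratio between the half-normal scale sigma and the ESW w.
_SIGMA_PER_ESW = float(np.sqrt(2.0 / np.pi))
_LOG_2 = float(np.log(2.0))
_LOG_2PI = float(np.log(2.0 * np.pi))


def _check_form(form: str) -> str:
    if form not in (WHALE_LIKE, DOLPHIN_LIKE):
        raise ValueError(
            f"unknown species form {form!r}; expected "
            f"{WHALE_LIKE!r} or {DOLPHIN_LIKE!r}"
        )
    return form


@dataclass
class DetectionParams:
    """Coefficients and residual effects of the strip-width model.

    Attributes
    ----------
    alpha0, alpha1, alpha2
        Intercept, Beaufort slope and group-size slope of log(w).
    sigma_eps0, sigma_eps1
        Standard deviations of the per-sighting and per-cell normal
        random effects on log(w).
    """

    alpha0: float = 0.0
    alpha1: float = 0.0
    alpha2: float = 0.0
    sigma_eps0: float = 0.0
    sigma_eps1: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_eps0 < 0 or self.sigma_eps1 < 0:
            raise ValueError("residual standard deviations must be >= 0")

    @property
    def alpha(self) -> np.ndarray:
        return np.array([self.alpha0, self.alpha1, self.alpha2], dtype=float)


def sigma_from_esw(w):
    """Half-normal scale sigma implied by an effective strip half-width.

    ``sigma = w * sqrt(2/pi)``, the unique relation under which the
    half-normal detection function integrates to ``w``.
    """
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValueError("effective strip half-width must be > 0")
    return w * _SIGMA_PER_ESW


def esw_from_sigma(sigma):
    """Inverse of :func:`sigma_from_esw`: ``w = sigma * sqrt(pi/2)``."""
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be > 0")
    return sigma / _SIGMA_PER_ESW


def _size_covariate(s, form: str):
    _check_form(form)
    s = np.asarray(s, dtype=float)
    if np.any(s < 1):
        raise ValueError("group size must be >= 1")
    return s if form == WHALE_LIKE else np.log(s)


def esw_sighting(params: DetectionParams, beaufort, group_size, form: str,
                 eps0=0.0):
    """Per-sighting effective strip half-width w_j (km).

    Whale-like forms use the raw group size as covariate; dolphin-like
    forms use its natural log.  ``eps0`` is the per-sighting residual on
    the log scale.
    """
    cov = _size_covariate(group_size, form)
    b = np.asarray(beaufort, dtype=float)
    log_w = params.alpha0 + params.alpha1 * b + params.alpha2 * cov + np.asarray(eps0)
    return np.exp(log_w)


def esw_cell(params: DetectionParams, beaufort_weighted, mean_size_covariate,
             form: str, eps1=0.0):
    """Per-cell effective strip half-width w_i (km).

    ``mean_size_covariate`` must already be on the covariate scale of the
    species form: the Poisson mean group size for whale-like species, or the
    log-scale mean ``mu + sigma^2/2`` (= ln of the arithmetic mean) for
    dolphin-like species, so that the shared coefficient alpha2 multiplies a
    quantity on the same scale at sighting and cell level.
    """
    _check_form(form)
    cov = np.asarray(mean_size_covariate, dtype=float)
    if form == WHALE_LIKE and np.any(cov < 1):
        raise ValueError("mean group size must be >= 1 for the whale-like form")
    b = np.asarray(beaufort_weighted, dtype=float)
    log_w = params.alpha0 + params.alpha1 * b + params.alpha2 * cov + np.asarray(eps1)
    return np.exp(log_w)


def distance_loglik(x, sigma):
    """Log-density of perpendicular distances under the half-normal model.

    ``x ~ HalfNormal(sigma)`` with density ``2*phi(x; 0, sigma)`` on x >= 0.
    """
    x = np.asarray(x, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(x < 0):
        raise ValueError("perpendicular distances must be >= 0")
    if np.any(sigma <= 0):
        raise ValueError("sigma must be > 0")
    return _LOG_2 - 0.5 * _LOG_2PI - np.log(sigma) - 0.5 * (x / sigma) ** 2
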