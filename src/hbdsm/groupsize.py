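"""Group-size likelihoods and the predicted mean group size.

Whale-like species travel in very small groups, modelled as Poisson counts
with mean ``lambda_s``.  Dolphin-like species form large, strongly skewed
groups, modelled as log-normal with log-scale location ``mu_s`` and spread
``sigma_s``; their arithmetic mean group size is ``exp(mu_s + sigma_s^2/2)``.
The mean group size serves both as a detectability covariate and as the
divisor converting individual density into expected group counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .detection import WHALE_LIKE, _check_form

__all__ = ["GroupSizeParams", "groupsize_loglik", "mean_group_size"]


@dataclass
class GroupSizeParams:
    """Parameters of the group-size distribution.

    ``lambda_s`` is the Poisson mean (whale-like form); ``mu_s``/``sigma_s``
    the log-normal parameters (dolphin-like form).  Only the fields relevant
    to the chosen form are used.
    """

    lambda_s: float = 1.0
    mu_s: float = 0.0
    sigma_s: float = 0.0

    def __post_init__(self) -> None:
        if self.lambda_s <= 0:
            raise ValueError("lambda_s must be > 0")
        if self.sigma_s < 0:
            raise ValueError("sigma_s must be >= 0")

    def mean(self, form: str) -> float:
        """Arithmetic mean group size under the given species form."""
        _check_form(form)
        if form == WHALE_LIKE:
            return float(self.lambda_s)
        return mean_group_size(self.mu_s, self.sigma_s)

    def covariate_mean(self, form: str) -> float:
        """Mean group size on the detection-covariate scale.

        Raw mean for whale-like; log-scale mean ``mu + sigma^2/2`` for
        dolphin-like (the natural log of the arithmetic mean).
        """
        _check_form(form)
        if form == WHALE_LIKE:
            return float(self.lambda_s)
        return float(self.mu_s + 0.5 * self.sigma_s**2)


def mean_group_size(mu_s: float, sigma_s: float) -> float:
    """Arithmetic mean of a log-normal group-size distribution.

    ``S = exp(mu + sigma^2/2)``; reduces to ``exp(mu)`` as sigma -> 0.
    """
    if sigma_s < 0:
        raise ValueError("sigma_s must be >= 0")
    return float(np.exp(mu_s + 0.5 * sigma_s**2))


def groupsize_loglik(s, params: GroupSizeParams, form: str,
                     zero_truncated: bool = False):
    """Log-density of observed group sizes.

    Poisson pmf for whale-like (integer sizes required), log-normal density
    for dolphin-like.  ``zero_truncated`` conditions the Poisson on s >= 1
    (observed groups necessarily contain at least one animal), renormalising
    the pmf by ``1 - exp(-lambda)``.
    """
    _check_form(form)
    s = np.asarray(s, dtype=float)
    if np.any(s < 1):
        raise ValueError("observed group sizes must be >= 1")
    if form == WHALE_LIKE:
        if not np.allclose(s, np.round(s)):
            raise ValueError("whale-like group sizes must be integers")
        ll = stats.poisson.logpmf(np.round(s).astype(int), params.lambda_s)
        if zero_truncated:
            ll = ll - np.log(-np.expm1(-params.lambda_s))
        return ll
    if params.sigma_s <= 0:
        raise ValueError("sigma_s must be > 0 for the dolphin-like likelihood")
    return stats.lognorm.logpdf(s, s=params.sigma_s, scale=np.exp(params.mu_s))
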