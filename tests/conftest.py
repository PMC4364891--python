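"""Shared fixtures: synthetic surveys and fitted models reused across tests.

Expensive objects (surveys with thousands of detections, MCMC fits) are
session-scoped; every test reads them without refitting.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

from hbdsm import (
    CetaceanDensityModel,
    DetectionParams,
    GroupSizeParams,
    HabitatParams,
    dolphin_like_config,
    simulate_survey,
    whale_like_config,
)

hypothesis_settings.register_profile("repro", derandomize=True, deadline=None)
hypothesis_settings.load_profile("repro")

TRUE_WHALE = dict(alpha0=1.111, alpha1=-0.008098, alpha2=0.02194,
                  lambda_s=1.8, omega0=-6.6, omega1=-16.2, omega2=-46.88,
                  g0=0.921)
TRUE_REFERENCE_MEAN = 66.0


def small_whale_config(seed: int, **overrides):
    """A reduced survey (≈260 surveyed cells, ~60 detections) for replicated fits."""
    kw = dict(lon_min=-125.0, lon_max=-118.0, lat_min=22.0, lat_max=29.0,
              effort_km_total=10_000.0, seed=seed)
    kw.update(overrides)
    return whale_like_config(**kw)


def quick_fit(cells, sightings, **kw):
    """A fit sized for replicated calibration checks (2 chains x 2500)."""
    params = dict(n_iterations=2500, n_burnin=1000, thin=3, n_chains=2,
                  adt_reference_mean=TRUE_REFERENCE_MEAN, seed=0)
    params.update(kw)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return CetaceanDensityModel(**params).fit(cells, sightings)


@pytest.fixture(scope="session")
def whale_survey():
    """Default blue-whale-like synthetic survey (sparse counts, ~150 detections)."""
    return simulate_survey(whale_like_config(seed=1))


@pytest.fixture(scope="session")
def dolphin_survey():
    return simulate_survey(dolphin_like_config(seed=2))


@pytest.fixture(scope="session")
def whale_fit(whale_survey):
    """Whale-form fit at the scale of the headline checks (3 chains x 3000)."""
    sv = whale_survey
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        model = CetaceanDensityModel(
            n_iterations=3000, n_burnin=1000, thin=5, n_chains=3, seed=42,
            adt_reference_mean=TRUE_REFERENCE_MEAN,
        ).fit(sv.cells, sv.sightings)
    return model


@pytest.fixture(scope="session")
def dolphin_fit(dolphin_survey):
    sv = dolphin_survey
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        model = CetaceanDensityModel(
            species_form="dolphin_like", g0_mean=0.970, g0_cv=0.017,
            n_iterations=3000, n_burnin=1000, thin=5, n_chains=3, seed=43,
            adt_reference_mean=TRUE_REFERENCE_MEAN,
        ).fit(sv.cells, sv.sightings)
    return model


@pytest.fixture(scope="session")
def plain_detection_survey():
    """A large survey with constant detection (no covariates, no residuals).

    All perpendicular distances share one half-normal scale, group sizes are
    zero-truncated Poisson(1.8), and the habitat is flat — the regime where
    the generator's marginal distributions have closed forms.
    """
    cfg = whale_like_config(
        lon_min=-120.0, lon_max=-118.33, lat_min=25.0, lat_max=26.67,
        effort_km_total=2000.0,
        true_detection=DetectionParams(alpha0=1.111, alpha1=0.0, alpha2=0.0,
                                       sigma_eps0=0.0, sigma_eps1=0.0),
        true_habitat=HabitatParams(omega=(0.26, 0.0, 0.0),
                                   theta=(0.26, 0.0, 0.0, 0.0),
                                   sigma_eps2=0.0, adt_reference_mean=66.0),
        seed=7,
    )
    return simulate_survey(cfg)
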