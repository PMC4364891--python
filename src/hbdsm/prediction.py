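"""Posterior density surfaces from ADT rasters, and ENSO-stratified maps.

For each raster cell the fitted habitat response is evaluated at every
retained posterior draw (cell residuals excluded by default, since they are
specific to the fitted survey cells) and summarised by the 0.025, 0.5 and
0.975 quantiles across draws.  Yearly surfaces can be annotated with the
July-December mean of a monthly ENSO index and labelled El Nino / La Nina /
neutral.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import xarray as xr

from .habitat import rescale_adt
from .inference import PosteriorResult

__all__ = [
    "predict_surface",
    "enso_yearly_surfaces",
    "july_december_mean",
    "enso_label",
]

logger = logging.getLogger(__name__)

EL_NINO_THRESHOLD = 0.5
LA_NINA_THRESHOLD = -0.5


def _habitat_draw_matrix(result: PosteriorResult, z: np.ndarray,
                         include_residuals: bool,
                         rng: np.random.Generator | None) -> np.ndarray:
    """Density for every (retained draw, raster cell): shape (n_draws, n_cells)."""
    z = z[None, :]
    form = result.habitat_form
    if form in ("poly2", "average"):
        w0 = result.pooled("omega0")[:, None]
        w1 = result.pooled("omega1")[:, None]
        w2 = result.pooled("omega2")[:, None]
        log_d2 = w0 + w1 * z + w2 * z ** 2
    if form in ("poly3", "average"):
        t = [result.pooled(f"theta{i}")[:, None] for i in range(4)]
        log_d3 = t[0] + t[1] * z + t[2] * z ** 2 + t[3] * z ** 3
    if form == "poly2":
        d = np.exp(log_d2)
    elif form == "poly3":
        d = np.exp(log_d3)
    else:
        vt = result.pooled("vartheta")[:, None]
        d = vt * np.exp(log_d2) + (1.0 - vt) * np.exp(log_d3)
    if include_residuals:
        if "sigma_eps2" not in result.draws:
            raise ValueError("fit has no habitat residual to include")
        sig = result.pooled("sigma_eps2")[:, None]
        rng = rng or np.random.default_rng((result.config.seed or 0) + 999)
        d = d * np.exp(rng.normal(0.0, 1.0, size=d.shape) * sig)
    return d


def predict_surface(result: PosteriorResult, adt, reference_mean: float | None = None,
                    include_residuals: bool = False,
                    rng: np.random.Generator | None = None) -> xr.Dataset:
    """Quantile maps of predicted density for an ADT raster (cm).

    Returns a Dataset with variables ``q025``, ``median``, ``q975``
    (individuals km^-2) and a boolean ``extrapolated`` flag marking raster
    cells whose ADT lies outside the range spanned by the fitted survey
    cells.  Per-cell habitat residuals are excluded unless
    ``include_residuals`` is set (wider, observation-level bands).
    """
    if not isinstance(adt, xr.DataArray):
        adt = xr.DataArray(np.asarray(adt, dtype=float))
    ref = result.adt_reference_mean if reference_mean is None else reference_mean
    flat = np.asarray(adt, dtype=float).ravel()
    z = np.asarray(rescale_adt(flat, ref))
    d = _habitat_draw_matrix(result, z, include_residuals, rng)
    q = np.nanquantile(d, [0.025, 0.5, 0.975], axis=0)
    lo, hi = result.adt_fitted_range
    extrap = (flat < lo) | (flat > hi)
    if extrap.any():
        logger.warning("%d raster cell(s) outside the fitted ADT range "
                       "[%.1f, %.1f] cm: predictions are extrapolations",
                       int(extrap.sum()), lo, hi)
    shape = adt.shape
    ds = xr.Dataset(
        {
            "q025": (adt.dims, q[0].reshape(shape)),
            "median": (adt.dims, q[1].reshape(shape)),
            "q975": (adt.dims, q[2].reshape(shape)),
            "extrapolated": (adt.dims, extrap.reshape(shape)),
        },
        coords=adt.coords,
        attrs={
            "units": "individuals km-2",
            "species_form": result.species_form,
            "habitat_form": result.habitat_form,
            "adt_reference_mean_cm": ref,
        },
    )
    return ds


def july_december_mean(mei: pd.Series, year: int) -> float:
    """Mean of the monthly index over July-December of one year (NaN if absent)."""
    idx = mei.index
    if not isinstance(idx, pd.PeriodIndex):
        idx = pd.PeriodIndex(pd.to_datetime(idx), freq="M")
    mask = (idx.year == year) & (idx.month >= 7)
    if not mask.any():
        return float("nan")
    return float(np.asarray(mei)[mask].mean())


def enso_label(mei_mean: float) -> str:
    """Categorical ENSO state from a July-December index mean."""
    if np.isnan(mei_mean):
        return "unknown"
    if mei_mean >= EL_NINO_THRESHOLD:
        return "el_nino"
    if mei_mean <= LA_NINA_THRESHOLD:
        return "la_nina"
    return "neutral"


def enso_yearly_surfaces(result: PosteriorResult, adt_by_year: dict,
                         mei: pd.Series | None = None,
                         include_residuals: bool = False) -> dict:
    """One density surface per year, annotated with its ENSO state.

    ``adt_by_year`` maps year -> ADT raster (the July-December mean field, or
    the surveyed-months mean where effort exists).  Years without index
    coverage get label "unknown" with a logged warning; the index is
    annotation only and never alters the surface.
    """
    out = {}
    for year, adt in sorted(adt_by_year.items()):
        surf = predict_surface(result, adt, include_residuals=include_residuals)
        m = july_december_mean(mei, year) if mei is not None else float("nan")
        if np.isnan(m):
            logger.warning("no ENSO index values for Jul-Dec %d; label unknown", year)
        surf.attrs["year"] = int(year)
        surf.attrs["mei_jul_dec"] = m
        surf.attrs["enso_label"] = enso_label(m)
        out[int(year)] = surf
    return out
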