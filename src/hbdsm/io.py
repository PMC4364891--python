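"""Reading and writing the package's tables, rasters and run metadata.

Tables (effort segments, sightings, model-ready cells, posterior draws and
summaries) are delimited text (CSV).  ADT rasters and density surfaces are
NetCDF (classic format via xarray's scipy backend) with lon/lat/week
coordinates.  Run metadata (configuration, seed, convergence flags) is YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

__all__ = [
    "read_table", "write_table",
    "read_adt", "write_adt", "write_surface",
    "read_posterior_draws", "write_posterior_draws",
    "read_metadata", "write_metadata",
]

_DATE_COLUMNS = ("date",)


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in _DATE_COLUMNS:
        if col in df.columns:
            df[col] = pd.to_datetime(df[col])
    return df


def write_adt(field: xr.DataArray, path) -> Path:
    path = Path(path)
    field.to_dataset(name=field.name or "adt").to_netcdf(path, engine="scipy")
    return path


def read_adt(path, var: str = "adt") -> xr.DataArray:
    with xr.open_dataset(path, engine="scipy") as ds:
        field = ds[var].load()
    return field


def write_surface(surface: xr.Dataset, path) -> Path:
    path = Path(path)
    enc = surface.copy()
    # NetCDF3 has no booleans
    if "extrapolated" in enc:
        enc["extrapolated"] = enc["extrapolated"].astype("i1")
    enc.to_netcdf(path, engine="scipy")
    return path


def write_posterior_draws(result, path) -> Path:
    """Flatten posterior draws to a long-format CSV (chain, draw, parameter columns)."""
    n_chains, n_draws = next(iter(result.draws.values())).shape
    out = {"chain": np.repeat(np.arange(n_chains), n_draws),
           "draw": np.tile(np.arange(n_draws), n_chains)}
    for name, v in result.draws.items():
        out[name] = np.asarray(v).ravel()
    return write_table(pd.DataFrame(out), path)


def read_posterior_draws(path) -> dict:
    df = pd.read_csv(path)
    chains = np.sort(df["chain"].unique())
    params = [c for c in df.columns if c not in ("chain", "draw")]
    return {
        p: np.stack([df.loc[df["chain"] == c, p].to_numpy() for c in chains])
        for p in params
    }


def write_metadata(meta: dict, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return path


def read_metadata(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
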