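"""Gridding of line-transect effort and sightings onto the ADT raster.

Raw survey data arrive as effort segments (a dated straight trackline piece
with a Beaufort sea state) and sightings (a dated position with perpendicular
distance, group size and Beaufort).  The likelihood consumes per-cell-year
records: trackline effort ``L_i`` (km), effort-weighted Beaufort ``B_i``,
group count ``n_i`` and the weekly ADT value ``ADT_i`` matched to the effort.

Cells are the raster's 1/3-degree boxes, indexed with half-open intervals
``[lon, lon + size) x [lat, lat + size)`` so every position belongs to exactly
one cell.  Segments are split at cell boundaries by linear interpolation in
lon/lat; lengths are haversine distances, so total effort is conserved.

Table schemas (delimited text, one row per record)
--------------------------------------------------
segments:  date, lon_start, lat_start, lon_end, lat_end, beaufort
sightings: date, lon, lat, distance_km, group_size, beaufort
cells:     lon_idx, lat_idx, lon, lat, year, effort_km, beaufort,
           n_groups, adt_cm
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "GridSpec",
    "EARTH_RADIUS_KM",
    "haversine_km",
    "week_start",
    "split_effort",
    "grid_effort",
    "assign_sightings",
    "match_adt",
    "build_cells",
]

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0

SEGMENT_COLUMNS = ["date", "lon_start", "lat_start", "lon_end", "lat_end", "beaufort"]
SIGHTING_COLUMNS = ["date", "lon", "lat", "distance_km", "group_size", "beaufort"]
CELL_COLUMNS = [
    "lon_idx", "lat_idx", "lon", "lat", "year",
    "effort_km", "beaufort", "n_groups", "adt_cm",
]


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in degrees."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def week_start(dates):
    """Monday of the ISO week containing each date (scalar or array-like)."""
    d = pd.to_datetime(dates)
    if isinstance(d, pd.Timestamp):
        return (d - pd.Timedelta(days=d.dayofweek)).normalize()
    d = pd.DatetimeIndex(d)
    return (d - pd.to_timedelta(d.dayofweek, unit="D")).normalize()


@dataclass(frozen=True)
class GridSpec:
    """Regular lon/lat grid of square cells, half-open on the upper edges."""

    lon_min: float
    lat_min: float
    n_lon: int
    n_lat: int
    cell_size: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if self.n_lon < 1 or self.n_lat < 1:
            raise ValueError("grid extent is empty")

    @property
    def lon_max(self) -> float:
        return self.lon_min + self.n_lon * self.cell_size

    @property
    def lat_max(self) -> float:
        return self.lat_min + self.n_lat * self.cell_size

    @property
    def lon_centers(self) -> np.ndarray:
        return self.lon_min + (np.arange(self.n_lon) + 0.5) * self.cell_size

    @property
    def lat_centers(self) -> np.ndarray:
        return self.lat_min + (np.arange(self.n_lat) + 0.5) * self.cell_size

    @classmethod
    def from_extent(cls, lon_min, lon_max, lat_min, lat_max,
                    cell_size=1.0 / 3.0) -> "GridSpec":
        if lon_max <= lon_min or lat_max <= lat_min:
            raise ValueError("grid extent is empty")
        n_lon = int(np.ceil((lon_max - lon_min) / cell_size - 1e-9))
        n_lat = int(np.ceil((lat_max - lat_min) / cell_size - 1e-9))
        return cls(lon_min, lat_min, n_lon, n_lat, cell_size)

    @classmethod
    def from_field(cls, field: xr.DataArray) -> "GridSpec":
        """Recover the grid from an ADT raster's lon/lat center coordinates."""
        lon = np.asarray(field["lon"])
        lat = np.asarray(field["lat"])
        size = float(np.round(np.diff(lon).mean(), 12)) if lon.size > 1 else 1.0 / 3.0
        return cls(float(lon[0] - size / 2), float(lat[0] - size / 2),
                   lon.size, lat.size, size)

    def cell_index(self, lon, lat):
        """(lon_idx, lat_idx, inside) with half-open boundary convention."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        # snap within ~1e-9 cell widths so edges that are exact in decimal
        # arithmetic land in the upper (half-open) cell despite binary rounding
        ix = np.floor((lon - self.lon_min) / self.cell_size + 1e-9).astype(int)
        iy = np.floor((lat - self.lat_min) / self.cell_size + 1e-9).astype(int)
        inside = (ix >= 0) & (ix < self.n_lon) & (iy >= 0) & (iy < self.n_lat)
        return ix, iy, inside


def split_effort(segments: pd.DataFrame, grid: GridSpec) -> pd.DataFrame:
    """Split each effort segment at cell boundaries.

    Returns one row per sub-piece with columns lon_idx, lat_idx, year, week,
    length_km, beaufort and the piece end-points.  Pieces outside the grid are
    dropped with a warning.  Total in-grid length is conserved.
    """
    pieces = []
    for row in segments.itertuples(index=False):
        lon0, lat0 = float(row.lon_start), float(row.lat_start)
        lon1, lat1 = float(row.lon_end), float(row.lat_end)
        if not all(np.isfinite([lon0, lat0, lon1, lat1])):
            raise ValueError("segment coordinates must be finite")
        # boundary-crossing parameters along the segment, in (0, 1)
        ts = [0.0, 1.0]
        for lo, hi, vmin, size in ((lon0, lon1, grid.lon_min, grid.cell_size),
                                   (lat0, lat1, grid.lat_min, grid.cell_size)):
            if hi != lo:
                k0 = int(np.floor((min(lo, hi) - vmin) / size)) + 1
                k1 = int(np.floor((max(lo, hi) - vmin) / size))
                for k in range(k0, k1 + 1):
                    t = (vmin + k * size - lo) / (hi - lo)
                    if 0.0 < t < 1.0:
                        ts.append(t)
        ts = np.unique(ts)
        date = pd.Timestamp(row.date)
        for ta, tb in zip(ts[:-1], ts[1:]):
            tm = 0.5 * (ta + tb)
            mx = lon0 + tm * (lon1 - lon0)
            my = lat0 + tm * (lat1 - lat0)
            ix, iy, inside = grid.cell_index(mx, my)
            ax, ay = lon0 + ta * (lon1 - lon0), lat0 + ta * (lat1 - lat0)
            bx, by = lon0 + tb * (lon1 - lon0), lat0 + tb * (lat1 - lat0)
            length = float(haversine_km(ax, ay, bx, by))
            if length == 0.0:
                continue
            if not inside:
                logger.warning("effort piece of %.2f km outside grid dropped", length)
                continue
            pieces.append((int(ix), int(iy), date.year, week_start(date),
                           length, int(row.beaufort), ax, ay, bx, by))
    return pd.DataFrame(
        pieces,
        columns=["lon_idx", "lat_idx", "year", "week", "length_km", "beaufort",
                 "lon_start", "lat_start", "lon_end", "lat_end"],
    )


def grid_effort(segments: pd.DataFrame, grid: GridSpec,
                pieces: pd.DataFrame | None = None) -> pd.DataFrame:
    """Aggregate effort into cell-year records: ``L_i`` and effort-weighted ``B_i``."""
    if pieces is None:
        pieces = split_effort(segments, grid)
    if pieces.empty:
        return pd.DataFrame(columns=["lon_idx", "lat_idx", "year", "lon", "lat",
                                     "effort_km", "beaufort"])
    g = pieces.groupby(["lon_idx", "lat_idx", "year"])
    out = g.agg(effort_km=("length_km", "sum")).reset_index()
    bw = g.apply(
        lambda t: np.average(t["beaufort"], weights=t["length_km"]),
        include_groups=False,
    )
    out["beaufort"] = bw.values
    out["lon"] = grid.lon_centers[out["lon_idx"]]
    out["lat"] = grid.lat_centers[out["lat_idx"]]
    return out[["lon_idx", "lat_idx", "lon", "lat", "year", "effort_km", "beaufort"]]


def assign_sightings(sightings: pd.DataFrame, grid: GridSpec) -> pd.DataFrame:
    """Count groups per cell-year; out-of-grid sightings are excluded with a warning."""
    if sightings.empty:
        return pd.DataFrame(columns=["lon_idx", "lat_idx", "year", "n_groups"])
    ix, iy, inside = grid.cell_index(sightings["lon"], sightings["lat"])
    n_out = int((~inside).sum())
    if n_out:
        logger.warning("%d sighting(s) outside the grid excluded", n_out)
    year = pd.to_datetime(sightings["date"]).dt.year.to_numpy()
    df = pd.DataFrame({"lon_idx": ix, "lat_idx": iy, "year": year})[inside]
    return (df.groupby(["lon_idx", "lat_idx", "year"]).size()
            .rename("n_groups").reset_index())


def match_adt(cells: pd.DataFrame, field: xr.DataArray,
              pieces: pd.DataFrame) -> pd.DataFrame:
    """Attach the effort-weighted weekly ADT value to each cell-year.

    For a cell-year whose effort falls in a single week this is that week's
    raster value verbatim; effort spread over several weeks yields the
    effort-weighted mean of the weekly values.  Raises if any surveyed
    cell-week has no ADT coverage.
    """
    week_index = {pd.Timestamp(w): k for k, w in
                  enumerate(pd.to_datetime(np.asarray(field["week"])))}
    values = np.asarray(field.transpose("week", "lat", "lon"))
    missing = []
    adt = {}
    for key, t in pieces.groupby(["lon_idx", "lat_idx", "year"]):
        wk = [week_index.get(pd.Timestamp(w)) for w in t["week"]]
        if any(k is None for k in wk):
            missing.append(key)
            continue
        v = values[np.array(wk), t["lat_idx"].to_numpy(), t["lon_idx"].to_numpy()]
        adt[key] = float(np.average(v, weights=t["length_km"]))
    if missing:
        raise ValueError(
            f"no ADT coverage for surveyed cell-week(s) of cells: {missing}"
        )
    out = cells.copy()
    out["adt_cm"] = [
        adt.get((r.lon_idx, r.lat_idx, r.year), np.nan)
        for r in out.itertuples(index=False)
    ]
    if out["adt_cm"].isna().any():
        raise ValueError("cells without effort pieces cannot be matched to ADT")
    return out


def build_cells(segments: pd.DataFrame, sightings: pd.DataFrame,
                field: xr.DataArray, grid: GridSpec | None = None) -> pd.DataFrame:
    """Full gridding pipeline: segments + sightings + ADT raster -> model-ready cells."""
    if grid is None:
        grid = GridSpec.from_field(field)
    pieces = split_effort(segments, grid)
    cells = grid_effort(segments, grid, pieces=pieces)
    cells = match_adt(cells, field, pieces)
    counts = assign_sightings(sightings, grid)
    cells = cells.merge(counts, on=["lon_idx", "lat_idx", "year"], how="left")
    cells["n_groups"] = cells["n_groups"].fillna(0).astype(int)
    lost = len(sightings) - int(cells["n_groups"].sum())
    if lost:
        logger.warning("%d sighting(s) fell in cells without recorded effort "
                       "or outside the grid", lost)
    return cells[CELL_COLUMNS]
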