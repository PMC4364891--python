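"""Gridding of effort segments and sightings onto the raster cells."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from hbdsm import (
    GridSpec,
    assign_sightings,
    build_cells,
    grid_effort,
    haversine_km,
    match_adt,
    split_effort,
)
from hbdsm.gridding import week_start

GRID = GridSpec.from_extent(-120.0, -118.0, 25.0, 27.0)  # 6 x 6 cells of 1/3 deg


def seg(date, lon0, lat0, lon1, lat1, beaufort):
    return dict(date=pd.Timestamp(date), lon_start=lon0, lat_start=lat0,
                lon_end=lon1, lat_end=lat1, beaufort=beaufort)


def segments_df(rows):
    return pd.DataFrame(rows)


class TestGridSpec:
    def test_half_open_boundaries(self):
        # a point exactly on an interior cell edge belongs to the upper cell
        ix, iy, inside = GRID.cell_index(-120.0 + 1 / 3, 25.0 + 2 / 3)
        assert (ix, iy) == (1, 2)
        assert inside

    def test_empty_extent_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            GridSpec.from_extent(-120.0, -120.0, 25.0, 27.0)

    def test_round_trip_through_field_coordinates(self):
        field = xr.DataArray(
            np.zeros((1, GRID.n_lat, GRID.n_lon)),
            dims=("week", "lat", "lon"),
            coords={"week": [pd.Timestamp("2000-07-03")],
                    "lat": GRID.lat_centers, "lon": GRID.lon_centers})
        g2 = GridSpec.from_field(field)
        assert g2.n_lon == GRID.n_lon and g2.n_lat == GRID.n_lat
        assert g2.lon_min == pytest.approx(GRID.lon_min)
        assert g2.cell_size == pytest.approx(GRID.cell_size)


class TestEffortGridding:
    def test_single_segment_inside_one_cell(self):
        # a segment fully inside a cell keeps its length and Beaufort
        s = segments_df([seg("2000-07-05", -119.95, 25.05, -119.85, 25.05, 3)])
        length = float(haversine_km(-119.95, 25.05, -119.85, 25.05))
        cells = grid_effort(s, GRID)
        assert len(cells) == 1
        assert cells.iloc[0]["effort_km"] == pytest.approx(length, rel=1e-12)
        assert cells.iloc[0]["beaufort"] == 3

    def test_effort_weighted_beaufort(self):
        # 5 km at Beaufort 2 plus 15 km at Beaufort 4 -> B = 3.5
        lat = 25.05
        lon0 = -119.99
        km_per_deg = float(haversine_km(lon0, lat, lon0 + 0.01, lat)) / 0.01
        d5, d15 = 5.0 / km_per_deg, 15.0 / km_per_deg
        s = segments_df([
            seg("2000-07-05", lon0, lat, lon0 + d5, lat, 2),
            seg("2000-07-05", lon0 + d5, lat, lon0 + d5 + d15, lat, 4),
        ])
        cells = grid_effort(s, GRID)
        assert len(cells) == 1
        # haversine lengths deviate from the planar 5/15 split by O(1e-8)
        assert cells.iloc[0]["beaufort"] == pytest.approx(3.5, abs=1e-6)

    def test_total_length_conserved_across_cell_boundaries(self):
        rng = np.random.default_rng(3)
        rows = []
        for k in range(40):
            lon0, lat0 = rng.uniform(-119.9, -118.1), rng.uniform(25.1, 26.9)
            lon1 = lon0 + rng.uniform(-0.4, 0.4)
            lat1 = lat0 + rng.uniform(-0.4, 0.4)
            rows.append(seg("2000-07-05", lon0, lat0,
                            np.clip(lon1, -119.99, -118.01),
                            np.clip(lat1, 25.01, 26.99), int(rng.integers(6))))
        s = segments_df(rows)
        total_in = float(haversine_km(s.lon_start, s.lat_start,
                                      s.lon_end, s.lat_end).sum())
        cells = grid_effort(s, GRID)
        assert cells["effort_km"].sum() == pytest.approx(total_in, rel=1e-6)

    def test_splitting_is_idempotent(self):
        # pieces already inside single cells re-split into themselves
        s = segments_df([seg("2000-07-05", -119.9, 25.1, -118.2, 26.8, 2)])
        pieces = split_effort(s, GRID)
        assert len(pieces) > 1
        again = split_effort(
            pieces.rename(columns={"length_km": "ignored"}).assign(
                date=pd.Timestamp("2000-07-05")),
            GRID)
        assert len(again) == len(pieces)
        np.testing.assert_allclose(np.sort(again["length_km"]),
                                   np.sort(pieces["length_km"]), rtol=1e-9)

    def test_zero_length_segment_contributes_nothing(self):
        s = segments_df([seg("2000-07-05", -119.5, 25.5, -119.5, 25.5, 1)])
        assert grid_effort(s, GRID).empty


class TestSightingAssignment:
    def _sightings(self, rows):
        return pd.DataFrame(rows, columns=["date", "lon", "lat"])

    def test_empty_table(self):
        counts = assign_sightings(self._sightings([]), GRID)
        assert counts.empty

    def test_three_in_one_cell(self):
        rows = [(pd.Timestamp("2000-07-05"), -119.9, 25.1)] * 3
        counts = assign_sightings(self._sightings(rows), GRID)
        assert len(counts) == 1
        assert counts.iloc[0]["n_groups"] == 3

    def test_boundary_sighting_assigned_once(self):
        rows = [(pd.Timestamp("2000-07-05"), -120.0 + 1 / 3, 25.0 + 1 / 3)]
        counts = assign_sightings(self._sightings(rows), GRID)
        assert counts["n_groups"].sum() == 1

    def test_outside_grid_excluded_with_warning(self, caplog):
        rows = [(pd.Timestamp("2000-07-05"), -119.9, 25.1),
                (pd.Timestamp("2000-07-05"), -90.0, 0.0)]
        with caplog.at_level("WARNING", logger="hbdsm.gridding"):
            counts = assign_sightings(self._sightings(rows), GRID)
        assert counts["n_groups"].sum() == 1
        assert "outside the grid" in caplog.text


class TestAdtMatching:
    def _field(self, values_by_week):
        weeks = list(values_by_week)
        data = np.stack([np.full((GRID.n_lat, GRID.n_lon), v)
                         for v in values_by_week.values()])
        return xr.DataArray(data, dims=("week", "lat", "lon"),
                            coords={"week": pd.to_datetime(weeks),
                                    "lat": GRID.lat_centers,
                                    "lon": GRID.lon_centers})

    def test_single_week_value_verbatim(self):
        s = segments_df([seg("2000-07-05", -119.9, 25.1, -119.85, 25.1, 2)])
        pieces = split_effort(s, GRID)
        cells = grid_effort(s, GRID, pieces=pieces)
        field = self._field({"2000-07-03": 63.0})
        out = match_adt(cells, field, pieces)
        assert out.iloc[0]["adt_cm"] == pytest.approx(63.0, abs=1e-12)

    def test_effort_weighted_weekly_mean(self):
        # 5 km in a 60-cm week and 15 km in an 80-cm week -> 75 cm
        lat = 25.05
        lon0 = -119.99
        km_per_deg = float(haversine_km(lon0, lat, lon0 + 0.01, lat)) / 0.01
        d5, d15 = 5.0 / km_per_deg, 15.0 / km_per_deg
        s = segments_df([
            seg("2000-07-05", lon0, lat, lon0 + d5, lat, 2),
            seg("2000-07-12", lon0 + d5, lat, lon0 + d5 + d15, lat, 2),
        ])
        pieces = split_effort(s, GRID)
        cells = grid_effort(s, GRID, pieces=pieces)
        field = self._field({"2000-07-03": 60.0, "2000-07-10": 80.0})
        out = match_adt(cells, field, pieces)
        assert out.iloc[0]["adt_cm"] == pytest.approx(75.0, abs=1e-6)

    def test_constant_field_returns_constant(self):
        s = segments_df([seg("2000-07-05", -119.9, 25.1, -118.2, 26.8, 2)])
        pieces = split_effort(s, GRID)
        cells = grid_effort(s, GRID, pieces=pieces)
        out = match_adt(cells, self._field({"2000-07-03": 57.5}), pieces)
        np.testing.assert_allclose(out["adt_cm"], 57.5, rtol=1e-12)

    def test_missing_week_coverage_is_an_error(self):
        s = segments_df([seg("2000-09-05", -119.9, 25.1, -119.85, 25.1, 2)])
        pieces = split_effort(s, GRID)
        cells = grid_effort(s, GRID, pieces=pieces)
        with pytest.raises(ValueError, match="no ADT coverage"):
            match_adt(cells, self._field({"2000-07-03": 60.0}), pieces)


class TestPartitionProperties:
    def test_every_sighting_and_km_counted_once(self, whale_survey):
        sv = whale_survey
        cells = build_cells(sv.segments, sv.sightings, sv.field,
                            sv.config.grid)
        assert cells["n_groups"].sum() == len(sv.sightings)
        total = float(haversine_km(sv.segments.lon_start, sv.segments.lat_start,
                                   sv.segments.lon_end, sv.segments.lat_end).sum())
        assert cells["effort_km"].sum() == pytest.approx(total, rel=1e-6)

    def test_week_start_is_monday(self):
        w = week_start(pd.Timestamp("2000-07-06"))  # a Thursday
        assert w == pd.Timestamp("2000-07-03")
        arr = week_start(pd.to_datetime(["2000-07-06", "2000-07-10"]))
        assert list(arr) == [pd.Timestamp("2000-07-03"),
                             pd.Timestamp("2000-07-10")]
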