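"""Synthetic ADT fields, zig-zag surveys and the ENSO index generator."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hbdsm import (
    DetectionParams,
    HabitatParams,
    expected_group_count,
    haversine_km,
    simulate_adt_field,
    simulate_mei,
    simulate_survey,
    whale_like_config,
)
from hbdsm.prediction import july_december_mean


def tiny_config(seed, effort=400.0, omega0=0.26, **overrides):
    """A 5x5-cell survey with flat habitat, for cheap replicated runs."""
    kw = dict(
        lon_min=-120.0, lon_max=-120.0 + 5 / 3, lat_min=25.0,
        lat_max=25.0 + 5 / 3, effort_km_total=effort,
        weeks=pd.date_range("2000-07-03", periods=4, freq="7D"),
        true_detection=DetectionParams(alpha0=1.111, alpha1=0.0, alpha2=0.0,
                                       sigma_eps0=0.0, sigma_eps1=0.0),
        true_habitat=HabitatParams(omega=(omega0, 0.0, 0.0),
                                   theta=(omega0, 0.0, 0.0, 0.0),
                                   sigma_eps2=0.0, adt_reference_mean=66.0),
        seed=seed,
    )
    kw.update(overrides)
    return whale_like_config(**kw)


class TestAdtField:
    def test_deterministic_for_fixed_seed(self):
        cfg = tiny_config(11)
        a = simulate_adt_field(cfg)
        b = simulate_adt_field(cfg)
        assert a.identical(b)

    def test_shape_and_range(self):
        cfg = whale_like_config(
            lon_min=-120.0, lon_max=-120.0 + 10 / 3,
            lat_min=25.0, lat_max=25.0 + 10 / 3,
            weeks=pd.date_range("2000-07-03", periods=4, freq="7D"), seed=1)
        field = simulate_adt_field(cfg)
        assert field.shape == (4, 10, 10)
        lo, hi = cfg.adt_range
        assert float(field.min()) >= lo and float(field.max()) <= hi

    def test_zero_spatial_amplitude_is_constant_in_space(self):
        cfg = tiny_config(3, adt_spatial_amplitude=0.0)
        field = simulate_adt_field(cfg)
        per_week_spread = field.max(dim=("lat", "lon")) - field.min(dim=("lat", "lon"))
        assert float(per_week_spread.max()) == 0.0

    def test_empty_extent_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            whale_like_config(lon_min=-120.0, lon_max=-120.0)


class TestSurveyGeneration:
    def test_deterministic_for_fixed_seed(self):
        a = simulate_survey(tiny_config(9))
        b = simulate_survey(tiny_config(9))
        pd.testing.assert_frame_equal(a.segments, b.segments)
        pd.testing.assert_frame_equal(a.sightings, b.sightings)
        pd.testing.assert_frame_equal(a.cells, b.cells)

    def test_total_effort_matches_configuration(self):
        sv = simulate_survey(tiny_config(4, effort=600.0))
        total = float(haversine_km(sv.segments.lon_start, sv.segments.lat_start,
                                   sv.segments.lon_end, sv.segments.lat_end).sum())
        assert total == pytest.approx(600.0, rel=1e-3)
        assert sv.cells["effort_km"].sum() == pytest.approx(total, rel=1e-6)

    def test_zero_density_gives_zero_sightings(self):
        sv = simulate_survey(tiny_config(5, omega0=-40.0))
        assert len(sv.sightings) == 0
        assert (sv.cells["n_groups"] == 0).all()

    def test_doubling_effort_doubles_mean_sighting_count(self):
        # oracle: the expected count is linear in trackline effort
        n1, n2 = [], []
        for r in range(200):
            n1.append(len(simulate_survey(tiny_config(1000 + r,
                                                      effort=250.0)).sightings))
            n2.append(len(simulate_survey(tiny_config(3000 + r,
                                                      effort=500.0)).sightings))
        n1, n2 = np.array(n1, float), np.array(n2, float)
        diff = n2.mean() - 2 * n1.mean()
        se = np.sqrt(n2.var(ddof=1) / 200 + 4 * n1.var(ddof=1) / 200)
        assert abs(diff) < 3 * se

    def test_emitted_truth_is_internally_consistent(self):
        # lambda_n recomputes exactly from the emitted latent values
        sv = simulate_survey(tiny_config(6))
        cfg = sv.config
        t = sv.cell_truth
        lam = expected_group_count(
            t["true_esw_km"], sv.cells["effort_km"], t["true_density"],
            cfg.true_g0, cfg.true_groupsize.mean(cfg.species_form))
        np.testing.assert_allclose(lam, t["lambda_n"], rtol=1e-10)

    def test_sightings_lie_in_surveyed_cells(self, whale_survey):
        sv = whale_survey
        grid = sv.config.grid
        ix, iy, inside = grid.cell_index(sv.sightings["lon"], sv.sightings["lat"])
        assert inside.all()
        surveyed = set(zip(sv.cells["lon_idx"], sv.cells["lat_idx"]))
        assert set(zip(ix, iy)) <= surveyed

    def test_perpendicular_distances_follow_half_normal(
            self, plain_detection_survey):
        # constant covariates: all distances share one half-normal scale
        sv = plain_detection_survey
        x = sv.sightings["distance_km"].to_numpy()
        sigma = np.exp(1.111) * np.sqrt(2 / np.pi)
        assert len(x) >= 5000
        p = stats.kstest(x, stats.halfnorm(scale=sigma).cdf).pvalue
        assert p > 0.01

    def test_beaufort_range_and_probabilities(self, whale_survey):
        b = whale_survey.segments["beaufort"]
        assert b.between(0, 5).all()


class TestMeiGenerator:
    def test_forced_constant_level(self):
        years = [1995, 1996]
        mei = simulate_mei(years, seed=0, monthly_sd=0.0,
                           year_means={1995: 2.0, 1996: 2.0})
        for y in years:
            assert july_december_mean(mei, y) == pytest.approx(2.0)

    def test_deterministic_for_fixed_seed(self):
        a = simulate_mei([2000, 2001], seed=4)
        b = simulate_mei([2000, 2001], seed=4)
        pd.testing.assert_series_equal(a, b)

    def test_alternating_series_averages_to_zero(self):
        idx = pd.period_range("1999-01", "1999-12", freq="M")
        mei = pd.Series([1.0 if k % 2 == 0 else -1.0 for k in range(12)],
                        index=idx)
        assert july_december_mean(mei, 1999) == pytest.approx(0.0)

    def test_empty_year_list_rejected(self):
        with pytest.raises(ValueError):
            simulate_mei([], seed=0)
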