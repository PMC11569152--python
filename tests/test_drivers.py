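"""Dynamic driver recipes: flood composite, interpolation, distances, climate, land price."""

import numpy as np
import pandas as pd
import pytest

from deltaclue.drivers import (
    FAR_DISTANCE,
    Feature,
    FeatureSchedule,
    FloodDepthSet,
    distance_raster,
    flood_composite,
    fractional_endpoint,
    interpolate_year,
    landprice_model,
    landprice_predict,
    moving_average_climate,
)
from deltaclue.grid import ContinuousRaster, GridSpec
from deltaclue.synth import gen_driver_fields

from conftest import raster_from, stack_from


def depth_set(spec, values):
    mk = lambda v: ContinuousRaster(spec, np.full(spec.shape, float(v)), name="d")
    return FloodDepthSet(*[mk(v) for v in values])


class TestFloodComposite:
    def test_unit_depths(self, spec2):
        out = flood_composite(depth_set(spec2, (1, 1, 1, 1)))
        assert out.values[0, 0] == pytest.approx(0.11101)

    def test_weighted_sum(self, spec2):
        out = flood_composite(depth_set(spec2, (2, 5, 10, 20)))
        assert out.values[0, 0] == pytest.approx(0.2602)

    def test_zero_depths(self, spec2):
        assert (flood_composite(depth_set(spec2, (0, 0, 0, 0))).values == 0).all()

    def test_negative_depth_rejected(self, spec2):
        with pytest.raises(ValueError):
            depth_set(spec2, (1, -1, 1, 1))


class TestInterpolation:
    @pytest.fixture
    def endpoints(self, spec2):
        a = ContinuousRaster(spec2, np.full((2, 2), 10.0), name="v")
        b = ContinuousRaster(spec2, np.full((2, 2), 42.0), name="v")
        return a, b

    def test_exact_at_endpoints(self, endpoints):
        a, b = endpoints
        np.testing.assert_array_equal(interpolate_year(a, b, 2018, 2018, 2050).values, a.values)
        np.testing.assert_array_equal(interpolate_year(a, b, 2050, 2018, 2050).values, b.values)

    def test_midpoint_is_cellwise_mean(self, endpoints):
        a, b = endpoints
        assert interpolate_year(a, b, 2034, 2018, 2050).values[0, 0] == 26.0

    def test_three_quarters(self, endpoints):
        a, b = endpoints
        assert interpolate_year(a, b, 2042, 2018, 2050).values[0, 0] == 34.0

    def test_affine_in_year(self, endpoints):
        a, b = endpoints
        ys = [interpolate_year(a, b, y, 2018, 2050).values[0, 0] for y in (2020, 2030, 2040)]
        assert ys[1] - ys[0] == pytest.approx((ys[2] - ys[1]))

    def test_fractional_endpoint_matches_dated_interpolation(self, endpoints):
        a, b = endpoints
        # a three-quarter-severity endpoint equals the 2042 map of 2018-2050
        np.testing.assert_allclose(
            fractional_endpoint(a, b, 0.75).values,
            interpolate_year(a, b, 2042, 2018, 2050).values,
        )

    def test_fraction_bounds(self, endpoints):
        a, b = endpoints
        np.testing.assert_array_equal(fractional_endpoint(a, b, 0.0).values, a.values)
        np.testing.assert_array_equal(fractional_endpoint(a, b, 1.0).values, b.values)


class TestDistanceRaster:
    def test_point_at_cell_center_and_1d_profile(self):
        spec = GridSpec(ncols=4, nrows=1, cellsize=1000.0)
        sched = FeatureSchedule([Feature("st", [[500.0, 500.0]], open_year=2000)])
        d = distance_raster(spec, sched, 2019)
        np.testing.assert_allclose(d.values[0], [0.0, 1000.0, 2000.0, 3000.0])

    def test_closed_feature_ignored(self):
        spec = GridSpec(ncols=2, nrows=1, cellsize=1000.0)
        sched = FeatureSchedule([
            Feature("far", [[1500.0, 500.0]], open_year=2000),
            Feature("near", [[500.0, 500.0]], open_year=2025, close_year=2035),
        ])
        assert distance_raster(spec, sched, 2030).values[0, 0] == 0.0
        assert distance_raster(spec, sched, 2036).values[0, 0] == 1000.0

    def test_empty_schedule_warns_and_fills_far(self, spec2):
        with pytest.warns(UserWarning, match="no feature open"):
            d = distance_raster(spec2, FeatureSchedule([]), 2019)
        assert (d.values == FAR_DISTANCE).all()

    def test_adding_features_never_increases_distance(self, spec10):
        one = FeatureSchedule([Feature("a", [[500.0, 500.0]], 2000)])
        two = FeatureSchedule(one.features + [Feature("b", [[9500.0, 9500.0]], 2000)])
        d1 = distance_raster(spec10, one, 2019).values
        d2 = distance_raster(spec10, two, 2019).values
        assert (d2 <= d1 + 1e-9).all()

    def test_polyline_densification(self):
        spec = GridSpec(ncols=3, nrows=3, cellsize=1000.0)
        line = Feature("rail", [[500.0, 500.0], [2500.0, 500.0]], 2000)
        d = distance_raster(spec, FeatureSchedule([line]), 2019)
        np.testing.assert_allclose(d.values[2], [0.0, 0.0, 0.0])  # along the line
        np.testing.assert_allclose(d.values[1], [1000.0, 1000.0, 1000.0])

    def test_schedule_csv_round_trip(self, tmp_path):
        sched = FeatureSchedule([
            Feature("a", [[500.0, 500.0]], 2000, 2035),
            Feature("b", [[100.0, 200.0], [300.0, 400.0]], 2025, None),
        ])
        sched.to_csv(tmp_path / "s.csv")
        back = FeatureSchedule.from_csv(tmp_path / "s.csv")
        assert back.features[0].close_year == 2035
        assert back.features[1].close_year is None
        np.testing.assert_allclose(back.features[1].coords, sched.features[1].coords)


class TestMovingAverageClimate:
    def series(self, spec, values):
        return {
            2000 + i: ContinuousRaster(spec, np.full(spec.shape, float(v)), name="t")
            for i, v in enumerate(values)
        }

    def test_constant_series_unchanged(self, spec2):
        out = moving_average_climate(self.series(spec2, [5, 5, 5]), window=2)
        assert all((r.values == 5).all() for r in out.values())

    def test_window_two_mean(self, spec2):
        out = moving_average_climate(self.series(spec2, [1, 3]), window=2, years=[2001])
        assert out[2001].values[0, 0] == 2.0

    def test_short_prefix_warns_and_averages_available(self, spec2):
        series = self.series(spec2, range(16))
        with pytest.warns(UserWarning, match="16 of 20"):
            out = moving_average_climate(series, window=20, years=[2015])
        assert out[2015].values[0, 0] == pytest.approx(np.mean(range(16)))

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            moving_average_climate({}, window=20)


class TestLandPrice:
    def test_noiseless_recovery(self, spec10, rng):
        stack = stack_from(spec10, {"alt": rng.standard_normal((10, 10))})
        price = ContinuousRaster(spec10, 3.0 * stack["alt"].values + 7.0, name="price")
        model = landprice_model(price, stack)
        assert model.r_squared == pytest.approx(1.0)
        pred = landprice_predict(model, stack)
        np.testing.assert_allclose(pred.values, price.values, rtol=1e-9)

    def test_independent_price_gives_near_zero_r2(self):
        spec = GridSpec(50, 50)
        stack = gen_driver_fields(spec, 3, 0, seed=0)
        rng = np.random.default_rng(1)
        price = ContinuousRaster(spec, rng.standard_normal(spec.shape), name="price")
        assert landprice_model(price, stack).r_squared < 0.05

    def test_planted_r2_recovered(self):
        spec = GridSpec(50, 50)
        r2s = []
        for seed in range(20):
            stack = gen_driver_fields(spec, 1, 0, seed=seed)
            rng = np.random.default_rng(100 + seed)
            x = stack["driver_0"].values
            # var(signal)=1, var(noise)=1 -> population R^2 = 0.5
            price = ContinuousRaster(spec, x + rng.standard_normal(spec.shape), name="p")
            r2s.append(landprice_model(price, stack).r_squared)
        assert np.mean(r2s) == pytest.approx(0.5, abs=0.05)

    def test_prediction_rescaled_to_training_maximum(self, spec10, rng):
        stack = stack_from(spec10, {"alt": rng.standard_normal((10, 10))})
        price = ContinuousRaster(spec10, 2.0 * stack["alt"].values + 5.0, name="price")
        model = landprice_model(price, stack)
        future = stack_from(spec10, {"alt": 10.0 * rng.standard_normal((10, 10))})
        pred = landprice_predict(model, future)
        assert pred.values.max() == pytest.approx(model.train_max)
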