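import math

import numpy as np
import pytest

from hikespeed.models import (
    GLMSpeedModel,
    NaismithParams,
    TerrainCoefficients,
    ToblerParams,
    breakeven_detour_percent,
    critical_gradient,
    degrees_to_gradient,
    naismith_speed,
    naismith_time,
    published_model,
    route_time,
    tobler_speed,
)
from hikespeed.terrain import TerrainClass

DEG = math.pi / 180.0


class TestGLMPrediction:
    def test_flat_paved(self, published_fit):
        assert published_fit.predict(0, 0, TerrainClass.PAVED_ROAD) == pytest.approx(
            math.exp(1.580), abs=1e-9)
        assert published_fit.predict(0, 0, TerrainClass.PAVED_ROAD) == pytest.approx(4.8550, abs=1e-4)

    def test_paved_slope_example(self, published_fit):
        # exp(1.580 - 0.0389 - 0.0363 - 0.0545)
        v = published_fit.predict(10, 5, TerrainClass.PAVED_ROAD)
        assert v == pytest.approx(math.exp(1.580 - 0.0389 - 0.0363 - 0.0545), abs=1e-4)
        assert v == pytest.approx(4.2644, abs=2e-4)

    def test_degenerate_coefficients_constant(self):
        model = GLMSpeedModel({t: TerrainCoefficients(1.0, 0.0, 0.0, 0.0)
                               for t in TerrainClass})
        for phi, theta in [(0, 0), (20, -10), (40, 30)]:
            assert model.predict(phi, theta, TerrainClass.OFFROAD_HEAVY) == pytest.approx(
                math.exp(1.0))

    def test_missing_terrain_class_rejected(self):
        with pytest.raises(ValueError):
            GLMSpeedModel({TerrainClass.PAVED_ROAD: TerrainCoefficients(1, 0, 0, -1)})

    def test_monotone_decreasing_in_hill_slope(self, published_fit):
        phis = np.linspace(0, 40, 50)
        for terrain in TerrainClass:
            v = published_fit.predict(phis, 0.0, terrain)
            assert np.all(np.diff(v) < 0)

    def test_decreasing_away_from_descent_optimum(self, published_fit):
        for terrain in TerrainClass:
            cf = published_fit.coefficients[terrain]
            theta_opt = -cf.c / (2 * cf.d)
            thetas = theta_opt + np.linspace(0, 30, 40)
            v = published_fit.predict(0.0, thetas, terrain)
            assert np.all(np.diff(v) < 0)
            v = published_fit.predict(0.0, theta_opt - np.linspace(0, 30, 40), terrain)
            assert np.all(np.diff(v) < 0)

    def test_intercept_ordering(self, published_fit):
        at = lambda t: published_fit.predict(0, 0, t)
        assert at(TerrainClass.OFFROAD_HEAVY) < at(TerrainClass.OFFROAD_UNKNOWN) \
            < at(TerrainClass.OFFROAD_LIGHT) == at(TerrainClass.PAVED_ROAD)

    def test_json_roundtrip(self, published_fit, tmp_path):
        path = tmp_path / "model.json"
        published_fit.to_json(path)
        back = GLMSpeedModel.from_json(path)
        assert back.coefficients == published_fit.coefficients


class TestNaismith:
    def test_flat_five_km(self):
        assert naismith_time(5.0, 0.0) == pytest.approx(60.0)

    def test_ascent_penalty_additive(self):
        for dist in (0.0, 3.0, 10.0):
            extra = naismith_time(dist, 100.0) - naismith_time(dist, 0.0)
            assert extra == pytest.approx(10.0)

    def test_zero_route(self):
        assert naismith_time(0.0, 0.0) == 0.0

    def test_descent_ignored(self):
        assert naismith_speed(-15.0) == pytest.approx(5.0)
        assert naismith_speed(-15.0, on_path=False) == pytest.approx(4.0)

    def test_negative_distance_raises(self):
        with pytest.raises(ValueError):
            naismith_time(-1.0, 0.0)


class TestTobler:
    def test_maximum_on_mild_descent(self):
        assert tobler_speed(-0.05) == 6.0
        grads = np.linspace(-0.8, 0.8, 2001)
        assert tobler_speed(grads).max() <= 6.0

    def test_flat_ground(self):
        assert tobler_speed(0.0) == pytest.approx(6 * math.exp(-0.175), abs=1e-9)
        assert tobler_speed(0.0) == pytest.approx(5.0368, abs=1e-4)

    def test_offroad_factor(self):
        assert tobler_speed(0.0, on_road=False) == pytest.approx(3.0221, abs=1e-4)

    def test_degree_adapter(self):
        assert degrees_to_gradient(45.0) == pytest.approx(1.0)


class TestCriticalGradient:
    def brute_force(self, model, terrain, convention, direction="uphill"):
        """0.01°-grid maximizer of the vertical ascent rate under direct ascent."""
        cf = model.coefficients[TerrainClass(terrain)]
        m = np.arange(0.01, 45.0 + 0.005, 0.01)
        sign = 1.0 if direction == "uphill" else -1.0
        ln_v = cf.c * sign * m + cf.d * m ** 2  # phi-terms constant in theta
        g = np.sin(m * DEG) if convention == "sin" else np.tan(m * DEG)
        rate = ln_v + np.log(g)
        return sign * float(m[np.argmax(rate)])

    @pytest.mark.parametrize("convention", ["sin", "tan"])
    @pytest.mark.parametrize("terrain", list(TerrainClass))
    def test_matches_grid_maximizer(self, published_fit, terrain, convention):
        root = critical_gradient(published_fit, terrain, "uphill", convention)
        grid = self.brute_force(published_fit, terrain, convention)
        assert root == pytest.approx(grid, abs=0.02)

    def test_paved_uphill_range(self, published_fit):
        cg = critical_gradient(published_fit, TerrainClass.PAVED_ROAD, "uphill", "sin")
        assert 14.0 <= cg <= 15.0

    def test_downhill_negative_and_matches_grid(self, published_fit):
        for terrain in TerrainClass:
            cg = critical_gradient(published_fit, terrain, "downhill", "sin")
            assert cg < 0
            assert cg == pytest.approx(
                self.brute_force(published_fit, terrain, "sin", "downhill"), abs=0.02)

    def test_no_interior_optimum_reported_above_45(self):
        model = GLMSpeedModel({t: TerrainCoefficients(1.5, 0.0, 0.0, -1e-9)
                               for t in TerrainClass})
        assert critical_gradient(model, TerrainClass.PAVED_ROAD) == math.inf


class TestDetourAndRouteTime:
    def test_paved_vs_heavy_breakeven(self, published_fit):
        pct = breakeven_detour_percent(published_fit, TerrainClass.PAVED_ROAD,
                                       TerrainClass.OFFROAD_HEAVY)
        assert pct == pytest.approx(100 * (math.exp(0.137) - 1), abs=1e-6)
        assert round(pct) == 15

    def test_identical_classes_zero(self, published_fit):
        assert breakeven_detour_percent(published_fit, TerrainClass.UNPAVED_ROAD,
                                        TerrainClass.UNPAVED_ROAD) == 0.0

    def test_paved_vs_light_zero_on_flat(self, published_fit):
        assert breakeven_detour_percent(published_fit, TerrainClass.PAVED_ROAD,
                                        TerrainClass.OFFROAD_LIGHT) == pytest.approx(0.0)

    def test_route_time_distance_speed_identity(self, published_fit):
        v = published_fit.predict(0, 0, TerrainClass.PAVED_ROAD)
        minutes = route_time(published_fit, [(v * 1000.0, 0.0, 0.0, TerrainClass.PAVED_ROAD)])
        assert minutes == pytest.approx(60.0)

    def test_splitting_section_preserves_total(self, published_fit):
        whole = [(2000.0, 12.0, 6.0, TerrainClass.UNPAVED_ROAD)]
        halves = [(1000.0, 12.0, 6.0, TerrainClass.UNPAVED_ROAD)] * 2
        assert route_time(published_fit, whole) == pytest.approx(route_time(published_fit, halves))

    def test_naismith_out_and_back_penalty_once(self):
        # symmetric hill: the ascent penalty applies only to the uphill leg
        up_down = [(1000.0, 10.0, 10.0, TerrainClass.PAVED_ROAD),
                   (1000.0, 10.0, -10.0, TerrainClass.PAVED_ROAD)]
        total = route_time(NaismithParams(), up_down)
        ascent = 1000.0 * math.tan(10.0 * DEG)
        assert total == pytest.approx(2 * 60.0 * 1.0 / 5.0 + 10.0 * ascent / 100.0)

    def test_pluggable_baseline_callable(self):
        baseline = lambda phi, theta, terrain: 4.0
        assert route_time(baseline, [(4000.0, 0, 0, TerrainClass.PAVED_ROAD)]) == \
            pytest.approx(60.0)

    def test_empty_route_rejected(self, published_fit):
        with pytest.raises(ValueError):
            route_time(published_fit, [])
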