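import math

import numpy as np
import pandas as pd
import pytest

from hikespeed.fitting import (
    DesignSpec,
    backward_eliminate,
    build_design,
    cross_validate,
    fit_glm,
    validate_constraints,
)
from hikespeed.models import GLMSpeedModel, TerrainCoefficients, published_model
from hikespeed.synthetic import simulate_sections
from hikespeed.terrain import TerrainClass


def max_table_error(fitted: GLMSpeedModel, truth: GLMSpeedModel) -> float:
    return max(abs(getattr(fitted.coefficients[t], k) - getattr(truth.coefficients[t], k))
               for t in TerrainClass for k in "abcd")


class TestDesignSpec:
    def test_interaction_requires_main_effect(self):
        with pytest.raises(ValueError):
            DesignSpec(("intercept", "offroad:phi", "road"))  # phi missing

    def test_intercept_always_present(self):
        spec = DesignSpec(("phi",))
        assert "intercept" in spec.terms

    def test_main_effect_not_removable_while_interaction_present(self):
        spec = DesignSpec()
        removable = spec.removable_terms()
        assert "road" not in removable and "phi" not in removable
        assert "offroad:phi" in removable

    def test_rank_deficiency_reported(self, published_fit):
        df = simulate_sections(n_tracks=5, sections_per_track=20, sigma=0.0, seed=0)
        df = df[df["terrain"] == "paved_road"]  # single class: dummies aliased
        with pytest.raises(ValueError, match="rank-deficient"):
            build_design(df, DesignSpec())


class TestFitGLM:
    def test_noise_free_recovery_is_exact(self, published_fit):
        df = simulate_sections(n_tracks=20, sections_per_track=30, sigma=0.0, seed=1)
        result = fit_glm(df)
        assert max_table_error(result.to_speed_model(), published_fit) < 1e-6

    def test_duplicating_sections_leaves_estimates_unchanged(self):
        df = simulate_sections(n_tracks=30, sections_per_track=20, sigma=0.2, seed=2)
        single = fit_glm(df)
        double = fit_glm(pd.concat([df, df], ignore_index=True))
        np.testing.assert_allclose(single.params, double.params, atol=1e-8)

    def test_cluster_robust_se_exceeds_classical_under_correlation(self):
        df = simulate_sections(n_tracks=200, sections_per_track=30,
                               sigma=0.15, track_sigma=0.2, seed=4)
        robust = fit_glm(df, robust=True)
        classical = fit_glm(df, robust=False)
        # shared per-track effects inflate the true uncertainty; the
        # sandwich estimator must see it where the classical one cannot
        assert robust.bse["intercept"] > 1.5 * classical.bse["intercept"]

    def test_true_model_rmse_matches_injected_noise(self, published_fit):
        sigma = 0.25
        df = simulate_sections(n_tracks=200, sections_per_track=50,
                               sigma=sigma, seed=6)
        from hikespeed.evaluation import predict_sections
        pred = predict_sections(published_fit, df)
        obs = df["speed_kmh"].to_numpy()
        rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
        # E[(m e^eps - m)^2] = m^2 (e^{2s^2} - 2 e^{s^2/2} + 1)
        factor = math.sqrt(math.exp(2 * sigma ** 2) - 2 * math.exp(sigma ** 2 / 2) + 1)
        expected = math.sqrt(np.mean(pred ** 2)) * factor
        assert rmse == pytest.approx(expected, rel=0.05)

    def test_mean_bias_small_over_replicates(self, published_fit):
        # 50 replicates at study scale: the average fitted value of each
        # collapsed coefficient stays within 10% of its generating value
        sums = {t: np.zeros(4) for t in TerrainClass}
        n_rep = 50
        for rep in range(n_rep):
            df = simulate_sections(n_tracks=200, sections_per_track=50,
                                   sigma=0.25, seed=1000 + rep)
            fitted = fit_glm(df, estimator="logols").to_speed_model()
            for t in TerrainClass:
                cf = fitted.coefficients[t]
                sums[t] += np.array([cf.a, cf.b, cf.c, cf.d])
        for t in TerrainClass:
            truth = published_fit.coefficients[t]
            mean_est = sums[t] / n_rep
            for est, true in zip(mean_est, (truth.a, truth.b, truth.c, truth.d)):
                assert abs(est - true) < 0.1 * abs(true)


class TestBackwardElimination:
    def test_strong_terms_survive(self):
        # truth with distinct coefficients everywhere and low noise
        truth = GLMSpeedModel({
            TerrainClass.PAVED_ROAD: TerrainCoefficients(1.6, -0.004, -0.007, -0.0022),
            TerrainClass.UNPAVED_ROAD: TerrainCoefficients(1.52, -0.006, -0.010, -0.0027),
            TerrainClass.OFFROAD_UNKNOWN: TerrainCoefficients(1.45, -0.009, -0.013, -0.0017),
            TerrainClass.OFFROAD_LIGHT: TerrainCoefficients(1.48, -0.009, -0.013, -0.0017),
            TerrainClass.OFFROAD_HEAVY: TerrainCoefficients(1.35, -0.009, -0.013, -0.0017),
        })
        df = simulate_sections(truth, n_tracks=150, sections_per_track=60,
                               sigma=0.05, seed=8)
        result = backward_eliminate(df, estimator="logols")
        assert set(result.spec.terms) == set(DesignSpec().terms)
        assert result.elimination_trace == []

    def test_null_interaction_eliminated(self, published_fit):
        # published truth has identical hill-slope response on paved and
        # unpaved roads, so the unpaved x phi interaction is truly zero
        df = simulate_sections(n_tracks=200, sections_per_track=50,
                               sigma=0.25, seed=5)
        result = backward_eliminate(df, estimator="logols")
        removed = {e["removed"] for e in result.elimination_trace}
        assert "unpaved:phi" in removed
        fitted = result.to_speed_model()
        # classes whose interactions were dropped collapse to a shared value
        assert fitted.coefficients[TerrainClass.UNPAVED_ROAD].b == \
            fitted.coefficients[TerrainClass.PAVED_ROAD].b
        # every term still removable under the hierarchy is significant
        for t in result.spec.removable_terms():
            assert result.term_pvalues[t] < 0.05

    def test_elimination_deterministic(self):
        df = simulate_sections(n_tracks=60, sections_per_track=30,
                               sigma=0.3, seed=9)
        a = backward_eliminate(df, estimator="logols")
        b = backward_eliminate(df, estimator="logols")
        assert a.spec.terms == b.spec.terms
        assert a.elimination_trace == b.elimination_trace


class TestConstraints:
    def test_published_model_passes(self, published_fit):
        report = validate_constraints(published_fit)
        assert report["passed"]
        for checks in report["per_terrain"].values():
            assert checks["critical_gradient_deg"] < 21.0

    def test_positive_hill_coefficient_fails(self):
        model = GLMSpeedModel({t: TerrainCoefficients(1.5, 0.01, -0.007, -0.002)
                               for t in TerrainClass})
        report = validate_constraints(model)
        assert not report["passed"]
        assert not report["per_terrain"]["paved_road"]["hill_slope_monotone"]

    def test_nonnegative_curvature_fails(self):
        model = GLMSpeedModel({t: TerrainCoefficients(1.5, -0.004, -0.007, 0.0)
                               for t in TerrainClass})
        report = validate_constraints(model)
        assert not report["passed"]
        assert not report["per_terrain"]["paved_road"]["walking_slope_concave"]


class TestCrossValidation:
    def test_noise_free_rmse_vanishes(self):
        df = simulate_sections(n_tracks=20, sections_per_track=30, sigma=0.0, seed=3)
        cv = cross_validate(df, k=10, seed=0)
        assert cv["pooled"]["rmse"] < 1e-6

    def test_deterministic_and_order_invariant(self):
        df = simulate_sections(n_tracks=25, sections_per_track=20, sigma=0.2, seed=12)
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = cross_validate(df, k=5, seed=42)
        b = cross_validate(shuffled, k=5, seed=42)
        for key in a["pooled"]:
            assert a["pooled"][key] == pytest.approx(b["pooled"][key], rel=1e-9)

    def test_requires_enough_tracks(self):
        df = simulate_sections(n_tracks=5, sections_per_track=10, sigma=0.1, seed=0)
        with pytest.raises(ValueError):
            cross_validate(df, k=10, seed=0)
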