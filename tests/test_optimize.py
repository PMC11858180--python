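"""Stationary-point analysis, bounded search, surface slices, validation."""

import dataclasses

import numpy as np
import pytest

import rsmkit as rk


def model_from_coef(factors, coef):
    """Wrap raw coefficients as a fitted-model object for optimization."""
    return rk.QuadraticModel(
        factors=tuple(factors),
        coef=np.asarray(coef, dtype=float),
        residuals=np.zeros(1),
        residual_df=1,
        ss_total=1.0,
        ss_model=1.0,
        ss_residual=0.0,
    )


def test_cellulase_optimum_matches_reported_conditions(cellulase_model):
    sp = rk.stationary_point(cellulase_model)
    assert sp.classification == "maximum"
    assert sp.interior
    # reported optimum: 154.529 r/min, 34.463 degC, 28.368 h at 10.975 U/mL
    np.testing.assert_allclose(sp.natural, [154.529, 34.463, 28.368], atol=0.2)
    assert sp.predicted == pytest.approx(10.975, abs=0.01)


def test_symmetric_bowl_peaks_at_origin(three_factors):
    model = model_from_coef(
        three_factors, [10, 0, 0, 0, 0, 0, 0, -1, -1, -1]
    )
    sp = rk.stationary_point(model)
    np.testing.assert_allclose(sp.coded, 0, atol=1e-12)
    assert sp.predicted == pytest.approx(10.0)
    assert sp.classification == "maximum"


def test_mixed_curvature_is_saddle(three_factors):
    model = model_from_coef(three_factors, [0, 0, 0, 0, 0, 0, 0, 1, -1, 0.5])
    assert rk.stationary_point(model).classification == "saddle"


def test_singular_hessian_raises_ridge_error(three_factors):
    model = model_from_coef(three_factors, [0, 1, 0, 0, 0, 0, 0, 0, 0, 0])
    with pytest.raises(rk.RidgeSystemError):
        rk.stationary_point(model)


def test_bounded_agrees_with_stationary_for_interior_maximum(cellulase_model):
    sp = rk.stationary_point(cellulase_model)
    bm = rk.bounded_maximize(cellulase_model)
    np.testing.assert_allclose(bm.coded, sp.coded, atol=1e-6)
    assert bm.predicted == pytest.approx(sp.predicted, abs=1e-9)


def test_linear_objective_maximized_at_box_corner(three_factors):
    model = model_from_coef(three_factors, [0, 1, 0, 0, 0, 0, 0, 0, 0, 0])
    bm = rk.bounded_maximize(model)
    assert bm.coded[0] == pytest.approx(1.0, abs=1e-9)
    assert bm.predicted == pytest.approx(1.0, abs=1e-9)


def test_bounded_maximize_matches_dense_grid_oracle(cellulase_model):
    # brute-force oracle: the full 101^3 coded lattice
    axis = np.linspace(-1, 1, 101)
    g = np.stack(np.meshgrid(axis, axis, axis, indexing="ij"), axis=-1)
    values = rk.predict(cellulase_model, g.reshape(-1, 3))
    bm = rk.bounded_maximize(cellulase_model)
    assert bm.predicted >= values.max() - 1e-3
    assert abs(bm.predicted - values.max()) <= 1e-3


def test_concave_maximum_dominates_random_points(three_factors):
    rng = np.random.default_rng(5)
    for _ in range(5):
        quad = -rng.uniform(0.5, 4.0, 3)
        coef = np.concatenate([[rng.normal()], rng.normal(0, 1, 3),
                               rng.normal(0, 0.2, 3), quad])
        model = model_from_coef(three_factors, coef)
        sp = rk.stationary_point(model)
        assert sp.classification == "maximum"
        pts = rng.uniform(-2, 2, size=(1000, 3))
        assert np.all(rk.predict(model, pts) <= sp.predicted + 1e-9)


class TestSurfaceGrid:
    def test_center_node_equals_intercept(self, cellulase_model):
        grid = rk.surface_grid(
            cellulase_model, "shaker_speed", "temperature", resolution=3
        )
        assert grid.predicted[1, 1] == pytest.approx(cellulase_model.b0)

    def test_every_node_matches_predict(self, cellulase_model):
        sp = rk.stationary_point(cellulase_model)
        grid = rk.surface_grid(
            cellulase_model, 0, 1,
            held={"incubation_time": sp.coded[2]}, resolution=7,
        )
        for a, ci in enumerate(grid.coded_i):
            for b, cj in enumerate(grid.coded_j):
                point = [ci, cj, sp.coded[2]]
                assert grid.predicted[a, b] == pytest.approx(
                    rk.predict(cellulase_model, point), rel=1e-12
                )
        # no slice value exceeds the global maximum
        assert grid.predicted.max() <= sp.predicted + 1e-9

    def test_identical_factors_rejected(self, cellulase_model):
        with pytest.raises(ValueError):
            rk.surface_grid(cellulase_model, "temperature", "temperature")


class TestValidateSettings:
    def test_practical_settings_near_optimum(self, cellulase_model):
        # rounded bench settings 154 r/min, 34 degC, 28 h
        pred, gap = rk.validate_settings(cellulase_model, [154, 34, 28])
        assert pred == pytest.approx(10.944, abs=0.002)
        assert gap == pytest.approx(10.975 - pred, abs=0.01)
        assert pred == pytest.approx(
            rk.predict(cellulase_model, [154, 34, 28], natural=True)
        )

    def test_gap_zero_at_the_optimum(self, cellulase_model):
        sp = rk.stationary_point(cellulase_model)
        pred, gap = rk.validate_settings(cellulase_model, sp.natural)
        assert gap == pytest.approx(0.0, abs=1e-6)

    def test_gap_nonnegative_for_concave_model(self, cellulase_model):
        rng = np.random.default_rng(9)
        lows = [f.low for f in cellulase_model.factors]
        highs = [f.high for f in cellulase_model.factors]
        for _ in range(10):
            settings = rng.uniform(lows, highs)
            _, gap = rk.validate_settings(cellulase_model, settings)
            assert gap >= -1e-9


def test_optimum_recovery_under_noise(three_factors):
    """Estimated optimum stays near the truth's optimum under realistic
    noise: coded error < 0.15 per coordinate in >= 90% of replicates."""
    truth_coef = np.array([10.61, 0.70, 1.50, 0.79, -0.065, 0.015, 0.33,
                           -3.78, -2.11, -2.99])
    truth_model = rk.QuadraticModel(
        factors=three_factors, coef=truth_coef, residuals=np.zeros(1),
        residual_df=1, ss_total=1.0, ss_model=1.0, ss_residual=0.0,
    )
    true_opt = rk.stationary_point(truth_model).coded
    spec = rk.TruthSpec(factors=three_factors, coef=truth_coef, noise_sd=0.3)
    rng = np.random.default_rng(17)
    design, batch = rk.simulate_response_batch(spec, 500, rng)
    hits = 0
    for y in batch:
        model = rk.fit_quadratic(
            design, rk.ResponseTable(dict(zip(design.run_ids, y)))
        )
        try:
            est = rk.stationary_point(model).coded
        except rk.RidgeSystemError:
            continue
        if np.all(np.abs(est - true_opt) < 0.15):
            hits += 1
    assert hits >= 450
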