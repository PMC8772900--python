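"""Data splitting, ANN regression, connection-weight importance, the
MLRM baseline and response surfaces."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.neural_network import MLPRegressor

from fhrva.models import (
    ANNModel,
    ann_importance,
    fit_mlrm,
    regression_metrics,
    response_surface,
    split_data,
    train_ann,
)
from fhrva.synthetic_ctg import synthetic_reduced_dataset

from .oracles import importance_double_loop


def _linear_model(feature_names, coefs, bias=0.0, eps=1e-6):
    """An ANNModel that is linear to ~1e-12: tanh driven in its linear range."""
    p = len(feature_names)
    return ANNModel(
        input_weights=np.asarray(coefs, float).reshape(p, 1) * eps,
        hidden_biases=np.zeros(1),
        output_weights=np.array([1.0 / eps]),
        output_bias=bias,
        hidden_size=1,
        x_mean=np.zeros(p),
        x_scale=np.ones(p),
        feature_names=tuple(feature_names),
    )


class TestSplitData:
    def test_n100_exact_sizes(self):
        s = split_data(100, seed=0)
        assert (s.train_idx.size, s.val_idx.size, s.test_idx.size) == (70, 15, 15)

    def test_n187_largest_remainder(self):
        s = split_data(187, seed=0)
        assert (s.train_idx.size, s.val_idx.size, s.test_idx.size) == (131, 28, 28)

    def test_same_seed_identical(self):
        a, b = split_data(57, seed=3), split_data(57, seed=3)
        np.testing.assert_array_equal(a.train_idx, b.train_idx)
        np.testing.assert_array_equal(a.test_idx, b.test_idx)

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            split_data(9, seed=0)

    @given(st.integers(10, 400), st.integers(0, 10_000))
    def test_partition_disjoint_and_exhaustive(self, n, seed):
        s = split_data(n, seed)
        joined = np.concatenate([s.train_idx, s.val_idx, s.test_idx])
        assert joined.size == n
        assert np.array_equal(np.sort(joined), np.arange(n))


class TestRegressionMetrics:
    def test_perfect_prediction(self):
        r, r2, rmse = regression_metrics([1, 2, 3, 4], [1, 2, 3, 4])
        assert (r, r2, rmse) == (pytest.approx(1.0), pytest.approx(1.0), pytest.approx(0.0))

    def test_mean_predictor_zero_r2(self):
        y = np.array([1.0, 2.0, 3.0])
        _, r2, _ = regression_metrics(y, np.full(3, y.mean()))
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_hand_evaluated_case(self):
        r, r2, rmse = regression_metrics([1, 2, 3], [2, 2, 2])
        assert rmse == pytest.approx(np.sqrt(2 / 3), rel=1e-12)
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_observations_warn(self):
        with pytest.warns(UserWarning):
            _, r2, _ = regression_metrics([2, 2, 2], [1, 2, 3])
        assert np.isnan(r2)

    def test_r2_equals_squared_correlation_for_linear_fit(self, rng):
        # For predictions from an OLS fit, 1 - SSE/SST equals corr(y, yhat)^2.
        x = rng.standard_normal(100)
        y = 2 * x + rng.standard_normal(100)
        coeffs = np.polyfit(x, y, 1)
        yhat = np.polyval(coeffs, x)
        r, r2, _ = regression_metrics(y, yhat)
        assert r2 == pytest.approx(r**2, rel=1e-9)


class TestANNImportance:
    def test_all_zero_weights(self):
        m = _linear_model(["a", "b"], [0.0, 0.0])
        m.input_weights = np.zeros((2, 1))
        m.output_weights = np.zeros(1)
        imp = ann_importance(m)
        assert (imp["contribution"] == 0).all() and (imp["normalized"] == 0).all()

    def test_single_hidden_unit_product(self):
        m = ANNModel(
            input_weights=np.array([[2.0]]), hidden_biases=np.zeros(1),
            output_weights=np.array([3.0]), output_bias=0.0, hidden_size=1,
            x_mean=np.zeros(1), x_scale=np.ones(1), feature_names=("x",),
        )
        assert ann_importance(m)["contribution"].iloc[0] == pytest.approx(6.0)

    def test_random_networks_match_double_loop_oracle(self, rng):
        for _ in range(25):
            p, h = rng.integers(2, 9), rng.integers(1, 11)
            a = rng.standard_normal((p, h))
            b = rng.standard_normal(h)
            m = ANNModel(a, np.zeros(h), b, 0.0, int(h), np.zeros(p), np.ones(p),
                         tuple(f"f{i}" for i in range(p)))
            imp = ann_importance(m)
            np.testing.assert_allclose(imp["contribution"].to_numpy(),
                                       importance_double_loop(a, b), atol=1e-12)
            if imp["contribution"].sum() > 0:
                assert imp["normalized"].sum() == pytest.approx(1.0, rel=1e-12)


class TestTrainANN:
    def test_prediction_matches_sklearn_forward_pass(self, rng):
        x = rng.standard_normal((40, 3))
        y = rng.standard_normal(40)
        net = MLPRegressor(hidden_layer_sizes=(4,), activation="tanh", solver="adam",
                           max_iter=20, random_state=0)
        import warnings as w
        with w.catch_warnings():
            w.simplefilter("ignore")
            net.fit(x, y)
        m = ANNModel(net.coefs_[0], net.intercepts_[0], net.coefs_[1].ravel(),
                     float(np.ravel(net.intercepts_[1])[0]), 4,
                     np.zeros(3), np.ones(3), ("a", "b", "c"))
        np.testing.assert_allclose(m.predict(x), net.predict(x), atol=1e-10)

    def test_learns_noiseless_linear_target(self):
        rng = np.random.default_rng(1)
        x = pd.DataFrame(rng.standard_normal((120, 2)), columns=["u", "v"])
        y = 3.0 * x["u"].to_numpy() - 2.0 * x["v"].to_numpy() + 5.0
        split = split_data(120, seed=1)
        _, metrics = train_ann(x, y, split, hidden_grid=(3,), n_restarts=5,
                               max_epochs=1500, learning_rate=0.02, seed=1)
        assert metrics.per_subset["overall"]["R2"] > 0.99

    def test_constant_target_predicts_constant(self):
        rng = np.random.default_rng(2)
        x = pd.DataFrame(rng.standard_normal((60, 2)), columns=["u", "v"])
        y = np.full(60, 7.0)
        split = split_data(60, seed=2)
        import warnings as w
        with w.catch_warnings():
            w.simplefilter("ignore")  # undefined R2 on constant subsets
            model, metrics = train_ann(x, y, split, hidden_grid=(2,), n_restarts=1,
                                       max_epochs=800, learning_rate=0.05, seed=2)
        assert np.allclose(model.predict(x), 7.0, atol=0.5)
        assert not metrics.per_subset["val"]["R2"] > 0  # undefined (NaN) or <= 0

    def test_training_deterministic_for_fixed_seed(self):
        x, y = synthetic_reduced_dataset(80, seed=4)
        split = split_data(80, seed=4)
        m1, r1 = train_ann(x, y, split, hidden_grid=(3,), n_restarts=1, max_epochs=100, seed=4)
        m2, r2 = train_ann(x, y, split, hidden_grid=(3,), n_restarts=1, max_epochs=100, seed=4)
        np.testing.assert_array_equal(m1.input_weights, m2.input_weights)
        assert r1.per_subset == r2.per_subset

    def test_permutation_invariance_of_prediction(self):
        x, y = synthetic_reduced_dataset(80, seed=5)
        split = split_data(80, seed=5)
        model, _ = train_ann(x, y, split, hidden_grid=(3,), n_restarts=1, max_epochs=100, seed=5)
        perm = np.random.default_rng(0).permutation(80)
        np.testing.assert_allclose(model.predict(x)[perm],
                                   model.predict(x.iloc[perm]), atol=1e-12)

    def test_linear_drivers_rank_in_top_importance_tier(self):
        # On a corpus whose response is dominated by the time-domain and
        # VLF/total-power components, those two inputs top the
        # connection-weight importance ranking.
        x, y = synthetic_reduced_dataset(400, seed=3)
        model, _ = train_ann(x, y, split_data(400, seed=3), hidden_grid=(6,),
                             n_restarts=2, max_epochs=400, seed=0)
        ranked = ann_importance(model)["normalized"].sort_values(ascending=False)
        assert set(ranked.index[:2]) == {"LIN_time", "LIN_VLF_power"}

    def test_invalid_hidden_size_rejected(self):
        x, y = synthetic_reduced_dataset(40, seed=6)
        with pytest.raises(ValueError):
            train_ann(x, y, split_data(40, seed=6), hidden_grid=(11,))


class TestMLRM:
    def test_noiseless_exact_recovery(self):
        x, _ = synthetic_reduced_dataset(187, seed=7)
        beta = np.array([0.2, -0.05, 2.0, 1.5, -0.7, 0.3, 0.9, -0.4])
        y = 4.0 + x.to_numpy(float) @ beta
        res = fit_mlrm(x, y)
        np.testing.assert_allclose(res.coefficients.to_numpy()[1:], beta, atol=1e-8)
        assert res.coefficients.iloc[0] == pytest.approx(4.0, abs=1e-8)
        assert res.r2 == pytest.approx(1.0, abs=1e-10)

    def test_diagnostics_shape_and_identities(self):
        x, y = synthetic_reduced_dataset(187, seed=8)
        res = fit_mlrm(x, y)
        np.testing.assert_allclose(res.tolerance.to_numpy(), 1.0 / res.vif.to_numpy(), rtol=1e-12)
        lo, hi = res.confidence_intervals["lower"], res.confidence_intervals["upper"]
        assert ((lo <= res.coefficients) & (res.coefficients <= hi)).all()
        assert res.pp_plot.shape == (187, 2)
        assert res.residual_vs_fitted.shape == (187, 2)
        assert 1.5 < res.durbin_watson < 2.5  # iid noise in the generator

    def test_rank_deficient_design_rejected_with_names(self):
        x, y = synthetic_reduced_dataset(60, seed=9)
        x = x.copy()
        x["LIN_SVB"] = 2.0 * x["LIN_time"]
        with pytest.raises(ValueError, match="LIN_time"):
            fit_mlrm(x, y)

    def test_standardized_coefficients_scale_free(self):
        x, y = synthetic_reduced_dataset(187, seed=10)
        res = fit_mlrm(x, y)
        x2 = x.copy()
        x2["LIN_time"] = x2["LIN_time"] * 100.0
        res2 = fit_mlrm(x2, y)
        assert res2.standardized_coefficients["LIN_time"] == pytest.approx(
            res.standardized_coefficients["LIN_time"], rel=1e-9
        )


class TestResponseSurface:
    def test_linear_model_gives_planar_surfaces(self):
        x, _ = synthetic_reduced_dataset(100, seed=11)
        model = _linear_model(x.columns, np.arange(1, 9) / 10.0)
        rs = response_surface(model, x, grid_size=9)
        assert len(rs.surfaces) == 9
        for grid in rs.surfaces.values():
            gx, gy = np.meshgrid(rs.grid_x, rs.grid_y, indexing="ij")
            a = np.column_stack([gx.ravel(), gy.ravel(), np.ones(gx.size)])
            coef, *_ = np.linalg.lstsq(a, grid.ravel(), rcond=None)
            plane = (a @ coef).reshape(grid.shape)
            assert np.abs(grid - plane).max() < 1e-8

    def test_surfaces_deterministic(self):
        x, y = synthetic_reduced_dataset(100, seed=12)
        model, _ = train_ann(x, y, split_data(100, seed=12), hidden_grid=(4,),
                             n_restarts=1, max_epochs=150, seed=12)
        a = response_surface(model, x, grid_size=7)
        b = response_surface(model, x, grid_size=7)
        for key in a.surfaces:
            np.testing.assert_array_equal(a.surfaces[key], b.surfaces[key])

    def test_unknown_input_rejected(self):
        x, _ = synthetic_reduced_dataset(50, seed=13)
        model = _linear_model(x.columns, np.ones(8))
        with pytest.raises(ValueError, match="unknown input"):
            response_surface(model, x, vary=("NL_variability", "bogus"))

    def test_week_dependent_interaction_curvature(self):
        # Trained on data whose nonlinear coupling grows with gestation, the
        # network's surface curvature is larger at week 41 than at week 30.
        x, y = synthetic_reduced_dataset(400, seed=3)
        model, _ = train_ann(x, y, split_data(400, seed=3), hidden_grid=(10,),
                             n_restarts=3, max_epochs=600, seed=3)
        rs = response_surface(model, x, grid_size=15)

        def curvature(grid):
            return float(np.ptp(np.diff(grid, 2, axis=0)))

        assert curvature(rs.surfaces[(41, 140.0)]) > curvature(rs.surfaces[(30, 140.0)])
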