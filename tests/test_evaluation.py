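"""Tests for the validation diagnostics."""

import numpy as np
import pandas as pd
import pytest

from ocgapfill.evaluation import (
    binned_stats,
    compute_metrics,
    daily_metric_series,
    decompose_rmse,
    estimate_epsilon_app,
    filter_threshold,
    hidden_size_sweep,
    spatial_bias_map,
)
from ocgapfill.mlp import TrainingOptions
from ocgapfill.synth import sample_chla


class TestComputeMetrics:
    def test_hand_case(self):
        m = compute_metrics(pred=[0.0, 1.0], obs=[1.0, 2.0])
        assert m.bias == pytest.approx(1.0)
        assert m.rmse == pytest.approx(1.0)
        assert m.cc == pytest.approx(1.0)
        assert m.n == 2

    def test_perfect_nonconstant_prediction(self):
        m = compute_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m.bias == 0.0 and m.rmse == 0.0 and m.cc == pytest.approx(1.0)

    def test_anticorrelated(self):
        obs = np.array([1.0, 2.0, 4.0])
        m = compute_metrics(-obs, obs)
        assert m.cc == pytest.approx(-1.0)

    def test_constant_series_cc_missing(self):
        m = compute_metrics([1.0, 1.0], [0.5, 1.5])
        assert np.isnan(m.cc)

    def test_rmse_dominates_bias(self):
        rng = np.random.default_rng(0)
        obs = rng.normal(size=100)
        pred = obs + rng.normal(0.3, 0.2, size=100)
        m = compute_metrics(pred, obs)
        assert m.rmse >= abs(m.bias)

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        obs, pred = rng.normal(size=50), rng.normal(size=50)
        m1 = compute_metrics(pred, obs)
        m2 = compute_metrics(pred + 3.7, obs + 3.7)
        assert m1.bias == pytest.approx(m2.bias, abs=1e-12)
        assert m1.rmse == pytest.approx(m2.rmse, abs=1e-12)

    def test_cc_affine_invariance(self):
        rng = np.random.default_rng(2)
        obs, pred = rng.normal(size=50), rng.normal(size=50)
        m1 = compute_metrics(pred, obs)
        m2 = compute_metrics(2.5 * pred - 1.0, obs)
        assert m1.cc == pytest.approx(m2.cc, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([1.0], [1.0, 2.0])

    def test_uniform_weights_match_unweighted(self):
        rng = np.random.default_rng(8)
        obs, pred = rng.normal(size=30), rng.normal(size=30)
        m0 = compute_metrics(pred, obs)
        m1 = compute_metrics(pred, obs, weights=np.full(30, 0.4))
        assert m1.bias == pytest.approx(m0.bias, abs=1e-12)
        assert m1.rmse == pytest.approx(m0.rmse, abs=1e-12)
        assert m1.cc == pytest.approx(m0.cc, abs=1e-12)

    def test_weighted_bias_hand_case(self):
        # residuals (1, 0) with weights (3, 1): bias = 0.75
        m = compute_metrics([0.0, 0.0], [1.0, 0.0], weights=[3.0, 1.0])
        assert m.bias == pytest.approx(0.75)
        assert m.rmse == pytest.approx(np.sqrt(0.75))

    def test_area_weighting_changes_daily_series(self):
        df = pd.DataFrame(
            {
                "time": [0, 0],
                "lat": [0.0, 60.0],  # cos weights 1.0 and 0.5
                "chla": [1.0, 0.0],
                "pred": [0.0, 0.0],
            }
        )
        flat = daily_metric_series(df)
        weighted = daily_metric_series(df, area_weighted=True)
        assert flat.loc[0, "bias"] == pytest.approx(0.5)
        assert weighted.loc[0, "bias"] == pytest.approx(1.0 / 1.5)


class TestFilterThreshold:
    def test_boundary_inclusive(self):
        df = pd.DataFrame({"chla": [0.5, 1.0, 1.5]})
        kept = filter_threshold(df, 1.0)
        assert kept["chla"].tolist() == [0.5, 1.0]

    def test_all_below_is_identity(self):
        df = pd.DataFrame({"chla": [0.1, 0.2]})
        assert filter_threshold(df).equals(df)

    def test_synthetic_marginal_removes_fraction_near_two_permille(self):
        values = sample_chla(200_000, seed=5)
        df = pd.DataFrame({"chla": values})
        removed = 1.0 - len(filter_threshold(df)) / len(df)
        assert 0.001 <= removed <= 0.004


class TestBinnedStats:
    def test_single_bin_equals_global(self):
        rng = np.random.default_rng(3)
        obs = rng.uniform(0, 1, size=200)
        pred = obs + rng.normal(0, 0.1, size=200)
        bs = binned_stats(pred, obs, [0.0, 1.0])
        m = compute_metrics(pred, obs)
        row = bs.table.iloc[0]
        assert row["count"] == 200
        assert row["bias"] == pytest.approx(m.bias, abs=1e-12)
        assert row["rmse"] == pytest.approx(m.rmse, abs=1e-12)

    def test_constant_residual_zero_bin_std(self):
        obs = np.array([0.1, 0.2, 0.3])
        bs = binned_stats(obs - 0.05, obs, [0.0, 0.5])
        assert bs.table.iloc[0]["resid_std"] == pytest.approx(0.0, abs=1e-15)

    def test_hand_built_two_bins(self):
        obs = np.array([0.1, 0.2, 0.6, 0.8])
        pred = np.array([0.2, 0.2, 0.5, 0.6])
        bs = binned_stats(pred, obs, [0.0, 0.5, 1.0])
        assert bs.counts.tolist() == [2, 2]
        assert bs.table.iloc[0]["bias"] == pytest.approx((-0.1 + 0.0) / 2)
        assert bs.table.iloc[1]["bias"] == pytest.approx((0.1 + 0.2) / 2)
        assert bs.table["fraction"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_overflow_bin_reported_and_counts_sum(self):
        obs = np.array([0.1, 0.4, 2.5])
        pred = np.zeros(3)
        bs = binned_stats(pred, obs, [0.0, 0.5, 1.0])
        assert bs.table["count"].sum() == 3
        assert bool(bs.table.iloc[-1]["overflow"])
        assert bs.table["fraction"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_last_bin_closed_at_top_edge(self):
        obs = np.array([1.0])
        bs = binned_stats(np.zeros(1), obs, [0.0, 0.5, 1.0])
        assert bs.table.iloc[1]["count"] == 1
        assert not bs.table["overflow"].any()

    def test_count_weighted_bin_mse_equals_global(self):
        rng = np.random.default_rng(4)
        obs = rng.uniform(0, 1, size=500)
        pred = obs + rng.normal(0, 0.2, size=500)
        bs = binned_stats(pred, obs, np.linspace(0, 1, 6))
        t = bs.table
        weighted = (t["count"] * t["rmse"] ** 2).sum() / t["count"].sum()
        global_mse = np.mean((obs - pred) ** 2)
        assert weighted == pytest.approx(global_mse, abs=1e-10)

    def test_bad_edges_rejected(self):
        with pytest.raises(ValueError):
            binned_stats([0.1], [0.1], [1.0, 0.5])


class TestDailySeries:
    @staticmethod
    def frame():
        return pd.DataFrame(
            {
                "time": [0, 0, 1, 1, 2],
                "chla": [0.2, 0.4, 0.3, 1.5, 0.2],
                "pred": [0.2, 0.4, 0.2, 1.4, 0.1],
            }
        )

    def test_perfect_predictions_zero_rmse(self):
        df = self.frame()
        df["pred"] = df["chla"]
        s = daily_metric_series(df)
        assert np.allclose(s["rmse"], 0.0)

    def test_constant_residual_rmse(self):
        df = self.frame()
        df["pred"] = df["chla"] - 0.25
        s = daily_metric_series(df)
        assert np.allclose(s["rmse"], 0.25)
        assert np.allclose(s["bias"], 0.25)

    def test_filter_changes_only_days_with_high_values(self):
        df = self.frame()
        full = daily_metric_series(df)
        filt = daily_metric_series(df, apply_filter=True)
        # day 1 contains obs 1.5 > 1.0; days 0 and 2 unchanged
        assert full.loc[0].equals(filt.loc[0])
        assert full.loc[2].equals(filt.loc[2])
        assert full.loc[1, "n"] == 2 and filt.loc[1, "n"] == 1

    def test_empty_day_flagged_missing(self):
        df = self.frame()
        df.loc[df["time"] == 2, "chla"] = np.nan
        s = daily_metric_series(df)
        assert s.loc[2, "n"] == 0
        assert np.isnan(s.loc[2, "rmse"])
        assert len(s) == 3  # one entry per day present


class TestSpatialBias:
    def test_perfect_predictions_zero_field(self):
        obs = np.random.default_rng(5).uniform(0, 1, size=(4, 3, 3))
        field = spatial_bias_map(obs, obs.copy())
        np.testing.assert_allclose(field, 0.0)

    def test_single_cell_constant_residual(self):
        obs = np.full((5, 2, 2), 0.3)
        pred = obs.copy()
        pred[:, 0, 1] -= 0.1
        field = spatial_bias_map(obs, pred)
        assert field[0, 1] == pytest.approx(0.1, abs=1e-12)
        assert field[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_masked_cells_stay_masked(self):
        obs = np.full((3, 2, 2), 0.3)
        obs[:, 1, 1] = np.nan
        field = spatial_bias_map(obs, np.full((3, 2, 2), 0.25))
        assert np.isnan(field[1, 1])
        assert field[0, 0] == pytest.approx(0.05)


class TestSweepAndUncertainty:
    def test_single_k_returned(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(300, 2))
        y = x[:, 0]
        opts = TrainingOptions(max_epochs=5, patience=5)
        res = hidden_size_sweep(x[0::2], y[0::2], x[1::2], y[1::2], [4], opts=opts)
        assert res.best_k == 4 and len(res.test_rmse) == 1

    def test_tie_breaks_to_smaller_k(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(200, 1))
        y = x[:, 0]
        opts = TrainingOptions(max_epochs=3, patience=3)
        # same k twice: identical RMSE, the first (equal-smallest) must win
        res = hidden_size_sweep(x[0::2], y[0::2], x[1::2], y[1::2], [3, 3], opts=opts)
        assert res.best_k == 3
        assert res.test_rmse[0] == res.test_rmse[1]

    def test_decomposition_invariants(self):
        d = decompose_rmse(0.18, 0.002)
        assert d.eps == pytest.approx(0.178)
        assert d.eps >= 0 and d.eps <= d.rmse
        # eps_app capped at total
        d2 = decompose_rmse(0.001, 0.002)
        assert d2.eps == 0.0 and d2.eps_app == 0.001

    def test_epsilon_app_rejects_degenerate_inputs(self):
        with pytest.raises(ValueError):
            estimate_epsilon_app(np.ones(2000))
        with pytest.raises(ValueError):
            estimate_epsilon_app(np.arange(10.0))
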