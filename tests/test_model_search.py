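import dataclasses

import numpy as np
import pandas as pd
import pytest

import qsrrkit as qk
from qsrrkit.errors import (
    DegenerateTargetError,
    InsufficientDataError,
    ValidationError,
)
from qsrrkit.model_search import _pick_winner


def _noiseless_linear(n=40, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.standard_normal((n, 3)), columns=["f1", "f2", "f3"],
        index=[f"c{i}" for i in range(n)],
    )
    y = pd.Series(3 * X["f1"] - X["f2"] + 0.5 + 10, index=X.index)
    return X, y


class TestRandomizeOrder:
    def test_same_seed_same_order(self, alkanol_table):
        a = qk.randomize_order(alkanol_table, 7)
        b = qk.randomize_order(alkanol_table, 7)
        assert a.names == b.names

    def test_single_row_unchanged(self):
        t = qk.CompoundTable([qk.CompoundRecord("only", "CCO", 1.0)])
        assert qk.randomize_order(t, 3).names == ["only"]

    def test_permutation_is_bijection(self, alkanol_table):
        shuffled = qk.randomize_order(alkanol_table, 5)
        assert sorted(shuffled.names) == sorted(alkanol_table.names)
        assert shuffled.names != alkanol_table.names

    def test_xy_rows_stay_aligned(self, linear_matrix):
        X, y, _ = linear_matrix
        Xr, yr = qk.randomize_xy(X, y, 9)
        assert list(Xr.index) == list(yr.index)
        assert sorted(Xr.index) == sorted(X.index)


class TestSelectFeatures:
    def test_single_feature_returned(self, fast_cfg):
        X, y = _noiseless_linear()
        Z = X[["f1"]]
        assert qk.select_features(Z, y, fast_cfg) == ["f1"]

    @pytest.mark.parametrize("k", [6, 9])
    def test_forced_n_features_returns_exactly_k(self, linear_matrix, fast_cfg, k):
        X, y, _ = linear_matrix
        cfg = dataclasses.replace(fast_cfg, forced_n_features=k)
        assert len(qk.select_features(X, y, cfg)) == k

    def test_too_few_rows_is_error(self, fast_cfg):
        X, y = _noiseless_linear(n=8)
        with pytest.raises(InsufficientDataError):
            qk.select_features(X, y, fast_cfg)

    def test_informative_features_survive_selection(self, linear_matrix, fast_cfg):
        X, y, truth = linear_matrix
        selected = qk.select_features(X, y, fast_cfg)
        assert set(truth.informative_features) <= set(selected)


class TestSearchModel:
    def test_noiseless_linear_picks_linear_with_near_perfect_r2(self, fast_cfg):
        X, y = _noiseless_linear()
        kind, params, scores = qk.search_model(X, y, fast_cfg)
        assert kind == "linear" and params == {}
        linear_row = scores[scores["learner"] == "linear"].iloc[0]
        assert linear_row["mean_r2"] >= 0.999

    def test_fixed_method_considers_only_that_candidate(self, fast_cfg):
        X, y = _noiseless_linear()
        cfg = dataclasses.replace(fast_cfg, method="svr")
        kind, params, scores = qk.search_model(X, y, cfg)
        assert kind == "svr" and {"C", "gamma"} <= set(params)
        assert set(scores["learner"]) == {"svr"}
        assert len(scores) == cfg.grid_points**2

    def test_constant_target_is_degenerate(self, fast_cfg):
        X, _ = _noiseless_linear()
        y = pd.Series(5.0, index=X.index)
        with pytest.raises(DegenerateTargetError):
            qk.search_model(X, y, fast_cfg)

    def test_tie_breaks_follow_simplicity_order(self):
        rows = [
            {"learner": "random_forest", "mean_r2": 0.9, "mean_mae": 0.1},
            {"learner": "svr", "mean_r2": 0.9, "mean_mae": 0.1},
            {"learner": "linear", "mean_r2": 0.9, "mean_mae": 0.1},
        ]
        assert _pick_winner(rows)["learner"] == "linear"
        rows[0]["mean_mae"] = 0.05  # lower MAE beats simplicity
        assert _pick_winner(rows)["learner"] == "random_forest"
        rows[1]["mean_r2"] = 0.95  # higher r2 beats everything
        assert _pick_winner(rows)["learner"] == "svr"


class TestOuterCV:
    def test_noiseless_linear_recovered_in_every_fold(self, fast_cfg):
        X, y = _noiseless_linear(n=50)
        report = qk.outer_cv(X, y, fast_cfg)
        assert report.n_folds == fast_cfg.outer_folds
        assert all(r2 >= 0.999 for r2 in report.fold_r2)
        assert report.mean_mae < 0.01

    def test_fixed_seed_reproduces_report(self, linear_matrix, fast_cfg):
        X, y, _ = linear_matrix
        a = qk.outer_cv(X, y, fast_cfg)
        b = qk.outer_cv(X, y, fast_cfg)
        assert a.fold_r2 == b.fold_r2
        assert a.fold_mae == b.fold_mae
        assert a.fold_learner == b.fold_learner
        assert a.fold_n_features == b.fold_n_features

    def test_fewer_rows_than_minimum_is_error(self, fast_cfg):
        X, y = _noiseless_linear(n=11)  # folds of 8-9 training rows < 10
        with pytest.raises(InsufficientDataError):
            qk.outer_cv(X.iloc[:4], y.iloc[:4], fast_cfg)

    def test_pure_noise_target_scores_near_zero(self, fast_cfg):
        """With no structure linking descriptors to rt, held-out r2 stays low."""
        rng = np.random.default_rng(17)
        X = pd.DataFrame(
            rng.standard_normal((60, 6)), columns=[f"f{j}" for j in range(6)],
            index=[f"c{i}" for i in range(60)],
        )
        y = pd.Series(10 + rng.normal(0, 1.0, 60), index=X.index)
        report = qk.outer_cv(X, y, fast_cfg)
        assert report.mean_r2 <= 0.2

    def test_report_aggregates(self):
        report = qk.CVReport(fold_r2=[0.9, 1.0], fold_mae=[0.2, 0.4])
        assert report.mean_r2 == pytest.approx(0.95)
        assert report.median_r2 == pytest.approx(0.95)
        assert report.mean_mae == pytest.approx(0.3)
        assert report.mae_sd == pytest.approx(np.std([0.2, 0.4], ddof=1))


class TestFitFinal:
    def test_training_range_bookkeeping(self, linear_matrix, fast_cfg):
        X, y, _ = linear_matrix
        model = qk.fit_final(X, y, fast_cfg)
        assert model.train_rt_min == y.min()
        assert model.train_rt_max == y.max()
        assert set(model.selected_features) <= set(X.columns)
        assert (model.feature_sds > 0).all()

    def test_in_sample_r2_dominates_cv_r2(self, linear_matrix, fast_cfg):
        from sklearn.metrics import r2_score

        X, y, _ = linear_matrix
        model, report = qk.train(X, y, fast_cfg)
        in_sample = r2_score(y, model.predict_matrix(X))
        assert in_sample >= report.mean_r2 - 1e-9

    def test_forced_feature_count_propagates(self, linear_matrix, fast_cfg):
        X, y, _ = linear_matrix
        cfg = dataclasses.replace(fast_cfg, forced_n_features=9)
        model = qk.fit_final(X, y, cfg)
        assert len(model.selected_features) == 9

    def test_unrestricted_no_worse_than_forced_small_subset(self, linear_matrix, fast_cfg):
        """Free subset-size choice should not lose to an undersized forced model."""
        X, y, _ = linear_matrix
        cut = 45
        X_tr, y_tr, X_te, y_te = X.iloc[:cut], y.iloc[:cut], X.iloc[cut:], y.iloc[cut:]
        cfg = dataclasses.replace(fast_cfg, method="linear")
        free = qk.fit_final(X_tr, y_tr, cfg)
        forced = qk.fit_final(X_tr, y_tr, dataclasses.replace(cfg, forced_n_features=2))
        mae = lambda m: float((m.predict_matrix(X_te) - y_te).abs().mean())
        assert mae(free) <= mae(forced) + 0.1


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"method": "boosting"},
            {"outer_folds": 1},
            {"svr_c_bounds": (0.0, 1.0)},
            {"svr_c_bounds": (10.0, 1.0)},
            {"forced_n_features": 0},
        ],
    )
    def test_invalid_settings_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            qk.SearchConfig(**kwargs)
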