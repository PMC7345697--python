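import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import qsrrkit as qk
from qsrrkit.descriptors import DescriptorFailure
from qsrrkit.errors import DescriptorError, ValidationError
from oracle_filters import brute_force_filters, pearson_pairwise


def _table(*pairs):
    return qk.CompoundTable([qk.CompoundRecord(n, s, None) for n, s in pairs])


class TestComputeDescriptors:
    def test_ethanol_reference_values(self):
        """Pinned against a direct reference descriptor run on ethanol."""
        X, failures = qk.compute_descriptors(_table(("ethanol", "CCO")))
        assert not failures
        row = X.loc["ethanol"]
        assert row["SLogP"] == pytest.approx(-0.0014, abs=1e-6)
        assert row["MolWt"] == pytest.approx(46.069, abs=1e-3)
        assert row["HeavyAtomCount"] == 3
        assert row["NumHDonors"] == 1
        assert row["TPSA"] == pytest.approx(20.23, abs=1e-2)

    def test_invalid_smiles_reported_and_excluded(self):
        X, failures = qk.compute_descriptors(_table(("ok", "CCO"), ("bad", "C(")))
        assert list(X.index) == ["ok"]
        assert [f.name for f in failures] == ["bad"]

    def test_all_invalid_is_hard_error(self):
        with pytest.raises(DescriptorError):
            qk.compute_descriptors(_table(("bad1", "C("), ("bad2", ")(")))

    def test_alkanol_slogp_increases_with_chain_length(self):
        pairs = [(f"c{k}", "C" * k + "O") for k in range(2, 11)]
        X, _ = qk.compute_descriptors(_table(*pairs))
        slogp = X["SLogP"].to_numpy()
        assert np.all(np.diff(slogp) > 0)

    def test_user_descriptors_take_precedence_on_collision(self):
        table = _table(("a", "CCO"), ("b", "CCCO"))
        table.extra_descriptors = pd.DataFrame(
            {"SLogP": [99.0, 98.0], "userD": [1.0, 2.0]}, index=["a", "b"]
        )
        X, _ = qk.compute_descriptors(table)
        assert X.loc["a", "SLogP"] == 99.0
        assert X.loc["b", "userD"] == 2.0
        assert not X.columns.duplicated().any()


class TestIndividualFilters:
    def test_near_constant_boundary_is_inclusive(self):
        col = np.array([1.0] * 18 + [2.0, 3.0])  # 18/20 = 0.90 exactly
        X = pd.DataFrame({"boundary": col, "spread": np.arange(20.0)})
        kept, dropped = qk.drop_near_constant(X, 0.90)
        assert dropped == ["boundary"]
        assert list(kept.columns) == ["spread"]

    def test_constant_column_dropped_distinct_kept(self):
        X = pd.DataFrame({"const": np.ones(20), "distinct": np.arange(20.0)})
        _, dropped = qk.drop_near_constant(X, 0.90)
        assert dropped == ["const"]

    def test_high_missing_boundary_is_inclusive(self):
        col = np.r_[np.full(15, np.nan), np.arange(5.0)]  # 15/20 = 0.75 exactly
        X = pd.DataFrame({"boundary": col, "full": np.arange(20.0)})
        _, dropped = qk.drop_high_missing(X, 0.75)
        assert dropped == ["boundary"]

    def test_fully_missing_dropped_fully_observed_kept(self):
        X = pd.DataFrame({"gone": np.full(10, np.nan), "full": np.arange(10.0)})
        kept, dropped = qk.drop_high_missing(X, 0.75)
        assert dropped == ["gone"] and list(kept.columns) == ["full"]

    def test_duplicated_column_dropped_with_earlier_partner(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(30)
        X = pd.DataFrame({"x": x, "z": rng.standard_normal(30), "x_copy": x})
        kept, dropped = qk.drop_correlated(X, 0.90)
        assert dropped == [("x_copy", "x")]
        assert list(kept.columns) == ["x", "z"]

    def test_affine_dependence_dropped(self):
        x = np.arange(20.0)
        X = pd.DataFrame({"x": x, "y": 2 * x + 1})
        _, dropped = qk.drop_correlated(X, 0.90)
        assert dropped == [("y", "x")]

    def test_independent_normals_both_kept(self):
        rng = np.random.default_rng(42)
        a, b = rng.standard_normal(100), rng.standard_normal(100)
        assert abs(pearson_pairwise(a, b)) < 0.9  # oracle confirms independence
        kept, dropped = qk.drop_correlated(pd.DataFrame({"a": a, "b": b}), 0.90)
        assert not dropped and list(kept.columns) == ["a", "b"]


class TestApplyFilters:
    def test_three_planted_columns_three_distinct_reasons(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.standard_normal((20, 4)), columns=list("abcd"))
        X["gone"] = np.nan
        X["const"] = 7.0
        X["dup"] = X["a"]
        _, report = qk.apply_filters(X)
        assert report.dropped == {
            "gone": "high_missing",
            "const": "near_constant",
            "dup": "correlated(a)",
        }
        assert report.kept_count == 4

    def test_clean_random_matrix_drops_nothing(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.standard_normal((50, 8)), columns=[f"c{j}" for j in range(8)])
        # oracle: no pair at or above threshold
        kept, dropped = brute_force_filters(X)
        assert not dropped
        _, report = qk.apply_filters(X)
        assert not report.dropped

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.standard_normal((25, 6)), columns=[f"c{j}" for j in range(6)])
        X["dup"] = X["c0"] * 3 + 1
        once, _ = qk.apply_filters(X)
        twice, second = qk.apply_filters(once)
        assert not second.dropped
        pd.testing.assert_frame_equal(once, twice)

    def test_dropped_plus_kept_partitions_input(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.standard_normal((15, 5)), columns=[f"c{j}" for j in range(5)])
        X["const"] = 0.0
        _, report = qk.apply_filters(X)
        assert sorted(report.kept + list(report.dropped)) == sorted(X.columns)

    @given(seed=st.integers(0, 500))
    def test_row_order_invariance(self, seed):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.standard_normal((12, 5)), columns=[f"c{j}" for j in range(5)])
        X["dup"] = X["c1"]
        _, rep1 = qk.apply_filters(X)
        perm = rng.permutation(len(X))
        _, rep2 = qk.apply_filters(X.iloc[perm])
        assert rep1.dropped == rep2.dropped and rep1.kept == rep2.kept

    def test_all_dropped_is_hard_error(self):
        X = pd.DataFrame({"a": np.ones(10), "b": np.full(10, np.nan)})
        with pytest.raises(ValidationError):
            qk.apply_filters(X)

    @given(seed=st.integers(0, 1000))
    def test_matches_brute_force_oracle(self, seed):
        from oracle_filters import random_planted_matrix

        X = random_planted_matrix(seed)
        oracle_kept, oracle_dropped = brute_force_filters(X)
        filtered, report = qk.apply_filters(X)
        assert list(filtered.columns) == oracle_kept
        assert report.dropped == oracle_dropped


class TestImputer:
    def test_median_fill(self):
        X = pd.DataFrame({"a": [1.0, 2.0, np.nan, 4.0]})
        medians = qk.fit_imputer(X)
        assert medians["a"] == 2.0
        filled = qk.apply_imputer(medians, X)
        assert filled["a"].tolist() == [1.0, 2.0, 2.0, 4.0]

    def test_identity_when_complete(self):
        X = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        pd.testing.assert_frame_equal(qk.apply_imputer(qk.fit_imputer(X), X), X)

    def test_unknown_column_is_contract_error(self):
        medians = qk.fit_imputer(pd.DataFrame({"a": [1.0, 2.0]}))
        with pytest.raises(ValidationError, match="unseen"):
            qk.apply_imputer(medians, pd.DataFrame({"mystery": [1.0]}))
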