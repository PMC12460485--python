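"""CART engine: split search vs brute force, donors, invariants."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synthpanel.cart import (
    TreeHyperparams,
    assign_leaf,
    fit_tree,
    synthesize_variable,
)


def brute_force_first_split(X: pd.DataFrame, y: np.ndarray, min_leaf: int):
    """Independent oracle: globally best (sse, predictor, threshold) split
    by trying every predictor and every midpoint threshold; ties resolved
    to the lowest predictor index then smallest threshold."""
    best = None
    for j, col in enumerate(X.columns):
        vals = X[col].to_numpy(dtype=float)
        for thr in sorted(set((a + b) / 2 for a, b in itertools.pairwise(sorted(set(vals))))):
            left = y[vals <= thr]
            right = y[vals > thr]
            if len(left) < min_leaf or len(right) < min_leaf:
                continue
            sse = ((left - left.mean()) ** 2).sum() + ((right - right.mean()) ** 2).sum()
            key = (round(sse, 9), j, thr)
            if best is None or key < best:
                best = key
    return best


class TestFit:
    def test_constant_response_gives_root_only_tree(self):
        X = pd.DataFrame({"x": np.arange(20.0)})
        tree = fit_tree(X, np.full(20, 7.0), "continuous")
        assert tree.n_leaves == 1
        assert list(tree.leaves()[0]) == [7.0] * 20

    def test_step_function_split_found_by_exhaustive_scan(self):
        X = pd.DataFrame({"x": np.arange(1.0, 11.0)})
        y = np.where(X["x"] <= 5, 0.0, 100.0)
        tree = fit_tree(X, y, "continuous", TreeHyperparams(min_leaf=5))
        assert tree.root.predictor == "x"
        assert tree.root.threshold == pytest.approx(5.5)
        assert tree.n_leaves == 2

    def test_min_leaf_blocks_perfect_split(self):
        X = pd.DataFrame({"x": np.arange(1.0, 9.0)})
        y = np.where(X["x"] <= 4, 0.0, 100.0)
        tree = fit_tree(X, y, "continuous", TreeHyperparams(min_leaf=5, min_split=10))
        assert tree.n_leaves == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fit_tree(pd.DataFrame({"x": []}), np.array([]), "continuous")

    def test_categorical_predictor_splits_by_mean_ordering(self):
        # level means: a=0, b=10, c=100 -> best split isolates c
        X = pd.DataFrame({"g": ["a", "b", "c"] * 4})
        y = np.array([0.0, 10.0, 100.0] * 4)
        tree = fit_tree(X, y, "continuous", TreeHyperparams(min_leaf=2, min_split=4))
        assert tree.root.is_categorical
        sides = [tree.root.left_levels, tree.root.right_levels]
        assert frozenset({"c"}) in sides

    @given(st.integers(min_value=0, max_value=500))
    @settings(max_examples=25, deadline=None)
    def test_first_split_equals_brute_force_on_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 13))
        X = pd.DataFrame(
            {"x0": rng.integers(0, 6, n).astype(float), "x1": rng.integers(0, 6, n).astype(float)}
        )
        y = rng.integers(0, 10, n).astype(float)
        hp = TreeHyperparams(min_leaf=2, min_split=4)
        oracle = brute_force_first_split(X, y, hp.min_leaf)
        tree = fit_tree(X, y, "continuous", hp)
        if oracle is None or ((y - y.mean()) ** 2).sum() - oracle[0] < 1e-9:
            assert tree.root.is_leaf or tree.root.decrease < 1e-6
        else:
            assert tree.root.predictor_index == oracle[1]
            assert tree.root.threshold == pytest.approx(oracle[2])


class TestAssign:
    def test_root_only_tree_maps_everything_to_root(self):
        tree = fit_tree(pd.DataFrame({"x": [1.0, 2.0]}), np.array([5.0, 5.0]), "continuous")
        assert assign_leaf(tree, {"x": -100.0}) == assign_leaf(tree, {"x": 100.0}) == 0

    def test_step_tree_assignment_matches_partition(self):
        X = pd.DataFrame({"x": np.arange(1.0, 11.0)})
        y = np.where(X["x"] <= 5, 0.0, 100.0)
        tree = fit_tree(X, y, "continuous", TreeHyperparams(min_leaf=5))
        ids = tree.apply(X)
        assert len(set(ids[:5])) == 1 and len(set(ids[5:])) == 1
        assert ids[0] != ids[9]
        # determinism: same row twice, same leaf
        assert assign_leaf(tree, {"x": 3.0}) == assign_leaf(tree, {"x": 3.0})

    def test_unseen_category_routes_to_majority_side(self):
        X = pd.DataFrame({"g": ["a"] * 6 + ["b"] * 2})
        y = np.array([0.0] * 6 + [100.0] * 2)
        tree = fit_tree(X, y, "continuous", TreeHyperparams(min_leaf=2, min_split=4))
        assert not tree.root.is_leaf
        majority_leaf = assign_leaf(tree, {"g": "a"})
        assert assign_leaf(tree, {"g": "zzz"}) == majority_leaf

    def test_missing_predictor_value_rejected(self):
        X = pd.DataFrame({"x": np.arange(1.0, 11.0)})
        y = np.where(X["x"] <= 5, 0.0, 100.0)
        tree = fit_tree(X, y, "continuous", TreeHyperparams(min_leaf=5))
        with pytest.raises(ValueError):
            tree.apply(pd.DataFrame({"x": [np.nan]}))


class TestSynthesize:
    def test_single_leaf_constant_response_returns_constant(self):
        X = pd.DataFrame({"x": np.arange(10.0)})
        tree = fit_tree(X, np.full(10, 3.5), "continuous")
        out = synthesize_variable(tree, X, np.random.default_rng(0))
        assert (out == 3.5).all()

    def test_leaf_membership_over_seeded_draws(self):
        X = pd.DataFrame({"x": [1.0, 2.0, 9.0, 10.0] * 3})
        y = np.array([1.0, 2.0, 9.0, 10.0] * 3)
        tree = fit_tree(X, y, "continuous", TreeHyperparams(min_leaf=2, min_split=4))
        low_rows = pd.DataFrame({"x": [1.5] * 100})
        for seed in range(5):
            vals = synthesize_variable(tree, low_rows, np.random.default_rng(seed))
            assert set(vals) <= {1.0, 2.0}

    def test_every_synthetic_value_is_an_observed_donor(self, small_panel):
        rows = small_panel.dropna(subset=["ChronicLoad"])
        X = rows[["Injury", "PlayerID"]]
        y = rows["AcuteLoad"].to_numpy()
        tree = fit_tree(X, y, "continuous", categorical=["PlayerID"])
        rng = np.random.default_rng(42)
        observed = set(y)
        for _ in range(5):
            draws = synthesize_variable(tree, X, rng)
            assert set(draws) <= observed
        assert len(X) >= 200  # ">= 1000 draws" overall across repeats

    def test_proper_synthesis_still_draws_observed_values(self):
        X = pd.DataFrame({"x": np.arange(20.0)})
        y = np.arange(20.0) * 2
        tree = fit_tree(X, y, "continuous", TreeHyperparams(min_leaf=5))
        vals = synthesize_variable(tree, X, np.random.default_rng(1), proper=True)
        assert set(vals) <= set(y)


class TestInvariants:
    def test_leaves_partition_training_response_multiset(self, small_panel):
        rows = small_panel.dropna(subset=["ChronicLoad"])
        tree = fit_tree(
            rows[["Injury", "PlayerID"]],
            rows["AcuteLoad"].to_numpy(),
            "continuous",
            categorical=["PlayerID"],
        )
        pooled = np.sort(np.concatenate(list(tree.leaves().values())))
        assert np.allclose(pooled, np.sort(rows["AcuteLoad"].to_numpy()))
        assert all(len(v) >= tree.hyperparams.min_leaf for v in tree.leaves().values())

    def test_accepted_splits_strictly_decrease_impurity(self, small_panel):
        rows = small_panel.dropna(subset=["ChronicLoad"])
        tree = fit_tree(
            rows[["Injury", "PlayerID", "WeekID"]],
            rows["AcuteLoad"].to_numpy(),
            "continuous",
            categorical=["PlayerID"],
        )
        for node in tree.internal_nodes():
            assert node.decrease > 0

    def test_distribution_preserved_no_worse_than_bootstrap(self, small_panel):
        from scipy.stats import ks_2samp

        rows = small_panel.dropna(subset=["ChronicLoad"])
        X = rows[["Injury", "PlayerID"]]
        y = rows["AcuteLoad"].to_numpy()
        tree = fit_tree(X, y, "continuous", categorical=["PlayerID"])
        ks_synth, ks_boot = [], []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            ks_synth.append(ks_2samp(synthesize_variable(tree, X, rng), y).statistic)
            boot = y[rng.integers(0, len(y), len(y))]
            ks_boot.append(ks_2samp(boot, y).statistic)
        assert np.mean(ks_synth) <= np.mean(ks_boot) + 0.01

    def test_gini_tree_on_binary_response(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(size=200)
        y = (x > 0.6).astype(int)
        tree = fit_tree(pd.DataFrame({"x": x}), y, "categorical")
        assert tree.root.threshold == pytest.approx(0.6, abs=0.05)
        draws = synthesize_variable(tree, pd.DataFrame({"x": [0.9] * 50}), np.random.default_rng(1))
        assert draws.mean() > 0.9
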