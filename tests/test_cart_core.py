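"""Variance-reduction split search, tree growth, and prediction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phytocart.dataio import ContractError
from phytocart.cart_core import FitSettings, best_split, grow_tree, node_variance, predict

from conftest import brute_force_best_split, make_stump, make_table, random_table


@pytest.mark.parametrize(
    "y,expected",
    [([2, 4, 6], 8 / 3), ([5, 5, 5], 0.0), ([0, 10], 25.0), ([7], 0.0)],
)
def test_node_variance_uses_divisor_n(y, expected):
    assert node_variance(y) == pytest.approx(expected, abs=1e-12)


def test_node_variance_empty_is_contract_error():
    with pytest.raises(ContractError):
        node_variance([])


def test_best_split_on_step_function(loose_settings):
    ev = best_split(pd.DataFrame({"x": [1.0, 2, 3, 4]}), np.array([0.0, 0, 10, 10]), loose_settings)
    assert (ev.variable, ev.threshold, ev.n_left, ev.n_right) == ("x", 2.5, 2, 2)
    assert ev.decrease == pytest.approx(25.0, abs=1e-12)


def test_best_split_constant_response_is_none(loose_settings):
    assert best_split(pd.DataFrame({"x": [1.0, 2, 3]}), np.array([4.0, 4, 4]), loose_settings) is None


def test_best_split_constant_predictors_is_none(loose_settings):
    assert best_split(pd.DataFrame({"x": [2.0, 2, 2]}), np.array([0.0, 1, 2]), loose_settings) is None


def test_best_split_prefers_stronger_variable(loose_settings):
    X = pd.DataFrame({"x1": [1.0, 2, 3, 4], "x2": [1.0, 3, 2, 4]})
    y = np.array([0.0, 0, 10, 10])
    ev = best_split(X, y, loose_settings)
    assert ev.variable == "x1" and ev.threshold == 2.5
    # independent confirmation that x1's candidate dominates every x2 candidate
    brute = brute_force_best_split(X, y)
    assert brute[1] == "x1" and brute[0] == pytest.approx(25.0)


def test_tied_variables_break_by_declared_order():
    X = pd.DataFrame({"b": [1.0, 2, 3, 4], "a": [1.0, 2, 3, 4]})
    y = np.array([0.0, 0, 10, 10])
    ev = best_split(X, y, FitSettings(min_leaf=1, min_split=2, variable_order=("a", "b")))
    assert ev.variable == "a"
    ev = best_split(X, y, FitSettings(min_leaf=1, min_split=2, variable_order=("b", "a")))
    assert ev.variable == "b"


def test_tied_thresholds_break_to_smaller(loose_settings):
    # thresholds 1.5 and 3.5 give identical decrease by symmetry
    ev = best_split(pd.DataFrame({"x": [1.0, 2, 3, 4]}), np.array([0.0, 10, 10, 0]), loose_settings)
    assert ev.threshold == 1.5


def test_min_leaf_restricts_candidates():
    ev = best_split(
        pd.DataFrame({"x": [1.0, 2, 3, 4]}),
        np.array([100.0, 0, 0, 0]),
        FitSettings(min_leaf=2, min_split=4),
    )
    assert ev.threshold == 2.5  # 1.5 would isolate a single sample


def test_grow_tree_step_function(toy_step_table, loose_settings):
    tree = grow_tree(toy_step_table, "y", ["x"], loose_settings)
    assert tree.n_leaves == 2
    leaves = sorted(tree.nodes[i].node_mean for i in tree.leaf_ids())
    assert leaves == [0.0, 10.0]
    assert tree.root.node_sse / tree.root.n_samples == pytest.approx(25.0)


def test_grow_tree_constant_response_is_single_leaf(loose_settings):
    table = make_table({"x": [1.0, 2, 3], "y": [4.0, 4, 4]}, ["x"], ["y"])
    tree = grow_tree(table, "y", ["x"], loose_settings)
    assert tree.n_leaves == 1 and tree.root.is_leaf


def test_grow_tree_drops_incomplete_rows(loose_settings):
    table = make_table({"x": [1.0, 2, np.nan, 4], "y": [0.0, 0, 10, 10]}, ["x"], ["y"])
    tree = grow_tree(table, "y", ["x"], loose_settings)
    assert tree.root.n_samples == 3


def test_full_growth_attains_r2_one_on_distinct_x(loose_settings):
    rng = np.random.default_rng(7)
    table = random_table(rng, 40, 2)
    tree = grow_tree(table, "y", settings=loose_settings)
    preds = predict(tree, table.data)
    assert np.allclose(preds, table.data["y"], atol=1e-12)


def test_duplicating_every_row_preserves_chosen_split():
    rng = np.random.default_rng(11)
    for _ in range(20):
        table = random_table(rng, rng.integers(6, 20), 2)
        X, y = table.data[table.predictors], table.data["y"].to_numpy()
        Xd = pd.concat([X, X], ignore_index=True)
        yd = np.concatenate([y, y])
        s = FitSettings(min_leaf=1, min_split=2)
        ev1, ev2 = best_split(X, y, s), best_split(Xd, yd, s)
        assert (ev1 is None) == (ev2 is None)
        if ev1 is not None:
            assert (ev1.variable, ev1.threshold) == (ev2.variable, ev2.threshold)
            assert ev1.decrease == pytest.approx(ev2.decrease, abs=1e-12)


def test_explained_variance_conservation(synth_abundance_tree):
    """Sum of weighted per-node decreases equals root variance minus weighted
    leaf variance (total explained variance identity)."""
    tree = synth_abundance_tree
    n_root = tree.root.n_samples
    total_decrease = sum(
        (tree.nodes[i].node_sse
         - tree.nodes[tree.nodes[i].left_child].node_sse
         - tree.nodes[tree.nodes[i].right_child].node_sse) / n_root
        for i in tree.internal_ids()
    )
    root_var = tree.root.node_sse / n_root
    leaf_var = sum(tree.nodes[i].node_sse for i in tree.leaf_ids()) / n_root
    assert total_decrease == pytest.approx(root_var - leaf_var, abs=1e-10)


def test_predict_routing_and_back_transform():
    stump = make_stump(var="DO", threshold=1.795, means=(3.85, 3.30))
    rows = pd.DataFrame({"DO": [1.0, 1.795, 2.5]})
    assert predict(stump, rows).tolist() == [3.85, 3.30, 3.30]  # >= goes right
    assert predict(stump, rows, back_transform=True) == pytest.approx(
        np.exp([3.85, 3.30, 3.30])
    )


def test_predict_single_leaf_returns_root_mean():
    from phytocart.dataio import RegressionTree, TreeNode

    tree = RegressionTree(
        nodes={0: TreeNode(0, "leaf", 5, 3.4, 0.0)}, root_id=0, response_name="richness"
    )
    assert predict(tree, pd.DataFrame({"DO": [0.1, 9.9]})).tolist() == [3.4, 3.4]


def test_predict_missing_routing_value_is_per_row_error():
    stump = make_stump(var="DO", threshold=1.795)
    with pytest.raises(ContractError, match="row 1"):
        predict(stump, pd.DataFrame({"DO": [1.0, np.nan]}))


def test_predict_absent_column_is_error():
    stump = make_stump(var="DO", threshold=1.795)
    with pytest.raises(ContractError, match="DO"):
        predict(stump, pd.DataFrame({"WT": [1.0]}))


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.lists(st.floats(-50, 50), min_size=2, max_size=25), st.integers(0, 2**16))
def test_split_decrease_never_exceeds_parent_variance(ys, seed):
    y = np.asarray(ys, dtype=float)
    x = np.random.default_rng(seed).uniform(0, 1, len(y))
    ev = best_split(pd.DataFrame({"x": x}), y, FitSettings(min_leaf=1, min_split=2))
    if ev is not None:
        assert 0.0 <= ev.decrease <= node_variance(y) + 1e-9


def test_root_split_matches_sklearn():
    """Independent cross-check: scikit-learn's depth-1 regression tree chooses
    the same split and impurity decrease (same criterion, same midpoints)."""
    from sklearn.tree import DecisionTreeRegressor

    rng = np.random.default_rng(3)
    table = random_table(rng, 80, 3)
    X, y = table.data[table.predictors], table.data["y"].to_numpy()
    ev = best_split(X, y, FitSettings(min_leaf=1, min_split=2))
    sk = DecisionTreeRegressor(max_depth=1).fit(X, y)
    assert table.predictors[sk.tree_.feature[0]] == ev.variable
    # scikit-learn stores features as float32; compare at that resolution
    assert sk.tree_.threshold[0] == pytest.approx(ev.threshold, abs=1e-5)
    sk_decrease = sk.tree_.impurity[0] - (
        sk.tree_.weighted_n_node_samples[1] * sk.tree_.impurity[1]
        + sk.tree_.weighted_n_node_samples[2] * sk.tree_.impurity[2]
    ) / sk.tree_.weighted_n_node_samples[0]
    assert ev.decrease == pytest.approx(sk_decrease, rel=1e-9)
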