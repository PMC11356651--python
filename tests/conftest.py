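"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations


import numpy as np
import pandas as pd
import pytest

from phytocart.dataio import RegressionTree, SampleTable, TreeNode
from phytocart.cart_core import FitSettings, grow_tree
from phytocart.community_stats import ln_transform
from phytocart.synthetic_data import default_scenario, generate_dataset


# ---------------------------------------------------------------------------
# Tree builders
# ---------------------------------------------------------------------------


def make_stump(
    var: str = "DO",
    threshold: float = 1.795,
    means: tuple[float, float] = (1.0, 2.0),
    ns: tuple[int, int] = (3, 3),
    sses: tuple[float, float] = (0.0, 0.0),
    response: str = "richness",
) -> RegressionTree:
    n = ns[0] + ns[1]
    root_mean = (ns[0] * means[0] + ns[1] * means[1]) / n
    root_sse = (
        sses[0] + sses[1]
        + ns[0] * (means[0] - root_mean) ** 2
        + ns[1] * (means[1] - root_mean) ** 2
    )
    nodes = {
        0: TreeNode(0, "internal", n, root_mean, root_sse, var, threshold, 1, 2),
        1: TreeNode(1, "leaf", ns[0], means[0], sses[0]),
        2: TreeNode(2, "leaf", ns[1], means[1], sses[1]),
    }
    return RegressionTree(nodes=nodes, root_id=0, response_name=response, transform="ln")


def make_table(columns: dict, predictors: list[str], responses: list[str]) -> SampleTable:
    data = pd.DataFrame(columns)
    if "site" not in data.columns:
        data.insert(0, "site", [f"s{i}" for i in range(len(data))])
    if "month" not in data.columns:
        data.insert(1, "month", "2019-04")
    return SampleTable(data=data, predictors=predictors, responses=responses)


def random_table(rng: np.random.Generator, n: int, p: int, round_x: bool = False) -> SampleTable:
    cols = {f"x{j}": rng.uniform(0, 10, n) for j in range(p)}
    if round_x:
        cols = {k: np.round(v, 1) for k, v in cols.items()}
    cols["y"] = rng.normal(0, 1, n)
    return make_table(cols, predictors=[f"x{j}" for j in range(p)], responses=["y"])


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def brute_force_best_split(x_matrix: pd.DataFrame, y: np.ndarray, min_leaf: int = 1):
    """Exhaustive scan over every (variable, observed-value-gap) candidate,
    written independently of the implementation: per-candidate variances via
    numpy on explicit masks.  Tie-break: earlier column, then smaller
    threshold (strict > comparison in scan order)."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    parent_var = np.var(y)
    best = None
    for var in x_matrix.columns:
        x = np.asarray(x_matrix[var], dtype=float)
        values = np.unique(x)
        for lo, hi in zip(values[:-1], values[1:]):
            thr = (lo + hi) / 2.0
            left = x < thr
            n1 = int(left.sum())
            n2 = n - n1
            if n1 < min_leaf or n2 < min_leaf:
                continue
            dec = parent_var - (n1 / n) * np.var(y[left]) - (n2 / n) * np.var(y[~left])
            if best is None or dec > best[0]:
                best = (dec, var, thr, n1, n2)
    if best is None or best[0] <= 0:
        return None
    return best


def enumerate_subtrees(tree: RegressionTree) -> list[frozenset]:
    """All rooted subtrees of ``tree`` as kept-node-id sets (leaves of the
    subtree are nodes whose children are excluded)."""

    def rec(nid: int) -> list[frozenset]:
        nd = tree.nodes[nid]
        out = [frozenset([nid])]
        if not nd.is_leaf:
            for l in rec(nd.left_child):
                for r in rec(nd.right_child):
                    out.append(frozenset([nid]) | l | r)
        return out

    return rec(tree.root_id)


def subtree_cost(tree: RegressionTree, kept: frozenset, alpha: float) -> tuple[float, int]:
    """R(T) + alpha * |leaves(T)| for the subtree given by ``kept``."""
    n_root = tree.root.n_samples
    r = 0.0
    leaves = 0
    for nid in kept:
        nd = tree.nodes[nid]
        if nd.is_leaf or nd.left_child not in kept:
            r += nd.node_sse / n_root
            leaves += 1
    return r + alpha * leaves, leaves


# ---------------------------------------------------------------------------
# Shared datasets
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def toy_step_table() -> SampleTable:
    """x=[1,2,3,4], y=[0,0,10,10]: the canonical hand-enumerable split."""
    return make_table(
        {"x": [1.0, 2.0, 3.0, 4.0], "y": [0.0, 0.0, 10.0, 10.0]},
        predictors=["x"], responses=["y"],
    )


@pytest.fixture(scope="session")
def synth_table() -> SampleTable:
    """One default-scenario draw (8 months x 27 sites) with both responses."""
    return generate_dataset(default_scenario(seed=5))


@pytest.fixture(scope="session")
def synth_abundance_tree(synth_table):
    """Full-grown ln-abundance tree on the default synthetic draw."""
    table = ln_transform(synth_table, "abundance")
    return grow_tree(table, "abundance", settings=FitSettings())


@pytest.fixture()
def loose_settings() -> FitSettings:
    return FitSettings(min_leaf=1, min_split=2)
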