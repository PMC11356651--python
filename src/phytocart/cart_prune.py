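"""Cost-complexity (weakest-link) pruning and final-subtree selection.

The resubstitution error of a (sub)tree is the sample-size-weighted node
variance summed over its leaves,

    R(T) = sum_{leaf l} (n_l / N_root) * var(l) = sum_l sse_l / N_root,

so that R of the root-only tree equals the population variance of the training
responses and R is additive over leaves.  Each internal node n has a critical
complexity parameter

    alpha(n) = (R(n) - R(T_n)) / (|leaves(T_n)| - 1),

the per-leaf price at which collapsing its subtree breaks even.  Weakest-link
pruning repeatedly collapses the internal node(s) with the minimal current
alpha, producing a nested sequence of optimal subtrees from the full tree down
to the root; the final model is chosen either by an explicit leaf-count budget
or by k-fold cross-validation over the alpha sequence (minimum-error or
one-standard-error rule).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dataio import ContractError, RegressionTree, SampleTable
from .cart_core import FitSettings, grow_tree

__all__ = [
    "PruneRecord",
    "PathEntry",
    "PrunePath",
    "LeafCountPolicy",
    "CVPolicy",
    "node_alpha",
    "prune_records",
    "prune_path",
    "select_subtree",
]

_TIE_TOL = 1e-12


@dataclass(frozen=True)
class PruneRecord:
    """Critical alpha bookkeeping for one internal node."""

    node_id: int
    alpha_star: float
    subtree_error: float
    node_error: float
    subtree_leaves: int


@dataclass
class PathEntry:
    """One optimal subtree along the pruning sequence."""

    alpha: float
    n_leaves: int
    training_error: float
    kept_ids: frozenset[int]
    _full_tree: RegressionTree = field(repr=False)
    _subtree: RegressionTree | None = field(default=None, repr=False)

    @property
    def subtree(self) -> RegressionTree:
        if self._subtree is None:
            self._subtree = self._full_tree.subtree_keeping(self.kept_ids)
        return self._subtree


@dataclass
class PrunePath:
    """Nested sequence of (alpha, subtree) pairs, full tree first, root last."""

    tree: RegressionTree
    entries: list[PathEntry]

    def __len__(self) -> int:
        return len(self.entries)

    def alphas(self) -> list[float]:
        return [e.alpha for e in self.entries]

    def entry_for_alpha(self, alpha: float) -> PathEntry:
        """The optimal subtree at complexity ``alpha`` (last entry with
        entry.alpha <= alpha)."""
        chosen = self.entries[0]
        for e in self.entries:
            if e.alpha <= alpha:
                chosen = e
            else:
                break
        return chosen


def _subtree_aggregates(tree: RegressionTree, node_id: int) -> tuple[float, int]:
    """(sum of leaf sse, leaf count) of the subtree rooted at ``node_id``,
    computed iteratively (trees may be deep)."""
    sse = 0.0
    leaves = 0
    stack = [node_id]
    while stack:
        nd = tree.nodes[stack.pop()]
        if nd.is_leaf:
            sse += nd.node_sse
            leaves += 1
        else:
            stack.extend((nd.left_child, nd.right_child))
    return sse, leaves


def node_alpha(tree: RegressionTree, node_id: int) -> float:
    """Critical complexity parameter of an internal node."""
    nd = tree.nodes[node_id]
    if nd.is_leaf:
        raise ContractError(f"node {node_id} is a leaf; alpha is defined for internal nodes")
    n_root = tree.root.n_samples
    sub_sse, sub_leaves = _subtree_aggregates(tree, node_id)
    return (nd.node_sse - sub_sse) / (n_root * (sub_leaves - 1))


def prune_records(tree: RegressionTree) -> list[PruneRecord]:
    n_root = tree.root.n_samples
    out = []
    for nid in sorted(tree.internal_ids()):
        nd = tree.nodes[nid]
        sub_sse, sub_leaves = _subtree_aggregates(tree, nid)
        out.append(
            PruneRecord(
                node_id=nid,
                alpha_star=(nd.node_sse - sub_sse) / (n_root * (sub_leaves - 1)),
                subtree_error=sub_sse / n_root,
                node_error=nd.node_sse / n_root,
                subtree_leaves=sub_leaves,
            )
        )
    return out


def prune_path(tree: RegressionTree) -> PrunePath:
    """Weakest-link pruning: collapse minimal-alpha node(s), recompute, repeat.

    Ties in the minimal alpha are collapsed in the same step, keeping the path
    nested and the recorded alphas strictly increasing.
    """
    tree.validate()
    full = tree.copy()
    n_root = full.root.n_samples
    parents = full.parent_map()

    # Iterative post-order aggregates over the full tree.
    sub_sse: dict[int, float] = {}
    sub_leaves: dict[int, int] = {}
    for nid in _postorder(full):
        nd = full.nodes[nid]
        if nd.is_leaf:
            sub_sse[nid] = nd.node_sse
            sub_leaves[nid] = 1
        else:
            sub_sse[nid] = sub_sse[nd.left_child] + sub_sse[nd.right_child]
            sub_leaves[nid] = sub_leaves[nd.left_child] + sub_leaves[nd.right_child]

    def crit(nid: int) -> float:
        nd = full.nodes[nid]
        return max((nd.node_sse - sub_sse[nid]) / (n_root * (sub_leaves[nid] - 1)), 0.0)

    internal = set(full.internal_ids())
    alpha = {nid: crit(nid) for nid in internal}
    kept = set(full.nodes)

    entries = [
        PathEntry(
            alpha=0.0,
            n_leaves=sub_leaves[full.root_id],
            training_error=sub_sse[full.root_id] / n_root,
            kept_ids=frozenset(kept),
            _full_tree=full,
        )
    ]

    while internal:
        amin = min(alpha[nid] for nid in internal)
        tol = _TIE_TOL * max(1.0, amin)
        to_collapse = sorted(nid for nid in internal if alpha[nid] <= amin + tol)
        for cid in to_collapse:
            if cid not in internal:  # already removed under an earlier tie
                continue
            # drop everything strictly below cid
            stack = [full.nodes[cid].left_child, full.nodes[cid].right_child]
            while stack:
                nid = stack.pop()
                nd = full.nodes[nid]
                kept.discard(nid)
                internal.discard(nid)
                alpha.pop(nid, None)
                if not nd.is_leaf:
                    stack.extend((nd.left_child, nd.right_child))
            internal.discard(cid)
            alpha.pop(cid, None)
            d_sse = full.nodes[cid].node_sse - sub_sse[cid]
            d_leaves = 1 - sub_leaves[cid]
            sub_sse[cid] = full.nodes[cid].node_sse
            sub_leaves[cid] = 1
            p = parents.get(cid)
            while p is not None:
                sub_sse[p] += d_sse
                sub_leaves[p] += d_leaves
                if p in internal:
                    alpha[p] = crit(p)
                p = parents.get(p)
        entry = PathEntry(
            alpha=amin,
            n_leaves=sub_leaves[full.root_id],
            training_error=sub_sse[full.root_id] / n_root,
            kept_ids=frozenset(kept),
            _full_tree=full,
        )
        if entries and amin <= entries[-1].alpha + _TIE_TOL * max(1.0, amin):
            entries[-1] = entry  # keep alphas strictly increasing
        else:
            entries.append(entry)
    return PrunePath(tree=full, entries=entries)


def _postorder(tree: RegressionTree) -> list[int]:
    order: list[int] = []
    stack = [tree.root_id]
    while stack:
        nid = stack.pop()
        order.append(nid)
        nd = tree.nodes[nid]
        if not nd.is_leaf:
            stack.extend((nd.left_child, nd.right_child))
    order.reverse()
    return order


# ---------------------------------------------------------------------------
# Final-subtree selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LeafCountPolicy:
    """Pick the path entry with the largest leaf count <= k."""

    k: int


@dataclass(frozen=True)
class CVPolicy:
    """k-fold cross-validation over the alpha sequence.

    ``rule="min"`` picks the alpha minimizing CV error; ``rule="one_se"`` the
    sparsest subtree within one standard error of the minimum (SE estimated
    from per-fold mean losses).
    """

    folds: int = 10
    rule: str = "min"  # "min" | "one_se"
    seed: int = 0


def select_subtree(
    path: PrunePath,
    policy: LeafCountPolicy | CVPolicy,
    table: SampleTable | None = None,
    response: str | None = None,
    predictors: Sequence[str] | None = None,
    settings: FitSettings | None = None,
) -> RegressionTree:
    """Choose the final subtree from a pruning path.

    The CV policy refits the grow+prune procedure on each training fold (the
    original table, response and fit settings are therefore required) and
    evaluates every candidate alpha at the geometric midpoints of the path's
    alpha sequence; deterministic given ``policy.seed``.
    """
    if not path.entries:
        raise ContractError("empty pruning path")
    if isinstance(policy, LeafCountPolicy):
        if policy.k < 1:
            raise ContractError("leaf-count policy requires k >= 1")
        candidates = [e for e in path.entries if e.n_leaves <= policy.k]
        if not candidates:
            raise ContractError(f"no path entry with <= {policy.k} leaves")
        best = max(candidates, key=lambda e: e.n_leaves)
        return best.subtree
    if isinstance(policy, CVPolicy):
        if table is None or response is None:
            raise ContractError("cv policy requires the training table and response")
        k = _cv_best_entry(path, policy, table, response, predictors, settings)
        return path.entries[k].subtree
    raise ContractError(f"unknown selection policy {policy!r}")


def _rep_alphas(alphas: Sequence[float]) -> list[float]:
    """Geometric midpoints of consecutive alphas (evaluation points)."""
    k = len(alphas)
    reps = []
    for i in range(k):
        if i < k - 1:
            reps.append(math.sqrt(max(alphas[i], 0.0) * max(alphas[i + 1], 0.0)))
        else:
            reps.append(alphas[i] * 2.0 if alphas[i] > 0 else 0.0)
    return reps


def _cv_best_entry(
    path: PrunePath,
    policy: CVPolicy,
    table: SampleTable,
    response: str,
    predictors: Sequence[str] | None,
    settings: FitSettings | None,
) -> int:
    predictors = list(predictors) if predictors is not None else list(table.predictors)
    settings = settings if settings is not None else FitSettings()
    fit_table = table.complete_rows([*predictors, response])
    n = fit_table.n
    folds = min(policy.folds, n)
    if folds < 2:
        raise ContractError("cv policy requires at least 2 folds")
    rng = np.random.default_rng(policy.seed)
    perm = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    fold_of[perm] = np.arange(n) % folds

    reps = _rep_alphas(path.alphas())
    y_all = np.asarray(fit_table.data[response], dtype=float)
    sse_per_fold = np.zeros((folds, len(reps)))
    n_per_fold = np.zeros(folds)

    from .cart_core import predict  # local import to avoid cycle at module load

    for f in range(folds):
        train_mask = fold_of != f
        sub = fit_table.data.loc[train_mask].reset_index(drop=True)
        train_table = SampleTable(
            data=sub,
            predictors=list(fit_table.predictors),
            responses=list(fit_table.responses),
            transforms=dict(fit_table.transforms),
        )
        fold_tree = grow_tree(train_table, response, predictors, settings)
        fold_path = prune_path(fold_tree)
        test = fit_table.data.loc[~train_mask]
        y_test = y_all[~train_mask]
        n_per_fold[f] = len(test)
        # per-node test statistics via one routing pass through the full fold tree
        stats = _route_stats(fold_path.tree, test, y_test)
        fold_alphas = fold_path.alphas()
        entry_sse = [
            sum(stats.get(leaf, 0.0) for leaf in _entry_leaves(fold_path, j))
            for j in range(len(fold_path.entries))
        ]
        for j, rep in enumerate(reps):
            idx = _last_le(fold_alphas, rep)
            sse_per_fold[f, j] = entry_sse[idx]

    cv_err = sse_per_fold.sum(axis=0) / n
    fold_mse = sse_per_fold / n_per_fold[:, None]
    se = fold_mse.std(axis=0, ddof=1) / math.sqrt(folds)

    k_min = int(np.argmin(cv_err))
    # among near-ties, prefer the sparsest subtree
    for j in range(len(cv_err) - 1, k_min, -1):
        if cv_err[j] <= cv_err[k_min] + _TIE_TOL * max(1.0, cv_err[k_min]):
            k_min = j
            break
    if policy.rule == "min":
        return k_min
    if policy.rule == "one_se":
        limit = cv_err[k_min] + se[k_min]
        for j in range(len(cv_err) - 1, -1, -1):  # sparsest first
            if cv_err[j] <= limit:
                return j
        return k_min
    raise ContractError(f"unknown cv rule {policy.rule!r}")


def _route_stats(tree: RegressionTree, rows, y: np.ndarray) -> dict[int, float]:
    """For every node, the test SSE if that node's mean were the prediction
    for all test rows routed through it."""
    cols = {
        nd.split_variable: np.asarray(rows[nd.split_variable], dtype=float)
        for nd in tree.nodes.values()
        if not nd.is_leaf
    }
    count: dict[int, int] = {}
    s1: dict[int, float] = {}
    s2: dict[int, float] = {}
    for i in range(len(y)):
        node = tree.root
        while True:
            nid = node.node_id
            count[nid] = count.get(nid, 0) + 1
            s1[nid] = s1.get(nid, 0.0) + y[i]
            s2[nid] = s2.get(nid, 0.0) + y[i] * y[i]
            if node.is_leaf:
                break
            x = cols[node.split_variable][i]
            node = tree.nodes[node.left_child if x < node.split_threshold else node.right_child]
    out = {}
    for nid, c in count.items():
        m = tree.nodes[nid].node_mean
        out[nid] = s2[nid] - 2.0 * m * s1[nid] + c * m * m
    return out


def _entry_leaves(path: PrunePath, j: int) -> list[int]:
    kept = path.entries[j].kept_ids
    full = path.tree
    leaves = []
    for nid in kept:
        nd = full.nodes[nid]
        if nd.is_leaf or nd.left_child not in kept:
            leaves.append(nid)
    return leaves


def _last_le(sorted_vals: Sequence[float], x: float) -> int:
    idx = 0
    for i, v in enumerate(sorted_vals):
        if v <= x:
            idx = i
        else:
            break
    return idx
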