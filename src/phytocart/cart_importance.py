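"""Per-variable contribution and split-sign accounting for fitted trees.

A split's variance decrease at node ``m`` (parent variance minus weighted
child variances) is weighted by the fraction of training samples reaching the
node, ``n_m / N_root``, making contributions commensurable across depths:
summed over all internal nodes, the weighted decreases equal the total
explained variance (root variance minus weighted leaf variance).  Per
variable ``i``, ``q_i`` is the sum over nodes splitting on ``i``, reported
under two normalizations:

* ``pc_share`` = q_i / sum_j q_j — shares summing to 1 over the splitting
  variables;
* ``pc_root`` = q_i / root variance — the fraction of *total* response
  variance attributed to the variable; these sum to ``total_explained``.

Each split is also signed: positive when the high side of the threshold
(x >= t) has the larger mean response, negative when the low side does.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .dataio import ContractError, RegressionTree

__all__ = ["VariableImportance", "ImportanceReport", "variable_contributions", "split_signs"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class VariableImportance:
    variable: str
    q: float
    pc_share: float  # q / sum(q); NaN when the tree has no splits
    pc_root: float  # q / root variance
    n_positive_splits: int
    n_negative_splits: int


@dataclass
class ImportanceReport:
    records: list[VariableImportance]
    total_explained: float
    root_variance: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "variable": r.variable,
                    "q": r.q,
                    "pc_share": r.pc_share,
                    "pc_root": r.pc_root,
                    "n_positive_splits": r.n_positive_splits,
                    "n_negative_splits": r.n_negative_splits,
                }
                for r in self.records
            ]
        )

    def __getitem__(self, variable: str) -> VariableImportance:
        for r in self.records:
            if r.variable == variable:
                return r
        raise KeyError(variable)


def _weighted_decrease(tree: RegressionTree, node) -> float:
    """(n_m / N_root) * per-node variance decrease = sse reduction / N_root."""
    left = tree.nodes[node.left_child]
    right = tree.nodes[node.right_child]
    return (node.node_sse - left.node_sse - right.node_sse) / tree.root.n_samples


def variable_contributions(tree: RegressionTree, variables: list[str] | None = None) -> ImportanceReport:
    """Summed weighted variance decrease per split variable, both
    normalizations, and signed split counts.

    ``variables`` fixes the report order (default: order of first appearance
    in the tree); variables never split on get q = 0.
    """
    tree.validate()
    root = tree.root
    if root.n_samples < 1:
        raise ContractError("tree has no training samples recorded")
    root_variance = root.node_sse / root.n_samples

    order: list[str] = list(variables) if variables is not None else []
    q: dict[str, float] = {v: 0.0 for v in order}
    for nid in sorted(tree.internal_ids()):
        nd = tree.nodes[nid]
        if nd.split_variable not in q:
            q[nd.split_variable] = 0.0
            order.append(nd.split_variable)
        q[nd.split_variable] += _weighted_decrease(tree, nd)

    signs = split_signs(tree)
    q_total = sum(q.values())
    total_explained = q_total / root_variance if root_variance > 0 else 0.0
    records = []
    for var in order:
        share = q[var] / q_total if q_total > 0 else float("nan")
        records.append(
            VariableImportance(
                variable=var,
                q=q[var],
                pc_share=share,
                pc_root=q[var] / root_variance if root_variance > 0 else 0.0,
                n_positive_splits=signs.get(var, (0, 0))[0],
                n_negative_splits=signs.get(var, (0, 0))[1],
            )
        )
    return ImportanceReport(records=records, total_explained=total_explained, root_variance=root_variance)


def split_signs(tree: RegressionTree) -> dict[str, tuple[int, int]]:
    """Per-variable (positive, negative) split counts.

    A split is positive when the right (x >= t) child's mean response exceeds
    the left child's, negative when it is lower.  An exact tie (only possible
    for a zero-decrease split) counts as neither and is logged.
    """
    out: dict[str, tuple[int, int]] = {}
    for nid in sorted(tree.internal_ids()):
        nd = tree.nodes[nid]
        left = tree.nodes[nd.left_child]
        right = tree.nodes[nd.right_child]
        pos, neg = out.get(nd.split_variable, (0, 0))
        if right.node_mean > left.node_mean:
            pos += 1
        elif right.node_mean < left.node_mean:
            neg += 1
        else:
            log.warning("tied child means at node %d; split counted as neither sign", nid)
        out[nd.split_variable] = (pos, neg)
    return out
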