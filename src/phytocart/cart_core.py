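"""Regression-tree growth by exhaustive variance-reduction split search.

The tree is grown on the (usually ln-transformed) response by recursive binary
partitioning.  At each node the sample variance is the population form

    E(D) = (1/N) * sum_i (y_i - ybar)^2,

and every candidate split — each predictor, with thresholds at midpoints
between consecutive distinct sorted values — is scored by the variance
decrease

    E = E(D) - (N1/N) E(D1) - (N2/N) E(D2),

the weighted within-child variances subtracted from the parent variance.  The
candidate with the maximal decrease wins; ties go to the earlier variable in
``variable_order`` and then to the smaller threshold, so fitting is fully
deterministic.  Rows routed by ``x < t`` go left, ``x >= t`` right.

Growth is deliberately deep (small ``min_leaf``); model selection is the
pruning stage's job (:mod:`phytocart.cart_prune`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .dataio import ContractError, RegressionTree, SampleTable, TreeNode

__all__ = [
    "SplitEvaluation",
    "FitSettings",
    "node_variance",
    "best_split",
    "grow_tree",
    "predict",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SplitEvaluation:
    """A scored candidate split: variance decrease in parent-node units."""

    variable: str
    threshold: float
    decrease: float
    n_left: int
    n_right: int


@dataclass(frozen=True)
class FitSettings:
    """Stopping rules for tree growth.

    Defaults grow deep (``min_leaf=2``, ``min_split=4``, no depth cap, any
    positive decrease admissible), mirroring a grow-then-prune design.
    """

    min_leaf: int = 2
    min_split: int = 4
    min_decrease: float = 0.0
    max_depth: int | None = None
    variable_order: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.min_leaf < 1:
            raise ContractError("min_leaf must be >= 1")
        if self.min_split < 2 * self.min_leaf:
            raise ContractError("min_split must be >= 2 * min_leaf")
        if self.min_decrease < 0:
            raise ContractError("min_decrease must be >= 0")


def node_variance(y: Sequence[float]) -> float:
    """Population-form sample variance, divisor N (not N-1)."""
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ContractError("node_variance requires at least one value")
    return float(np.mean((y - y.mean()) ** 2))


def _scan_variable(x: np.ndarray, y: np.ndarray, min_leaf: int):
    """Best admissible split on one predictor.

    Returns ``(decrease_sse, threshold, n_left)`` where ``decrease_sse`` is the
    reduction in sum of squared errors (variance decrease times N), or ``None``
    if no admissible threshold exists.  Among equal decreases the smallest
    threshold is returned (argmax takes the first, and candidates are scanned
    in increasing-threshold order).
    """
    n = x.size
    order = np.argsort(x, kind="stable")
    xs = x[order]
    ys = y[order]
    cum = np.cumsum(ys)
    cumsq = np.cumsum(ys * ys)
    total, total_sq = cum[-1], cumsq[-1]
    n_left = np.arange(1, n)
    distinct = xs[1:] > xs[:-1]
    ok = distinct & (n_left >= min_leaf) & ((n - n_left) >= min_leaf)
    if not ok.any():
        return None
    sl, sql = cum[:-1], cumsq[:-1]
    sse_left = sql - sl * sl / n_left
    n_right = n - n_left
    sse_right = (total_sq - sql) - (total - sl) ** 2 / n_right
    sse_parent = total_sq - total * total / n
    dec = sse_parent - sse_left - sse_right
    dec = np.where(ok, dec, -np.inf)
    i = int(np.argmax(dec))
    threshold = (xs[i] + xs[i + 1]) / 2.0
    return max(float(dec[i]), 0.0), float(threshold), int(n_left[i])


def best_split(
    x_matrix: pd.DataFrame,
    y: np.ndarray,
    settings: FitSettings = FitSettings(),
) -> SplitEvaluation | None:
    """Exhaustive search over (variable, midpoint-threshold) candidates.

    Returns the candidate maximizing the variance decrease, or ``None`` when no
    candidate satisfies ``min_leaf`` on both sides or the best decrease falls
    below ``min_decrease``.  Rows must be complete for all candidate predictors.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if len(x_matrix) != n:
        raise ContractError("x_matrix and y must have equal length")
    if n < settings.min_split:
        return None
    variables = (
        [v for v in settings.variable_order if v in x_matrix.columns]
        if settings.variable_order is not None
        else list(x_matrix.columns)
    )
    best: SplitEvaluation | None = None
    best_sse_dec = -np.inf
    for var in variables:
        x = np.asarray(x_matrix[var], dtype=float)
        if np.isnan(x).any():
            raise ContractError(f"missing values in predictor {var!r}; drop rows upstream")
        hit = _scan_variable(x, y, settings.min_leaf)
        if hit is None:
            continue
        sse_dec, threshold, n_left = hit
        if sse_dec > best_sse_dec:  # strict: earlier variable wins ties
            best_sse_dec = sse_dec
            best = SplitEvaluation(
                variable=var,
                threshold=threshold,
                decrease=sse_dec / n,
                n_left=n_left,
                n_right=n - n_left,
            )
    if best is None or best_sse_dec <= 0.0 or best.decrease < settings.min_decrease:
        return None  # a zero-decrease split is no split at all
    return best


def grow_tree(
    table: SampleTable,
    response: str,
    predictors: Sequence[str] | None = None,
    settings: FitSettings = FitSettings(),
) -> RegressionTree:
    """Grow a regression tree by recursive variance-reduction partitioning.

    Rows with any missing value among the declared predictors or the response
    are dropped (count logged); no surrogate splits.  The response column is
    used as-is: transform it first (see
    :func:`phytocart.community_stats.ln_transform`) or request
    ``transform="identity"`` implicitly by fitting an untransformed column.
    """
    predictors = list(predictors) if predictors is not None else list(table.predictors)
    unknown = [c for c in [*predictors, response] if c not in table.data.columns]
    if unknown:
        raise ContractError(f"unknown column(s): {', '.join(unknown)}")
    cols = [*predictors, response]
    n_before = table.n
    fit_table = table.complete_rows(cols)
    if fit_table.n < n_before:
        log.info("dropped %d incomplete row(s) before fitting", n_before - fit_table.n)

    if settings.variable_order is None:
        settings = FitSettings(
            min_leaf=settings.min_leaf,
            min_split=settings.min_split,
            min_decrease=settings.min_decrease,
            max_depth=settings.max_depth,
            variable_order=tuple(predictors),
        )

    X = fit_table.data[predictors].reset_index(drop=True)
    y = np.asarray(fit_table.data[response], dtype=float)

    nodes: dict[int, TreeNode] = {}
    counter = iter(range(10**9))

    def build(idx: np.ndarray, depth: int) -> int:
        nid = next(counter)
        yi = y[idx]
        mean = float(yi.mean())
        sse = float(np.sum((yi - mean) ** 2))
        node = TreeNode(nid, "leaf", int(idx.size), mean, sse)
        nodes[nid] = node
        depth_ok = settings.max_depth is None or depth < settings.max_depth
        if depth_ok and idx.size >= settings.min_split and sse > 0.0:
            ev = best_split(X.iloc[idx], yi, settings)
            if ev is not None:
                x = np.asarray(X[ev.variable], dtype=float)[idx]
                left_idx = idx[x < ev.threshold]
                right_idx = idx[x >= ev.threshold]
                node.kind = "internal"
                node.split_variable = ev.variable
                node.split_threshold = ev.threshold
                node.left_child = build(left_idx, depth + 1)
                node.right_child = build(right_idx, depth + 1)
        return nid

    root_id = build(np.arange(fit_table.n), 0)
    tree = RegressionTree(
        nodes=nodes,
        root_id=root_id,
        response_name=response,
        transform=table.transform_of(response),
        fit_settings={**asdict(settings), "variable_order": list(settings.variable_order or ())},
    )
    tree.validate()
    return tree


def predict(
    tree: RegressionTree,
    rows: pd.DataFrame | SampleTable,
    back_transform: bool = False,
) -> np.ndarray:
    """Route each row to a leaf and return leaf means.

    Routing follows ``x < t`` left / ``x >= t`` right.  With
    ``back_transform=True`` and an ln-scale tree, predictions are
    exponentiated to the raw response scale.  A missing value on a variable
    needed for routing raises a :class:`ContractError` naming the row.
    """
    data = rows.data if isinstance(rows, SampleTable) else rows
    needed = {nd.split_variable for nd in tree.nodes.values() if not nd.is_leaf}
    absent = needed - set(data.columns)
    if absent:
        raise ContractError(f"rows lack split variable(s): {', '.join(sorted(absent))}")

    cols = {v: np.asarray(data[v], dtype=float) for v in needed}
    out = np.empty(len(data), dtype=float)
    for i in range(len(data)):
        node = tree.root
        while not node.is_leaf:
            x = cols[node.split_variable][i]
            if np.isnan(x):
                raise ContractError(
                    f"row {i}: missing value for split variable {node.split_variable!r}"
                )
            node = tree.nodes[node.left_child if x < node.split_threshold else node.right_child]
        out[i] = node.node_mean
    if back_transform and tree.transform == "ln":
        out = np.exp(out)
    return out
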