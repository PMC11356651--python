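"""On-disk formats and the in-memory data model shared by every pipeline stage.

The exchange object between stages is the :class:`SampleTable` — one row per
(site, month) sample carrying eight environmental predictors (WT, DO, EC, pH,
ORP, Tur, TN, TP) and one or more phytoplankton response columns (species
richness, abundance).  Fitted regression trees travel as :class:`RegressionTree`
objects and round-trip through a versioned JSON document; a DOT exporter renders
them for graphviz (rectangles for split nodes, ovals for leaves).

The reader only *flags* missing values; which rows to drop is decided by the
fitting stage, so I/O stays policy-free.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PREDICTOR_VARS",
    "RESPONSE_VARS",
    "SchemaError",
    "ParseError",
    "FormatError",
    "ContractError",
    "TableSchema",
    "SampleTable",
    "TreeNode",
    "RegressionTree",
    "read_sample_table",
    "write_sample_table",
    "read_tree",
    "write_tree",
    "tree_to_dict",
    "tree_from_dict",
    "export_dot",
]

#: Canonical predictor column order; also the default split tie-break order.
PREDICTOR_VARS = ["WT", "DO", "EC", "pH", "ORP", "Tur", "TN", "TP"]

#: Canonical response columns.
RESPONSE_VARS = ["richness", "abundance"]

#: Strings treated as explicit missing markers in sample-table CSVs.
NA_MARKERS = ["NA", "NaN", "nan", ""]

TREE_SCHEMA_VERSION = 1


class SchemaError(ValueError):
    """A declared column is absent or a table-level invariant is violated."""


class ParseError(ValueError):
    """A cell could not be parsed as a number."""


class FormatError(ValueError):
    """A serialized document is malformed (bad JSON, dangling node ids ...)."""


class ContractError(ValueError):
    """An operation precondition was violated."""


@dataclass(frozen=True)
class TableSchema:
    """Column declaration for a sample-table CSV."""

    predictors: tuple[str, ...] = tuple(PREDICTOR_VARS)
    responses: tuple[str, ...] = tuple(RESPONSE_VARS)
    site_col: str = "site"
    month_col: str = "month"
    sample_id_col: str | None = None  # optional; (site, month) must otherwise be unique

    @property
    def numeric_columns(self) -> tuple[str, ...]:
        return self.predictors + self.responses


DEFAULT_SCHEMA = TableSchema()


@dataclass
class SampleTable:
    """A feature table of environmental predictors plus response columns.

    ``data`` holds one row per sample; missing cells are ``NaN``.  ``transforms``
    records response transforms already applied (e.g. ``{"abundance": "ln"}``)
    so predictions can be back-transformed downstream.
    """

    data: pd.DataFrame
    predictors: list[str] = field(default_factory=lambda: list(PREDICTOR_VARS))
    responses: list[str] = field(default_factory=lambda: list(RESPONSE_VARS))
    transforms: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.data) < 1:
            raise SchemaError("sample table must contain at least one row")
        missing = [c for c in [*self.predictors, *self.responses] if c not in self.data.columns]
        if missing:
            raise SchemaError(f"declared column(s) missing from table: {', '.join(missing)}")

    @property
    def n(self) -> int:
        return len(self.data)

    def transform_of(self, response: str) -> str:
        return self.transforms.get(response, "identity")

    def complete_rows(self, columns: Sequence[str]) -> "SampleTable":
        """Rows with no missing value in ``columns`` (fitting-stage policy)."""
        mask = self.data[list(columns)].notna().all(axis=1)
        if not mask.any():
            raise ContractError("no complete rows for columns " + ", ".join(columns))
        return replace(self, data=self.data.loc[mask].reset_index(drop=True))

    def with_column(self, name: str, values: np.ndarray) -> "SampleTable":
        data = self.data.copy()
        data[name] = values
        return replace(self, data=data)


def read_sample_table(path: str | Path, schema: TableSchema = DEFAULT_SCHEMA) -> SampleTable:
    """Read a sample-table CSV (comma-separated, UTF-8, header row, NA = missing).

    Raises :class:`SchemaError` naming any absent declared column and
    :class:`ParseError` with the row index for non-numeric cells.  Positivity
    invariants (richness a positive integer, abundance > 0) are enforced here,
    on raw (untransformed) tables.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=NA_MARKERS)
    for col in schema.numeric_columns:
        if col not in raw.columns:
            raise SchemaError(f"declared column missing from {path.name}: {col!r}")
    data = raw.copy()
    for col in schema.numeric_columns:
        parsed = pd.to_numeric(raw[col], errors="coerce")
        bad = parsed.isna() & raw[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ParseError(
                f"non-numeric value {raw[col][row]!r} in column {col!r} at row {row}"
            )
        data[col] = parsed.astype(float)
    _check_response_invariants(data, schema)
    return SampleTable(
        data=data,
        predictors=list(schema.predictors),
        responses=list(schema.responses),
    )


def _check_response_invariants(data: pd.DataFrame, schema: TableSchema) -> None:
    if "richness" in schema.responses:
        vals = data["richness"].dropna()
        if ((vals <= 0) | (vals != np.round(vals))).any():
            row = int(vals.index[(vals <= 0) | (vals != np.round(vals))][0])
            raise SchemaError(f"richness must be a positive integer; offending row {row}")
    if "abundance" in schema.responses:
        vals = data["abundance"].dropna()
        if (vals <= 0).any():
            row = int(vals.index[vals <= 0][0])
            raise SchemaError(f"abundance must be > 0; offending row {row}")


def write_sample_table(table: SampleTable, path: str | Path) -> Path:
    path = Path(path)
    table.data.to_csv(path, index=False, na_rep="NA")
    return path


# ---------------------------------------------------------------------------
# Regression-tree model
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    """One node of a binary regression tree.

    Routing convention: samples with ``x < split_threshold`` go to the left
    child, ``x >= split_threshold`` to the right child.  ``node_mean`` and
    ``node_sse`` (sum of squared deviations from the node mean) are computed on
    the model (usually ln) scale over the training samples reaching the node.
    """

    node_id: int
    kind: str  # "internal" | "leaf"
    n_samples: int
    node_mean: float
    node_sse: float
    split_variable: str | None = None
    split_threshold: float | None = None
    left_child: int | None = None
    right_child: int | None = None

    @property
    def is_leaf(self) -> bool:
        return self.kind == "leaf"


@dataclass
class RegressionTree:
    nodes: dict[int, TreeNode]
    root_id: int
    response_name: str
    transform: str = "ln"  # "ln" | "identity"
    fit_settings: dict = field(default_factory=dict)

    def node(self, node_id: int) -> TreeNode:
        return self.nodes[node_id]

    @property
    def root(self) -> TreeNode:
        return self.nodes[self.root_id]

    def leaf_ids(self, subtree_root: int | None = None) -> list[int]:
        out: list[int] = []
        stack = [self.root_id if subtree_root is None else subtree_root]
        while stack:
            node = self.nodes[stack.pop()]
            if node.is_leaf:
                out.append(node.node_id)
            else:
                stack.extend([node.right_child, node.left_child])
        return out

    def internal_ids(self) -> list[int]:
        return [i for i, nd in self.nodes.items() if not nd.is_leaf]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids())

    @property
    def n_internal(self) -> int:
        return len(self.internal_ids())

    def parent_map(self) -> dict[int, int]:
        parents: dict[int, int] = {}
        for nd in self.nodes.values():
            if not nd.is_leaf:
                parents[nd.left_child] = nd.node_id
                parents[nd.right_child] = nd.node_id
        return parents

    def validate(self) -> None:
        """Check structural invariants; raises :class:`FormatError` on failure."""
        if self.root_id not in self.nodes:
            raise FormatError(f"root id {self.root_id} not among nodes")
        parents = {}
        for nd in self.nodes.values():
            if nd.is_leaf:
                continue
            for child in (nd.left_child, nd.right_child):
                if child not in self.nodes:
                    raise FormatError(f"node {nd.node_id} references missing child {child}")
                if child in parents:
                    raise FormatError(f"node {child} has two parents")
                parents[child] = nd.node_id
            if nd.split_variable is None or nd.split_threshold is None:
                raise FormatError(f"internal node {nd.node_id} lacks a split rule")
        non_root = set(self.nodes) - {self.root_id}
        if set(parents) != non_root:
            orphans = non_root - set(parents)
            raise FormatError(f"unreachable node(s): {sorted(orphans)}")
        n_leaves = sum(1 for nd in self.nodes.values() if nd.is_leaf)
        if n_leaves != len(self.nodes) - n_leaves + 1:
            raise FormatError("leaf count must equal internal count + 1")
        for nd in self.nodes.values():
            if not nd.is_leaf:
                left, right = self.nodes[nd.left_child], self.nodes[nd.right_child]
                if left.n_samples + right.n_samples != nd.n_samples:
                    raise FormatError(f"child sample counts do not sum at node {nd.node_id}")

    def copy(self) -> "RegressionTree":
        return RegressionTree(
            nodes={i: replace(nd) for i, nd in self.nodes.items()},
            root_id=self.root_id,
            response_name=self.response_name,
            transform=self.transform,
            fit_settings=dict(self.fit_settings),
        )

    def subtree_keeping(self, keep: Iterable[int]) -> "RegressionTree":
        """Prune to the node-id set ``keep``; kept nodes whose children are
        dropped become leaves (their stored mean/sse/n are already correct)."""
        keep = set(keep)
        nodes: dict[int, TreeNode] = {}
        for i in keep:
            nd = replace(self.nodes[i])
            if not nd.is_leaf and (nd.left_child not in keep or nd.right_child not in keep):
                nd.kind = "leaf"
                nd.split_variable = None
                nd.split_threshold = None
                nd.left_child = None
                nd.right_child = None
            nodes[i] = nd
        out = RegressionTree(
            nodes=nodes,
            root_id=self.root_id,
            response_name=self.response_name,
            transform=self.transform,
            fit_settings=dict(self.fit_settings),
        )
        out.validate()
        return out


# ---------------------------------------------------------------------------
# Tree serialization (versioned JSON document)
# ---------------------------------------------------------------------------


def tree_to_dict(tree: RegressionTree) -> dict:
    tree.validate()
    nodes = []
    for nid in sorted(tree.nodes):
        nd = tree.nodes[nid]
        doc = {
            "node_id": nd.node_id,
            "kind": nd.kind,
            "n_samples": nd.n_samples,
            "node_mean": nd.node_mean,
            "node_sse": nd.node_sse,
        }
        if not nd.is_leaf:
            doc.update(
                split_variable=nd.split_variable,
                split_threshold=nd.split_threshold,
                left_child=nd.left_child,
                right_child=nd.right_child,
            )
        nodes.append(doc)
    return {
        "schema_version": TREE_SCHEMA_VERSION,
        "response_name": tree.response_name,
        "transform": tree.transform,
        "fit_settings": tree.fit_settings,
        "root_id": tree.root_id,
        "nodes": nodes,
    }


def tree_from_dict(doc: Mapping) -> RegressionTree:
    try:
        version = doc["schema_version"]
        if version != TREE_SCHEMA_VERSION:
            raise FormatError(f"unsupported tree schema version {version!r}")
        nodes: dict[int, TreeNode] = {}
        for nd in doc["nodes"]:
            node = TreeNode(
                node_id=int(nd["node_id"]),
                kind=str(nd["kind"]),
                n_samples=int(nd["n_samples"]),
                node_mean=float(nd["node_mean"]),
                node_sse=float(nd["node_sse"]),
                split_variable=nd.get("split_variable"),
                split_threshold=_maybe_float(nd.get("split_threshold")),
                left_child=_maybe_int(nd.get("left_child")),
                right_child=_maybe_int(nd.get("right_child")),
            )
            if node.kind not in ("internal", "leaf"):
                raise FormatError(f"unknown node kind {node.kind!r}")
            nodes[node.node_id] = node
        tree = RegressionTree(
            nodes=nodes,
            root_id=int(doc["root_id"]),
            response_name=str(doc["response_name"]),
            transform=str(doc.get("transform", "ln")),
            fit_settings=dict(doc.get("fit_settings", {})),
        )
    except (KeyError, TypeError, ValueError) as exc:
        if isinstance(exc, FormatError):
            raise
        raise FormatError(f"malformed tree document: {exc}") from exc
    tree.validate()
    return tree


def _maybe_float(x):
    return None if x is None else float(x)


def _maybe_int(x):
    return None if x is None else int(x)


def write_tree(tree: RegressionTree, path: str | Path) -> Path:
    """Serialize losslessly; floats use repr round-trip precision."""
    path = Path(path)
    path.write_text(json.dumps(tree_to_dict(tree), indent=1), encoding="utf-8")
    return path


def read_tree(path: str | Path) -> RegressionTree:
    path = Path(path)
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed tree document {path.name}: {exc}") from exc
    return tree_from_dict(doc)


# ---------------------------------------------------------------------------
# DOT export
# ---------------------------------------------------------------------------


def export_dot(tree: RegressionTree, digits: int = 4) -> str:
    """Render the tree as a DOT digraph.

    Internal (split) nodes are rectangles labeled with the split rule; leaves
    are ovals labeled with the mean response on the model scale and the sample
    count.  Out-edges carry "var < t" / "var ≥ t" labels.
    """
    tree.validate()
    lines = ["digraph regression_tree {", "  node [fontname=helvetica];"]
    for nid in sorted(tree.nodes):
        nd = tree.nodes[nid]
        if nd.is_leaf:
            label = f"{_fmt(nd.node_mean, digits)}\\nn={nd.n_samples}"
            lines.append(f'  n{nid} [shape=oval, label="{label}"];')
        else:
            label = f"{nd.split_variable}\\nn={nd.n_samples}"
            lines.append(f'  n{nid} [shape=box, label="{label}"];')
    for nid in sorted(tree.nodes):
        nd = tree.nodes[nid]
        if nd.is_leaf:
            continue
        t = _fmt(nd.split_threshold, digits)
        lines.append(f'  n{nid} -> n{nd.left_child} [label="{nd.split_variable} < {t}"];')
        lines.append(f'  n{nid} -> n{nd.right_child} [label="{nd.split_variable} ≥ {t}"];')
    lines.append("}")
    return "\n".join(lines)


def _fmt(x: float, digits: int) -> str:
    if x is None or not math.isfinite(x):
        return "?"
    return f"{x:.{digits}g}"
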