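"""Repeated-holdout validation of the grow+prune pipeline.

The protocol: repeatedly draw a uniformly random train/test partition
(default 2/3 train, 1/3 test), refit the tree (growth plus pruning, same
policy as the headline fit) on the training rows, predict the test rows, and
score each run by the mean relative prediction error

    ER_run = (1/n) * sum_j |y_j - y_pred,j| / y_j

on the model (by default ln) scale.  The headline statistic is the mean and
standard deviation of ER over runs.  The absolute value makes ER a precision
measure; a signed variant (errors may cancel) is kept as an option.  Fully
reproducible given a seed: run r uses the seeded stream (seed, r).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dataio import ContractError, SampleTable
from .cart_core import FitSettings, grow_tree, predict
from .cart_prune import CVPolicy, LeafCountPolicy, prune_path, select_subtree

__all__ = ["ValidationReport", "relative_error", "split_indices", "holdout_validate"]


def relative_error(y_true, y_pred, signed: bool = False) -> float:
    """Mean relative prediction error (1/n) * sum |y - y_hat| / y.

    With ``signed=True`` the absolute value is dropped (positive and negative
    deviations may then cancel).  A zero true value is a contract error.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size == 0 or y_true.size != y_pred.size:
        raise ContractError("relative_error requires equal-length nonempty vectors")
    if np.any(y_true == 0):
        raise ContractError("a true value of 0 makes the relative error undefined")
    rel = (y_true - y_pred) / y_true
    if not signed:
        rel = np.abs(rel)
    return float(rel.mean())

log = logging.getLogger(__name__)


@dataclass
class ValidationReport:
    n_runs: int
    per_run_error: list[float]
    er_mean: float
    er_sd: float  # sample (n-1) sd over runs
    holdout_fraction: float
    error_scale: str  # "ln" | "raw"
    signed: bool = False
    failed_runs: int = 0

    def summary(self) -> str:
        return (
            f"ER = {100 * self.er_mean:.2f}% ± {100 * self.er_sd:.2f}% "
            f"(mean ± SD over {self.n_runs} runs, {self.error_scale} scale)"
        )


def split_indices(
    n: int, holdout_fraction: float, run: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/test partition; |test| = round(n * fraction).

    Deterministic for (n, run, seed); different runs under the same seed give
    independent partitions.
    """
    if n < 3:
        raise ContractError("need at least 3 samples to partition")
    if not 0 < holdout_fraction < 1:
        raise ContractError("holdout_fraction must be in (0, 1)")
    n_test = int(round(n * holdout_fraction))
    n_test = min(max(n_test, 1), n - 1)
    rng = np.random.default_rng([seed, run])
    perm = rng.permutation(n)
    return np.sort(perm[n_test:]), np.sort(perm[:n_test])


def holdout_validate(
    table: SampleTable,
    response: str,
    predictors: Sequence[str] | None = None,
    fit_settings: FitSettings = FitSettings(),
    prune_policy: LeafCountPolicy | CVPolicy | None = None,
    n_runs: int = 200,
    holdout_fraction: float = 1.0 / 3.0,
    seed: int = 0,
    error_scale: str | None = None,
    signed: bool = False,
) -> ValidationReport:
    """Repeated random 2/3–1/3 holdout with per-run refitting.

    ``prune_policy=None`` skips pruning (the full-grown tree predicts).
    ``error_scale`` defaults to the table's recorded transform for the
    response ("ln" if the response was ln-transformed, else "raw"); errors are
    computed on that scale.  A test response equal to 0 on the chosen scale is
    a contract error (the relative error is undefined); runs whose training
    subset cannot satisfy the fit preconditions are recorded as failed and
    excluded with a warning.
    """
    predictors = list(predictors) if predictors is not None else list(table.predictors)
    fit_table = table.complete_rows([*predictors, response])
    n = fit_table.n
    y_all = np.asarray(fit_table.data[response], dtype=float)
    if error_scale is None:
        error_scale = "ln" if fit_table.transform_of(response) == "ln" else "raw"
    if np.any(y_all == 0):
        raise ContractError("a response value of 0 makes the relative error undefined")

    errors: list[float] = []
    failed = 0
    for run in range(n_runs):
        train_idx, test_idx = split_indices(n, holdout_fraction, run, seed)
        train = SampleTable(
            data=fit_table.data.iloc[train_idx].reset_index(drop=True),
            predictors=list(fit_table.predictors),
            responses=list(fit_table.responses),
            transforms=dict(fit_table.transforms),
        )
        try:
            tree = grow_tree(train, response, predictors, fit_settings)
            if prune_policy is not None:
                path = prune_path(tree)
                tree = select_subtree(
                    path, prune_policy, table=train, response=response,
                    predictors=predictors, settings=fit_settings,
                )
        except ContractError as exc:
            failed += 1
            log.warning("run %d failed (%s); excluded", run, exc)
            continue
        test_rows = fit_table.data.iloc[test_idx]
        y_pred = predict(tree, test_rows)
        errors.append(relative_error(y_all[test_idx], y_pred, signed=signed))

    if not errors:
        raise ContractError("every validation run failed")
    arr = np.asarray(errors)
    return ValidationReport(
        n_runs=len(errors),
        per_run_error=errors,
        er_mean=float(arr.mean()),
        er_sd=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        holdout_fraction=holdout_fraction,
        error_scale=error_scale,
        signed=signed,
        failed_runs=failed,
    )
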