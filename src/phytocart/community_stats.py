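"""Descriptive and comparative statistics for the sampling campaigns.

Per-month marginal summaries (mean ± sd with range), one-way ANOVA across
months with Tukey HSD post hoc tests (Tukey–Kramer form for unequal group
sizes), Kolmogorov–Smirnov normality and Bartlett homoscedasticity checks,
the Spearman rank-correlation matrix across environmental variables and
responses (pairwise deletion), phylum abundance proportions, and the ln
transform applied to responses before tree fitting.

The KS test is run against a normal with the group's *estimated* mean and sd;
with estimated parameters the nominal p-values are conservative
(Lilliefors caveat).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import ContractError, SampleTable

__all__ = [
    "MonthlySummary",
    "CorrelationMatrix",
    "MonthComparison",
    "PhylumProportions",
    "summarize_by_month",
    "compare_months",
    "spearman_matrix",
    "phylum_proportions",
    "ln_transform",
]


@dataclass(frozen=True)
class MonthlySummary:
    month: str
    variable: str
    mean: float
    sd: float  # sample (n-1) convention; NaN when fewer than 2 values
    min: float
    max: float
    group_size: int

    def formatted(self, digits: int = 2) -> str:
        """"mean ± sd (min, max)" display string."""
        sd = "NA" if math.isnan(self.sd) else f"{self.sd:.{digits}f}"
        return (
            f"{self.mean:.{digits}f} ± {sd}"
            f"({self.min:.{digits}f}, {self.max:.{digits}f})"
        )


def summarize_by_month(table: SampleTable, columns: list[str] | None = None) -> list[MonthlySummary]:
    """Per-month mean/sd/min/max per variable, missing values excluded.

    sd uses the sample (n-1) convention and is reported as NaN for groups with
    fewer than two non-missing values (never as 0).
    """
    columns = columns if columns is not None else [*table.predictors, *table.responses]
    out: list[MonthlySummary] = []
    for month, group in table.data.groupby("month", sort=True):
        for col in columns:
            vals = group[col].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                continue
            out.append(
                MonthlySummary(
                    month=str(month),
                    variable=col,
                    mean=float(vals.mean()),
                    sd=float(vals.std(ddof=1)) if vals.size >= 2 else float("nan"),
                    min=float(vals.min()),
                    max=float(vals.max()),
                    group_size=int(vals.size),
                )
            )
    return out


@dataclass
class MonthComparison:
    variable: str
    F: float
    df1: int
    df2: int
    p: float
    tukey: pd.DataFrame  # columns: group1, group2, mean_diff, p_adj, reject (alpha=0.05)
    normality: dict[str, float]  # per-group KS p against N(mean, sd)
    homoscedasticity: float  # Bartlett p; NaN if any group has zero variance


def compare_months(table: SampleTable, variable: str, alpha: float = 0.05) -> MonthComparison:
    """One-way ANOVA of ``variable`` across months with post hoc Tukey HSD.

    df convention: (groups - 1, N - groups).  Requires >= 2 months each with
    >= 2 non-missing values.
    """
    groups: dict[str, np.ndarray] = {}
    for month, grp in table.data.groupby("month", sort=True):
        vals = grp[variable].dropna().to_numpy(dtype=float)
        if vals.size >= 2:
            groups[str(month)] = vals
    if len(groups) < 2:
        raise ContractError("compare_months requires >= 2 months with >= 2 values each")
    labels = list(groups)
    arrays = [groups[m] for m in labels]
    n_total = sum(a.size for a in arrays)
    df1, df2 = len(arrays) - 1, n_total - len(arrays)

    F, p = stats.f_oneway(*arrays)

    hsd = stats.tukey_hsd(*arrays)
    rows = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            p_adj = float(hsd.pvalue[i, j])
            rows.append(
                {
                    "group1": labels[i],
                    "group2": labels[j],
                    "mean_diff": float(arrays[i].mean() - arrays[j].mean()),
                    "p_adj": p_adj,
                    "reject": p_adj < alpha,
                }
            )
    tukey = pd.DataFrame(rows)

    normality = {}
    for m, a in groups.items():
        sd = a.std(ddof=1)
        if sd == 0:
            normality[m] = float("nan")
        else:
            normality[m] = float(stats.kstest(a, "norm", args=(a.mean(), sd)).pvalue)

    if any(a.std(ddof=1) == 0 for a in arrays):
        bartlett_p = float("nan")
    else:
        bartlett_p = float(stats.bartlett(*arrays).pvalue)

    return MonthComparison(
        variable=variable,
        F=float(F),
        df1=df1,
        df2=df2,
        p=float(p),
        tukey=tukey,
        normality=normality,
        homoscedasticity=bartlett_p,
    )


@dataclass
class CorrelationMatrix:
    variables: list[str]
    rho: pd.DataFrame  # Spearman coefficients, unit diagonal
    p: pd.DataFrame
    tiers: pd.DataFrame  # "p<0.001" | "p<0.01" | "p<0.05" | "ns"

    def tier_of(self, a: str, b: str) -> str:
        return str(self.tiers.loc[a, b])


def _tier(p: float) -> str:
    if math.isnan(p):
        return "ns"
    if p < 0.001:
        return "p<0.001"
    if p < 0.01:
        return "p<0.01"
    if p < 0.05:
        return "p<0.05"
    return "ns"


def spearman_matrix(table: SampleTable, columns: list[str] | None = None) -> CorrelationMatrix:
    """Spearman rank correlations with pairwise deletion.

    Average ranks on ties; p-values from the t-distribution approximation.
    Pairs with a constant column (or < 3 complete cases) get NaN.
    """
    columns = columns if columns is not None else [*table.predictors, *table.responses]
    k = len(columns)
    rho = np.eye(k)
    pmat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            sub = table.data[[columns[i], columns[j]]].dropna()
            if len(sub) < 3:
                r, p = float("nan"), float("nan")
            else:
                x = sub.iloc[:, 0].to_numpy(dtype=float)
                y = sub.iloc[:, 1].to_numpy(dtype=float)
                if np.all(x == x[0]) or np.all(y == y[0]):
                    r, p = float("nan"), float("nan")
                else:
                    res = stats.spearmanr(x, y)
                    r, p = float(res.statistic), float(res.pvalue)
            rho[i, j] = rho[j, i] = r
            pmat[i, j] = pmat[j, i] = p
    rho_df = pd.DataFrame(rho, index=columns, columns=columns)
    p_df = pd.DataFrame(pmat, index=columns, columns=columns)
    tiers = p_df.map(_tier)
    for c in columns:
        tiers.loc[c, c] = "p<0.001"
    return CorrelationMatrix(variables=list(columns), rho=rho_df, p=p_df, tiers=tiers)


@dataclass
class PhylumProportions:
    per_sample: pd.DataFrame  # index sample_id, columns phyla, rows sum to 1
    per_month: pd.DataFrame | None  # month x phylum mean of per-sample proportions
    dominant_species: pd.Series  # species ranked by mean abundance, descending
    excluded_samples: list


def phylum_proportions(species_table: pd.DataFrame) -> PhylumProportions:
    """Phylum abundance proportions from a long-format species table.

    Expects columns ``sample_id``, ``species``, ``phylum``, ``abundance`` and
    optionally ``month`` (enables per-month averages of per-sample
    proportions).  All-zero samples are excluded (returned in
    ``excluded_samples``); negative abundances are a contract error.
    """
    required = {"sample_id", "species", "phylum", "abundance"}
    missing = required - set(species_table.columns)
    if missing:
        raise ContractError(f"species table lacks column(s): {', '.join(sorted(missing))}")
    if (species_table["abundance"] < 0).any():
        raise ContractError("abundance must be >= 0")

    totals = species_table.groupby("sample_id")["abundance"].sum()
    excluded = totals.index[totals == 0].tolist()
    kept = species_table[~species_table["sample_id"].isin(excluded)]
    if kept.empty:
        raise ContractError("no sample with positive total abundance")

    by_phylum = (
        kept.groupby(["sample_id", "phylum"])["abundance"].sum().unstack(fill_value=0.0)
    )
    per_sample = by_phylum.div(by_phylum.sum(axis=1), axis=0)

    per_month = None
    if "month" in kept.columns:
        month_of = kept.drop_duplicates("sample_id").set_index("sample_id")["month"]
        per_month = per_sample.groupby(month_of).mean()

    dominant = (
        kept.groupby("species")["abundance"].mean().sort_values(ascending=False)
    )
    return PhylumProportions(
        per_sample=per_sample,
        per_month=per_month,
        dominant_species=dominant,
        excluded_samples=excluded,
    )


def ln_transform(table: SampleTable, response: str) -> SampleTable:
    """Replace ``response`` with its natural log; records the transform so
    predictions can be back-transformed.  Any value <= 0 is a contract error
    naming the row."""
    if response not in table.data.columns:
        raise ContractError(f"unknown response column {response!r}")
    vals = table.data[response]
    bad = vals.notna() & (vals <= 0)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ContractError(f"ln transform requires positive values; row {row} has {vals.iloc[row]}")
    data = table.data.copy()
    data[response] = np.log(vals.astype(float))
    transforms = {**table.transforms, response: "ln"}
    return replace(table, data=data, transforms=transforms)
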