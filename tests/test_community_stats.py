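"""Monthly summaries, ANOVA/post hoc machinery, correlations, proportions."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phytocart.dataio import ContractError
from phytocart.community_stats import (
    compare_months,
    ln_transform,
    phylum_proportions,
    spearman_matrix,
    summarize_by_month,
)

from conftest import make_table


def table_with_months(values_by_month: dict, var: str = "WT"):
    rows = []
    for month, vals in values_by_month.items():
        for v in vals:
            rows.append({"site": f"s{len(rows)}", "month": month, var: v, "richness": 1})
    return make_table(
        {k: [r[k] for r in rows] for k in rows[0]}, predictors=[var], responses=["richness"]
    )


def test_monthly_summary_hand_values():
    table = table_with_months({"2019-04": [8.0, 10.0, 12.0]})
    (s,) = [s for s in summarize_by_month(table, ["WT"])]
    assert (s.mean, s.sd, s.min, s.max, s.group_size) == (10.0, 2.0, 8.0, 12.0, 3)
    assert s.formatted() == "10.00 ± 2.00(8.00, 12.00)"


def test_single_row_month_has_undefined_sd():
    table = table_with_months({"2019-04": [7.5]})
    (s,) = summarize_by_month(table, ["WT"])
    assert s.mean == 7.5 and math.isnan(s.sd)


def test_constant_column_has_zero_sd():
    table = table_with_months({"2019-04": [5.0, 5.0, 5.0]})
    (s,) = summarize_by_month(table, ["WT"])
    assert s.sd == 0.0 and s.min == s.max == s.mean == 5.0


def test_anova_hand_computation():
    table = table_with_months({"a": [1.0, 2, 3], "b": [4.0, 5, 6]})
    res = compare_months(table, "WT")
    assert res.F == pytest.approx(13.5)
    assert (res.df1, res.df2) == (1, 4)
    assert len(res.tukey) == 1
    assert res.tukey.loc[0, "mean_diff"] == pytest.approx(-3.0)


def test_identical_groups_give_zero_f():
    table = table_with_months({"a": [1.0, 2, 3], "b": [1.0, 2, 3]})
    res = compare_months(table, "WT")
    assert res.F == pytest.approx(0.0)
    assert res.p == pytest.approx(1.0)


def test_df_convention_eight_groups():
    rng = np.random.default_rng(0)
    sizes = [20] * 7 + [19]  # N = 159 over 8 campaigns
    table = table_with_months(
        {f"m{i}": rng.normal(size=s).tolist() for i, s in enumerate(sizes)}
    )
    res = compare_months(table, "WT")
    assert (res.df1, res.df2) == (7, 151)
    assert set(res.normality) == {f"m{i}" for i in range(8)}
    assert 0 <= res.homoscedasticity <= 1


def test_zero_variance_group_gives_undefined_bartlett():
    table = table_with_months({"a": [2.0, 2.0, 2.0], "b": [1.0, 2, 3]})
    res = compare_months(table, "WT")
    assert math.isnan(res.homoscedasticity)


def test_fewer_than_two_groups_is_contract_error():
    table = table_with_months({"a": [1.0, 2, 3]})
    with pytest.raises(ContractError):
        compare_months(table, "WT")


def test_duplicated_rows_change_df_not_group_means():
    base = {"a": [1.0, 2, 3], "b": [4.0, 5, 6]}
    doubled = {k: v * 2 for k, v in base.items()}
    r1 = compare_months(table_with_months(base), "WT")
    r2 = compare_months(table_with_months(doubled), "WT")
    assert r2.df2 == 2 * r1.df2 + r1.df1 + 1  # N doubles, groups unchanged
    assert r1.tukey["mean_diff"].tolist() == r2.tukey["mean_diff"].tolist()


# --- Spearman matrix -------------------------------------------------------


def corr_table(x, y):
    return make_table(
        {"a": list(x), "b": list(y), "richness": [1] * len(x)},
        predictors=["a", "b"], responses=["richness"],
    )


@pytest.mark.parametrize(
    "x,y,expected",
    [
        ([1, 2, 3], [1, 2, 3], 1.0),
        ([1, 2, 3], [3, 2, 1], -1.0),
        ([1, 2, 3, 4, 5], [1, 3, 2, 5, 4], 0.8),
    ],
)
def test_spearman_hand_values(x, y, expected):
    corr = spearman_matrix(corr_table(x, y), ["a", "b"])
    assert corr.rho.loc["a", "b"] == pytest.approx(expected, abs=1e-12)
    assert corr.rho.loc["b", "a"] == corr.rho.loc["a", "b"]
    assert corr.rho.loc["a", "a"] == 1.0


def test_constant_column_gives_undefined_rho():
    corr = spearman_matrix(corr_table([2, 2, 2, 2], [1, 2, 3, 4]), ["a", "b"])
    assert math.isnan(corr.rho.loc["a", "b"])
    assert corr.tier_of("a", "b") == "ns"


def test_pairwise_deletion_uses_complete_cases():
    table = corr_table([1, 2, 3, 4, np.nan], [1, 2, 3, 4, 5])
    corr = spearman_matrix(table, ["a", "b"])
    assert corr.rho.loc["a", "b"] == pytest.approx(1.0)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 2**16))
def test_spearman_invariant_under_monotone_transform(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=12)
    y = rng.normal(size=12)
    base = spearman_matrix(corr_table(x, y), ["a", "b"]).rho.loc["a", "b"]
    warped = spearman_matrix(corr_table(np.exp(x), y**3 + 5 * y), ["a", "b"]).rho.loc["a", "b"]
    assert warped == pytest.approx(base, abs=1e-12)


def test_tiers_consistent_with_p(synth_table):
    corr = spearman_matrix(synth_table)
    for a in corr.variables:
        for b in corr.variables:
            p = corr.p.loc[a, b]
            tier = corr.tiers.loc[a, b]
            if a == b or math.isnan(p):
                continue
            if p < 0.001:
                assert tier == "p<0.001"
            elif p >= 0.05:
                assert tier == "ns"


# --- phylum proportions ----------------------------------------------------


def species_frame(rows):
    return pd.DataFrame(rows, columns=["sample_id", "species", "phylum", "abundance", "month"])


def test_single_sample_proportions():
    out = phylum_proportions(
        species_frame(
            [("s1", "spA", "Bacillariophyta", 30.0, "2019-04"),
             ("s1", "spB", "Cyanobacteria", 70.0, "2019-04")]
        )
    )
    assert out.per_sample.loc["s1", "Bacillariophyta"] == pytest.approx(0.3)
    assert out.per_sample.loc["s1", "Cyanobacteria"] == pytest.approx(0.7)


def test_month_average_of_per_sample_proportions():
    out = phylum_proportions(
        species_frame(
            [("s1", "spA", "B", 2.0, "m"), ("s1", "spB", "C", 8.0, "m"),
             ("s2", "spA", "B", 4.0, "m"), ("s2", "spB", "C", 6.0, "m")]
        )
    )
    assert out.per_month.loc["m", "B"] == pytest.approx(0.3)
    assert out.per_month.loc["m", "C"] == pytest.approx(0.7)


def test_single_phylum_sample_is_all_one():
    out = phylum_proportions(species_frame([("s1", "spA", "B", 5.0, "m")]))
    assert out.per_sample.loc["s1", "B"] == 1.0


def test_all_zero_sample_is_excluded():
    out = phylum_proportions(
        species_frame([("s1", "spA", "B", 0.0, "m"), ("s2", "spA", "B", 3.0, "m")])
    )
    assert out.excluded_samples == ["s1"]
    assert list(out.per_sample.index) == ["s2"]


def test_proportions_sum_to_one_within_tolerance():
    rng = np.random.default_rng(4)
    rows = [
        (f"s{i}", f"sp{j}", f"phy{j % 3}", float(rng.uniform(0, 100)), "m")
        for i in range(10) for j in range(7)
    ]
    out = phylum_proportions(species_frame(rows))
    assert np.allclose(out.per_sample.sum(axis=1), 1.0, atol=1e-12)
    assert out.dominant_species.index[0] == out.dominant_species.idxmax()


# --- ln transform ----------------------------------------------------------


def test_ln_transform_values_and_metadata():
    table = make_table(
        {"WT": [1.0, 2.0], "richness": [28.0, 1.0]}, ["WT"], ["richness"]
    )
    out = ln_transform(table, "richness")
    assert out.data["richness"].tolist() == pytest.approx([math.log(28), 0.0], abs=1e-4)
    assert out.data["richness"].iloc[0] == pytest.approx(3.3322, abs=1e-4)
    assert out.transform_of("richness") == "ln"
    assert table.data["richness"].iloc[0] == 28.0  # original untouched


def test_ln_transform_rejects_nonpositive():
    table = make_table({"WT": [1.0, 2.0], "richness": [28.0, 0.0]}, ["WT"], ["richness"])
    with pytest.raises(ContractError, match="row 1"):
        ln_transform(table, "richness")
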