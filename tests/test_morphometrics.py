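"""Cell/tissue statistics: CVcv, growth, proportions, staging, divisions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cellnerve import (
    cvcv,
    division_summary,
    growth_table,
    make_growth_series,
    relative_increase,
    stage_threshold_extrapolation,
    tissue_proportions,
)


def test_cvcv_constant_is_zero():
    assert cvcv([50.0, 50.0, 50.0]) == 0.0


def test_cvcv_hand_computed_pair():
    # {1, 3}: sd (n-1) = sqrt(2), mean = 2  ->  sqrt(2)/2
    assert cvcv([1.0, 3.0]) == pytest.approx(np.sqrt(2) / 2)


@settings(max_examples=30, deadline=None)
@given(st.lists(st.floats(min_value=1.0, max_value=1e4), min_size=2, max_size=50),
       st.floats(min_value=0.1, max_value=100.0))
def test_cvcv_scale_and_permutation_invariance(volumes, scale):
    arr = np.asarray(volumes)
    assert cvcv(scale * arr) == pytest.approx(cvcv(arr), rel=1e-9)
    assert cvcv(arr[::-1]) == pytest.approx(cvcv(arr), rel=1e-9)


def test_cvcv_validation():
    with pytest.raises(ValueError):
        cvcv([1.0])


def test_relative_increase():
    assert relative_increase(2.0, 2.0) == 0.0
    assert relative_increase(2.0, 3.0) == 0.5
    with pytest.raises(ValueError):
        relative_increase(0.0, 1.0)


def test_relative_increase_series_matches_loop(rng):
    series = rng.uniform(1, 100, size=10)
    got = [relative_increase(a, b) for a, b in zip(series[:-1], series[1:])]
    expected = [(series[i + 1] - series[i]) / series[i] for i in range(9)]
    np.testing.assert_allclose(got, expected)


def test_growth_table_toy(toy_table):
    # mean per-sample L1 volume: 100 at both stages; L2: 240 at both stages
    g = growth_table(toy_table, measure="tissue_volume")
    assert len(g) == 2  # (2 stages - 1) x 2 tissues
    assert (g["relative_increase"] == 0.0).all()
    counts = growth_table(toy_table, measure="cell_count")
    assert (counts["relative_increase"] == 0.0).all()


def test_growth_table_doubling_series():
    table = make_growth_series({"L1": [10.0, 20.0, 40.0]},
                               stages=("1-I", "1-II", "2-I"), n_samples=3,
                               cells_per_tissue=10, volume_cv=0.0, seed=0)
    g = growth_table(table, measure="tissue_volume")
    np.testing.assert_allclose(g["relative_increase"], [1.0, 1.0])
    np.testing.assert_allclose(g["percent_change"], [100.0, 100.0])


def test_growth_table_missing_tissue_flagged():
    table = make_growth_series({"L1": [10.0, 20.0], "L2": [5.0, 6.0]},
                               stages=("1-I", "1-II"), n_samples=2,
                               cells_per_tissue=5, seed=0)
    table = table[~((table["tissue_id"] == "L2") & (table["stage"] == "1-II"))]
    g = growth_table(table, measure="tissue_volume")
    l2 = g[g["tissue_id"] == "L2"].iloc[0]
    assert l2["missing"] and np.isnan(l2["relative_increase"])


def test_growth_table_needs_two_stages(toy_table):
    with pytest.raises(ValueError):
        growth_table(toy_table[toy_table["stage"] == "2-I"])


def test_tissue_proportions_sum_to_one(toy_table):
    for measure in ("volume", "cell_count"):
        props = tissue_proportions(toy_table, measure=measure)
        sums = props.groupby("sample_id")["share"].sum()
        np.testing.assert_allclose(sums, 1.0)


def test_tissue_proportions_hand_values():
    table = pd.DataFrame({
        "sample_id": ["s", "s"], "cohort": "A", "stage": "1-I",
        "cell_id": [1, 2], "tissue_id": ["A", "B"], "volume": [30.0, 70.0],
    })
    props = tissue_proportions(table).set_index("tissue_id")["share"]
    assert props["A"] == pytest.approx(0.3)
    assert props["B"] == pytest.approx(0.7)
    single = tissue_proportions(table[table["tissue_id"] == "A"])
    assert single["share"].tolist() == [1.0]


def test_stage_threshold_extrapolation():
    assert stage_threshold_extrapolation(2.0, 4.0, 10.0) == 5.0
    assert stage_threshold_extrapolation(0.0, 4.0, 10.0) == 0.0
    with pytest.raises(ValueError):
        stage_threshold_extrapolation(1.0, 0.0, 10.0)


@settings(max_examples=30, deadline=None)
@given(st.tuples(*[st.floats(min_value=0.01, max_value=1e3)] * 3))
def test_stage_threshold_random_triples(triple):
    a, b, c = triple
    assert stage_threshold_extrapolation(a, b, c) == pytest.approx(a / b * c)


def _tally(n_peri, n_anti, stage="3-III"):
    return pd.DataFrame({
        "division_class": ["periclinal"] * n_peri + ["anticlinal"] * n_anti,
        "stage": [stage] * (n_peri + n_anti),
    })


def test_division_summary_published_tallies():
    summary = division_summary(_tally(40, 30)).set_index("division_class")
    assert summary.loc["periclinal", "count"] == 40
    assert summary.loc["periclinal", "total"] == 70
    assert summary.loc["periclinal", "percent_rounded"] == 57
    assert summary.loc["anticlinal", "percent_rounded"] == 43
    late = division_summary(_tally(34, 6)).set_index("division_class")
    assert late.loc["periclinal", "percent_rounded"] == 85


def test_division_summary_single_class_and_sum():
    only = division_summary(_tally(12, 0))
    assert only["percent"].tolist() == [100.0]
    both = division_summary(_tally(40, 30))
    assert both["percent"].sum() == pytest.approx(100.0)


def test_division_summary_grouped():
    tally = pd.concat([_tally(4, 1, "3-III"), _tally(2, 3, "3-IV")])
    grouped = division_summary(tally, by=["stage"])
    assert grouped["count"].sum() == 10
    assert (grouped["total"] == 10).all()


def test_division_summary_empty():
    with pytest.raises(ValueError):
        division_summary(pd.DataFrame({"division_class": []}))
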