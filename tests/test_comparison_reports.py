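"""Comparison statistics: modal factors, percentage differences against the
published per-biome tables, cross-tabs, overlaps, areas, ratios, AGC summaries."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluxgap import (
    DataError,
    EmptyStratumError,
    ForestType,
    UndefinedRatioError,
    agc_summary,
    area_table,
    cross_tabulate,
    iqr_overlap,
    load_table,
    modal_factor,
    overlap_percent,
    pct_difference,
    removals_by_type_report,
    run_gain_loss,
    swamp_dry_ratio,
)
from fluxgap.comparison_reports import (
    old_growth_factor_differences,
    round_half_away,
    secondary_plantation_factor_differences,
)

from conftest import random_stack


# ------------------------------------------------------------ modal factor

def test_modal_factor_basics():
    layer = np.array([0.59] * 60 + [0.24] * 40)
    assert modal_factor(layer, np.ones(100, bool)) == 0.59
    uniform = np.full(10, 0.24)
    assert modal_factor(uniform, np.ones(10, bool)) == 0.24
    tie = np.array([0.24] * 50 + [0.59] * 50)
    assert modal_factor(tie, np.ones(100, bool)) == 0.24  # ties -> smallest
    with pytest.raises(EmptyStratumError):
        modal_factor(layer, np.zeros(100, bool))


def test_modal_factor_is_member_of_stratum(rng):
    layer = rng.choice([0.1, 0.24, 0.59, 0.95], size=500)
    mask = rng.random(500) < 0.5
    assert modal_factor(layer, mask) in set(layer[mask])


# ------------------------------------------------- percentage differences

OLD_GROWTH_ROWS = load_table("table5").to_dict("records")
SECONDARY_ROWS = [
    r
    for r in load_table("table6").to_dict("records")
    if not pd.isna(r["printed_pct_diff"])
]


@pytest.mark.parametrize("row", OLD_GROWTH_ROWS, ids=lambda r: r["biome"])
def test_old_growth_factor_differences_match_printed(row):
    """Per-biome old-growth removal-factor gaps at printed (integer) precision."""
    got = pct_difference(row["eo_comparison"], row["nghgi_rf"], decimals=0)
    assert got == row["printed_pct_diff"]


@pytest.mark.parametrize(
    "row", SECONDARY_ROWS, ids=lambda r: f"{r['stratum']}-{r['biome']}"
)
def test_secondary_plantation_differences_match_printed(row):
    got = pct_difference(row["eo_rf"], row["nghgi_rf"], decimals=int(row["printed_decimals"]))
    assert got == row["printed_pct_diff"]


def test_pct_difference_identity_and_zero_reference():
    assert pct_difference(3.3, 3.3) == 0.0
    with pytest.raises(UndefinedRatioError):
        pct_difference(1.0, 0.0)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    a=st.floats(min_value=0.01, max_value=1e3),
    b=st.floats(min_value=0.01, max_value=1e3),
)
def test_pct_difference_reciprocal_identity(a, b):
    """(1 + p_ab/100)(1 + p_ba/100) = 1 before rounding."""
    p_ab = pct_difference(a, b, decimals=12)
    p_ba = pct_difference(b, a, decimals=12)
    assert (1 + p_ab / 100) * (1 + p_ba / 100) == pytest.approx(1.0, rel=1e-9)


def test_round_half_away_from_zero():
    assert round_half_away(-12.5) == -13.0
    assert round_half_away(12.5) == 13.0
    assert round_half_away(31.746, 1) == 31.7


# ------------------------------------------------------------- cross-tabs

def test_cross_tabulate_identity_and_counts(stack64):
    ct = cross_tabulate(stack64.forest_type_t0, stack64.forest_type_t0)
    present = [i for i, ft in enumerate(ct.row_classes)
               if (stack64.forest_type_t0 == int(ft)).any()]
    diag = ct.percentages[present, present]
    np.testing.assert_allclose(diag, 100.0)
    assert ct.counts.sum() == stack64.n_cells
    row_sums = ct.percentages.sum(axis=1)
    np.testing.assert_allclose(row_sums[present], 100.0, atol=1e-6)


def test_cross_tabulate_confusion_recovery(rng):
    """A configured 65% relabeling rate is recovered within 3 binomial SE."""
    n = 10_000
    p = 0.65
    map_a = np.full(n, int(ForestType.old_secondary), np.uint8)
    fired = rng.random(n) < p
    map_b = np.where(fired, int(ForestType.primary_old_growth), map_a).astype(np.uint8)
    ct = cross_tabulate(map_a, map_b)
    i = ct.row_classes.index(ForestType.old_secondary)
    j = ct.col_classes.index(ForestType.primary_old_growth)
    recovered = ct.percentages[i, j]
    se = 100 * np.sqrt(p * (1 - p) / n)
    assert abs(recovered - 100 * p) <= 3 * se


def test_cross_tabulate_empty_mask_and_misalignment(stack64):
    ct = cross_tabulate(
        stack64.forest_type_t0, stack64.alt_class, mask=np.zeros(stack64.shape, bool)
    )
    assert ct.counts.sum() == 0
    assert set(ct.empty_rows) == set(ct.row_classes)
    with pytest.raises(DataError):
        cross_tabulate(stack64.forest_type_t0, stack64.alt_class[:10])


# ---------------------------------------------------------------- overlap

def test_overlap_percent_cases():
    a = np.zeros(100, bool)
    b = np.zeros(100, bool)
    b[:50] = True
    assert overlap_percent(b, b) == 100.0
    a[50:60] = True
    assert overlap_percent(a, b) == 0.0
    # a subset of b with |a| = 0.11 |b| gives exactly 11%.
    b = np.zeros(100, bool)
    b[:100] = True
    a = np.zeros(100, bool)
    a[:11] = True
    assert overlap_percent(a, b) == 11.0
    with pytest.raises(EmptyStratumError):
        overlap_percent(a, np.zeros(100, bool))


# ------------------------------------------------------------ area tables

def test_area_table_arithmetic():
    stack = random_stack(seed=31, size=10)
    stack = dataclasses.replace(
        stack,
        forest_type_t0=np.full(stack.shape, int(ForestType.plantation_forest), np.uint8),
        loss_year=np.full(stack.shape, 0, np.int16),
        gain_flag=np.zeros(stack.shape, bool),
        agc_t0=np.ones(stack.shape, np.float32),
        biome=np.zeros(stack.shape, np.uint8),
    )
    table = area_table(stack)
    assert table.total() == pytest.approx(100 * 0.09 / 1000)  # 0.009 thousand ha


def test_area_table_tiling_invariance(stack64):
    whole = area_table(stack64).table.groupby("label")["area_kha"].sum()
    halves = []
    for rows in (slice(0, 32), slice(32, 64)):
        sub = dataclasses.replace(
            stack64,
            forest_type_t0=stack64.forest_type_t0[rows],
            agc_t0=stack64.agc_t0[rows],
            loss_year=stack64.loss_year[rows],
            gain_flag=stack64.gain_flag[rows],
            alt_class=stack64.alt_class[rows],
            biome=stack64.biome[rows],
            peat=stack64.peat[rows],
            managed_land=None,
            managed_forest=None,
        )
        halves.append(area_table(sub).table.groupby("label")["area_kha"].sum())
    tiled = halves[0].add(halves[1], fill_value=0.0)
    pd.testing.assert_series_equal(
        whole.sort_index(), tiled.sort_index(), check_names=False, rtol=1e-12
    )


# ------------------------------------------------- published area fixtures

def test_indonesia_swamp_dry_ratios_from_printed_areas():
    t7 = load_table("table7")
    indo = t7[t7["country"] == "Indonesia"]
    nghgi = indo[indo["dataset"] == "nghgi"]
    eo = indo[indo["dataset"] == "global_eo"]
    swamp = nghgi[nghgi["wetness"] == "swamp"]["land_type"]
    dry = nghgi[nghgi["wetness"] == "dry"]["land_type"]
    assert swamp_dry_ratio(nghgi, swamp, dry) == 0.15
    swamp = eo[eo["wetness"] == "swamp"]["land_type"]
    dry = eo[eo["wetness"] == "dry"]["land_type"]
    assert swamp_dry_ratio(eo, swamp, dry) == 0.13
    with pytest.raises(UndefinedRatioError):
        zero_dry = nghgi.assign(area_kha=np.where(nghgi["wetness"] == "dry", 0.0,
                                                  nghgi["area_kha"]))
        swamp_dry_ratio(zero_dry,
                        nghgi[nghgi["wetness"] == "swamp"]["land_type"],
                        nghgi[nghgi["wetness"] == "dry"]["land_type"])


def test_equal_swamp_and_dry_areas_give_unity():
    table = pd.DataFrame(
        {"land_type": ["swampA", "dryA"], "area_kha": [123.4, 123.4]}
    )
    assert swamp_dry_ratio(table, ["swampA"], ["dryA"]) == 1.00


def test_printed_natural_forest_and_cropland_subtotals():
    t7 = load_table("table7")

    def subtotal(country, dataset, land_class):
        rows = t7[
            (t7["country"] == country)
            & (t7["dataset"] == dataset)
            & (t7["land_class"] == land_class)
        ]
        return float(rows["area_kha"].sum())

    assert subtotal("Indonesia", "nghgi", "natural_forest") == pytest.approx(89_274)
    assert subtotal("Malaysia", "global_eo", "natural_forest") == pytest.approx(17_441.2)
    assert subtotal("Malaysia", "nghgi", "cropland") == pytest.approx(7_038.75)
    assert round_half_away(subtotal("Malaysia", "nghgi", "cropland"), 1) == 7_038.8


def test_brazil_type_table_column_totals():
    t4 = load_table("table4")
    for dataset, expected in (("global_eo", -0.77), ("nghgi", -0.45)):
        rows = t4[t4["dataset"] == dataset]
        assert rows["gross_removals_gtco2_yr"].sum() == pytest.approx(expected, abs=1e-9)
        assert rows["area_kha"].sum() == 258_463


# --------------------------------------------------------- AGC summaries

def test_agc_summary_constant_layer():
    stack = random_stack(seed=33, size=8)
    stack = dataclasses.replace(stack, agc_t0=np.full(stack.shape, 77.0, np.float32))
    mean, q1, med, q3 = agc_summary(stack, np.ones(stack.shape, bool))
    assert mean == q1 == med == q3 == 77.0
    with pytest.raises(EmptyStratumError):
        agc_summary(stack, np.zeros(stack.shape, bool))


def test_agc_summary_lognormal_quantiles_match_closed_form(rng):
    median, sigma = 100.0, 0.5
    n = 10_000
    side = 100
    values = rng.lognormal(np.log(median), sigma, size=side * side).astype(np.float32)
    stack = random_stack(seed=35, size=side)
    stack = dataclasses.replace(stack, agc_t0=values.reshape(side, side))
    mean, q1, med, q3 = agc_summary(stack, np.ones(stack.shape, bool))
    z = 0.6744897501960817
    assert q1 == pytest.approx(median * np.exp(-sigma * z), rel=0.02)
    assert med == pytest.approx(median, rel=0.02)
    assert q3 == pytest.approx(median * np.exp(sigma * z), rel=0.02)


def test_iqr_overlap_predicate():
    assert not iqr_overlap((0.5, 0.0, 0.5, 1.0), (2.5, 2.0, 2.5, 3.0))
    assert iqr_overlap((1.0, 0.0, 1.0, 2.0), (2.0, 1.5, 2.0, 3.0))


# ------------------------------------------------ removals-by-type report

def test_removals_by_type_report_single_and_permuted(default_factors):
    stack = random_stack(seed=37)
    ledger = run_gain_loss(stack, default_factors)
    areas = area_table(stack)
    single = removals_by_type_report([ledger], [areas], ["eo"])
    assert single.loc["Total", "eo_gross_removals_mg_co2e_yr"] == pytest.approx(
        ledger.gross_removals(), rel=1e-9
    )
    two = removals_by_type_report([ledger, ledger], [areas, areas], ["a", "b"])
    swapped = removals_by_type_report([ledger, ledger], [areas, areas], ["b", "a"])
    pd.testing.assert_frame_equal(
        two[["a_area_kha", "a_gross_removals_mg_co2e_yr"]],
        swapped[["a_area_kha", "a_gross_removals_mg_co2e_yr"]],
    )


def test_fixture_driven_difference_reports_are_complete():
    og = old_growth_factor_differences()
    assert (og["pct_diff"] == og["printed_pct_diff"]).all()
    sp = secondary_plantation_factor_differences()
    comparable = sp[sp["printed_pct_diff"].notna()]
    assert len(comparable) == 12
    assert (comparable["pct_diff"] == comparable["printed_pct_diff"]).all()
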