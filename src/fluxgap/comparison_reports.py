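"""Inventory-comparison statistics and report tables.

Implements the comparison layer between an earth-observation flux dataset
and national-inventory reporting: modal removal factors per stratum,
rounded percentage differences between factor sets, classification
cross-tabulations between two forest-type maps, mask overlap fractions,
area tables in thousand hectares, swamp:dry forest area ratios, and
aboveground-carbon distribution summaries with an IQR-overlap check.

The packaged fixture CSVs under :mod:`fluxgap.data` transcribe the published
per-biome factor tables and country area tables these reports are checked
against; loaders are provided here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, EmptyStratumError, UndefinedRatioError
from .gainloss_engine import FluxLedger
from .synthetic_landscape import GridStack
from .types import ForestType

__all__ = [
    "CrossTab",
    "AreaTable",
    "round_half_away",
    "modal_factor",
    "pct_difference",
    "cross_tabulate",
    "overlap_percent",
    "area_table",
    "swamp_dry_ratio",
    "agc_summary",
    "iqr_overlap",
    "removals_by_type_report",
    "load_table",
    "old_growth_factor_differences",
    "secondary_plantation_factor_differences",
]

_TABLE_FILES = {
    "table4": "table4_forest_type_removals_brazil.csv",
    "table5": "table5_old_growth_removal_factors.csv",
    "table6": "table6_secondary_plantation_removal_factors.csv",
    "table7": "table7_land_areas_southeast_asia.csv",
    "table8": "table8_emission_removal_factors.csv",
}


def load_table(name: str) -> pd.DataFrame:
    """Load one packaged comparison fixture (``table4`` .. ``table8``)."""
    try:
        fname = _TABLE_FILES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(_TABLE_FILES)}")
    with resources.files("fluxgap.data").joinpath(fname).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (report convention; numpy rounds half-even)."""
    factor = 10.0 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


# ------------------------------------------------------------------ factors

def modal_factor(factor_layer: np.ndarray, stratum_mask: np.ndarray) -> float:
    """Most frequent factor value within a stratum; ties go to the smallest."""
    selected = np.asarray(factor_layer)[np.asarray(stratum_mask, dtype=bool)]
    if selected.size == 0:
        raise EmptyStratumError("modal_factor over an empty stratum")
    values, counts = np.unique(selected, return_counts=True)
    # np.unique returns ascending values, so argmax picks the smallest on ties.
    return float(values[np.argmax(counts)])


def pct_difference(candidate: float, reference: float, decimals: int = 0) -> float:
    """Rounded percentage difference, 100 x (candidate - reference) / reference."""
    if reference == 0:
        raise UndefinedRatioError("pct_difference with zero reference")
    return round_half_away(100.0 * (candidate - reference) / reference, decimals)


# ----------------------------------------------------------- cross-tab maps

@dataclass
class CrossTab:
    """Row-normalized classification-agreement matrix between two type maps."""

    row_classes: tuple[ForestType, ...]
    col_classes: tuple[ForestType, ...]
    counts: np.ndarray       # integer cell counts
    percentages: np.ndarray  # row-normalized to 100; zero-count rows all-zero
    empty_rows: tuple[ForestType, ...] = ()

    def to_frame(self, percentages: bool = True) -> pd.DataFrame:
        data = self.percentages if percentages else self.counts
        return pd.DataFrame(
            data,
            index=[ft.name for ft in self.row_classes],
            columns=[ft.name for ft in self.col_classes],
        )


def cross_tabulate(
    map_a: np.ndarray,
    map_b: np.ndarray,
    mask: Optional[np.ndarray] = None,
    classes: Sequence[ForestType] = tuple(ForestType),
) -> CrossTab:
    """Cross-tabulate two aligned categorical layers (rows = first map)."""
    a = np.asarray(map_a).ravel()
    b = np.asarray(map_b).ravel()
    if a.shape != b.shape:
        raise DataError(f"misaligned layers: {map_a.shape} vs {map_b.shape}")
    if mask is not None:
        m = np.asarray(mask, dtype=bool).ravel()
        if m.shape != a.shape:
            raise DataError("mask shape does not match layers")
        a, b = a[m], b[m]
    classes = tuple(classes)
    k = len(classes)
    code_to_idx = {int(ft): i for i, ft in enumerate(classes)}
    counts = np.zeros((k, k), dtype=np.int64)
    for code_a in np.unique(a):
        ia = code_to_idx.get(int(code_a))
        if ia is None:
            continue
        sub = b[a == code_a]
        for code_b, cnt in zip(*np.unique(sub, return_counts=True)):
            ib = code_to_idx.get(int(code_b))
            if ib is not None:
                counts[ia, ib] = cnt
    row_totals = counts.sum(axis=1)
    percentages = np.zeros_like(counts, dtype=np.float64)
    nonzero = row_totals > 0
    percentages[nonzero] = 100.0 * counts[nonzero] / row_totals[nonzero, None]
    empty = tuple(ft for ft, total in zip(classes, row_totals) if total == 0)
    return CrossTab(
        row_classes=classes,
        col_classes=classes,
        counts=counts,
        percentages=percentages,
        empty_rows=empty,
    )


def overlap_percent(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Percent of ``mask_b`` cells also in ``mask_a`` (denominator = second mask)."""
    a = np.asarray(mask_a, dtype=bool).ravel()
    b = np.asarray(mask_b, dtype=bool).ravel()
    if a.shape != b.shape:
        raise DataError("misaligned masks")
    nb = int(b.sum())
    if nb == 0:
        raise EmptyStratumError("overlap_percent with empty denominator mask")
    return 100.0 * int((a & b).sum()) / nb


# -------------------------------------------------------------- area tables

@dataclass
class AreaTable:
    """Areas (thousand hectares) keyed by (region, type label)."""

    table: pd.DataFrame  # columns: region, label, area_kha

    def total(self, region: Optional[str] = None) -> float:
        df = self.table if region is None else self.table[self.table["region"] == region]
        return float(df["area_kha"].sum())

    def subtotal(self, labels: Iterable[str], region: Optional[str] = None) -> float:
        df = self.table if region is None else self.table[self.table["region"] == region]
        return float(df[df["label"].isin(set(labels))]["area_kha"].sum())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def area_table(
    stack: GridStack,
    region_layer: str = "biome",
    type_layer: str = "forest_type_t0",
) -> AreaTable:
    """Per (region, forest type) area of a landscape, in thousand hectares."""
    region = getattr(stack, region_layer).ravel()
    types = getattr(stack, type_layer).ravel()
    if region.shape != types.shape:
        raise DataError("misaligned grouping layers")
    df = pd.DataFrame({"region_code": region.astype(int), "type_code": types.astype(int)})
    grouped = df.value_counts(["region_code", "type_code"]).reset_index(name="cells")
    grouped["region"] = [stack.biome_name(c) for c in grouped["region_code"]]
    grouped["label"] = [ForestType(c).name for c in grouped["type_code"]]
    grouped["area_kha"] = grouped["cells"] * stack.cell_area / 1000.0
    grouped = grouped.sort_values(["region_code", "type_code"]).reset_index(drop=True)
    return AreaTable(table=grouped[["region", "label", "area_kha"]])


def swamp_dry_ratio(
    table: pd.DataFrame,
    swamp_labels: Iterable[str],
    dry_labels: Iterable[str],
    area_column: str = "area_kha",
    label_column: str = "land_type",
    decimals: int = 2,
) -> float:
    """Ratio of total swamp (peatland) forest area to dry forest area."""
    swamp_labels, dry_labels = set(swamp_labels), set(dry_labels)
    swamp = table[table[label_column].isin(swamp_labels)]
    dry = table[table[label_column].isin(dry_labels)]
    if swamp.empty or dry.empty:
        raise DataError("swamp or dry label set resolves to no rows")
    dry_total = float(dry[area_column].sum())
    if dry_total == 0:
        raise UndefinedRatioError("zero dry forest area")
    return round_half_away(float(swamp[area_column].sum()) / dry_total, decimals)


# ----------------------------------------------------------- AGC summaries

def agc_summary(
    stack: GridStack, stratum_mask: np.ndarray
) -> tuple[float, float, float, float]:
    """(mean, q1, median, q3) of AGC over a stratum, Mg C/ha.

    Quantiles use linear interpolation between order statistics.
    """
    mask = np.asarray(stratum_mask, dtype=bool).ravel()
    values = stack.agc_t0.ravel()[mask]
    if values.size == 0:
        raise EmptyStratumError("agc_summary over an empty stratum")
    q1, med, q3 = np.quantile(values.astype(np.float64), [0.25, 0.5, 0.75])
    return float(values.mean()), float(q1), float(med), float(q3)


def iqr_overlap(
    summary_a: tuple[float, float, float, float],
    summary_b: tuple[float, float, float, float],
) -> bool:
    """True iff the two [q1, q3] interquartile intervals intersect."""
    _, q1a, _, q3a = summary_a
    _, q1b, _, q3b = summary_b
    return q1a <= q3b and q1b <= q3a


# ----------------------------------------------------- removals-by-type view

def removals_by_type_report(
    ledgers: Sequence[FluxLedger],
    areas: Sequence[AreaTable],
    labels: Sequence[str],
) -> pd.DataFrame:
    """Side-by-side area and gross removals per forest type for several datasets.

    Column sums are computed from the unrounded values and reported in a
    ``Total`` row. Datasets must share the forest-type vocabulary.
    """
    if not (len(ledgers) == len(areas) == len(labels)):
        raise DataError("ledgers, areas and labels must have equal length")
    frames = []
    vocab = None
    for ledger, area, label in zip(ledgers, areas, labels):
        removals = ledger.table[ledger.table["component"] == "removal"]
        by_type = removals.groupby("forest_type")["value_mg_co2e_per_yr"].sum()
        area_by_type = area.table.groupby("label")["area_kha"].sum()
        types = sorted(set(by_type.index) | set(area_by_type.index))
        if vocab is None:
            vocab = types
        elif set(types) - set(vocab):
            raise DataError(
                f"forest-type vocabulary mismatch: {sorted(set(types) - set(vocab))}"
            )
        frames.append(
            pd.DataFrame(
                {
                    f"{label}_area_kha": area_by_type.reindex(vocab).fillna(0.0),
                    f"{label}_gross_removals_mg_co2e_yr": by_type.reindex(vocab).fillna(0.0),
                }
            )
        )
    report = pd.concat(frames, axis=1)
    report.index.name = "forest_type"
    total = report.sum(axis=0).to_frame().T
    total.index = pd.Index(["Total"], name="forest_type")
    return pd.concat([report, total])


# ------------------------------------------------- fixture-driven comparisons

def old_growth_factor_differences() -> pd.DataFrame:
    """Recompute per-biome old-growth factor differences from the fixture.

    Adds a ``pct_diff`` column (nearest integer, half away from zero) from the
    EO comparison factor against the inventory factor.
    """
    df = load_table("table5").copy()
    df["pct_diff"] = [
        pct_difference(eo, ref, decimals=0)
        for eo, ref in zip(df["eo_comparison"], df["nghgi_rf"])
    ]
    return df


def secondary_plantation_factor_differences() -> pd.DataFrame:
    """Recompute plantation / young-secondary factor differences from the fixture."""
    df = load_table("table6").copy()
    comparable = df["printed_pct_diff"].notna()
    diffs = []
    for row in df.itertuples(index=False):
        if pd.isna(row.printed_pct_diff):
            diffs.append(np.nan)
        else:
            diffs.append(
                pct_difference(row.eo_rf, row.nghgi_rf, decimals=int(row.printed_decimals))
            )
    df["pct_diff"] = diffs
    return df[comparable | df["eo_rf"].notna()].reset_index(drop=True)
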