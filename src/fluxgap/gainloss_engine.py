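"""IPCC gain-loss carbon accounting applied per grid cell.

Each cell is classified into an IPCC land-use transition category, loss
events book a committed emission of the full carbon stock (aboveground pool
expanded to belowground/deadwood/litter via ratios, optionally soil), and
forested cell-years accrue removals at a stratum removal factor. All ledger
values are average-annual over the accounting period (total divided by the
period length in years), in Mg CO2e/yr.

The per-cell primitives (:func:`classify_transition`,
:func:`committed_emission`, :func:`removal_flux`) are scalar and exact; the
landscape engine (:func:`run_gain_loss`) is the vectorized composition of
the same arithmetic and is tested against a per-cell loop.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, DataError
from .synthetic_landscape import GridStack
from .types import (
    CO2_PER_C,
    EMISSION_COMPONENTS,
    LOSS_NONE,
    FluxComponent,
    ForestType,
    IpccCategory,
)

__all__ = [
    "RemovalFactor",
    "FactorTable",
    "AccountingOptions",
    "FluxLedger",
    "classify_transition",
    "committed_emission",
    "removal_flux",
    "run_gain_loss",
    "convert_units",
    "example_factor_table",
]

LEDGER_COLUMNS = [
    "region",
    "category",
    "forest_type",
    "component",
    "value_mg_co2e_per_yr",
    "period_start",
    "period_end",
    "provenance",
]


@dataclass(frozen=True)
class RemovalFactor:
    """Removal factor for one (biome, forest type) stratum, Mg C/ha/yr."""

    central: float
    low: Optional[float] = None
    high: Optional[float] = None


@dataclass(frozen=True)
class FactorTable:
    """Emission/removal factors and carbon-pool expansion ratios.

    Pool ratios expand aboveground carbon to the other biomass pools:
    belowground via the root:shoot ratio, deadwood and litter as fractions
    of AGC. ``soil_emission`` is a committed Mg C/ha released on loss when
    soil accounting is enabled. Peat terms are CO2e rates for drained /
    burned organic soils. ``carbon_fraction`` converts dry biomass to carbon.
    """

    removal_factor: Mapping[tuple[str, ForestType], RemovalFactor]
    root_shoot_ratio: Union[float, Mapping[str, float]] = 0.25
    deadwood_ratio: float = 0.10
    litter_ratio: float = 0.04
    soil_emission: float = 0.0          # Mg C/ha committed on loss
    peat_decomposition: float = 0.0     # Mg CO2e/ha/yr on drained peat
    peat_fire: float = 0.0              # Mg CO2e/ha per burn event
    flfl_burn_emission: float = 0.0     # Mg CO2e/ha per FL-FL burn event
    carbon_fraction: float = 0.47
    co2_per_c: float = CO2_PER_C

    def __post_init__(self):
        if not 0.0 < self.carbon_fraction < 1.0:
            raise ConfigurationError("carbon_fraction must be in (0, 1)")
        for name in ("deadwood_ratio", "litter_ratio", "soil_emission",
                     "peat_decomposition", "peat_fire", "flfl_burn_emission"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        for (biome, ft), rf in self.removal_factor.items():
            if rf.central < 0:
                raise ConfigurationError(
                    f"negative removal factor for ({biome}, {ft.name})"
                )

    def resolve(self, biome: str, forest_type: ForestType) -> float:
        """Central removal factor for a stratum (0 for nonforest)."""
        if forest_type == ForestType.nonforest:
            return 0.0
        try:
            return self.removal_factor[(biome, forest_type)].central
        except KeyError:
            raise ConfigurationError(
                f"no removal factor for stratum ({biome!r}, {forest_type.name})"
            ) from None

    def root_shoot(self, biome: Optional[str] = None) -> float:
        if isinstance(self.root_shoot_ratio, Mapping):
            if biome is None or biome not in self.root_shoot_ratio:
                raise ConfigurationError(f"no root:shoot ratio for biome {biome!r}")
            return float(self.root_shoot_ratio[biome])
        return float(self.root_shoot_ratio)

    # ------------------------------------------------------------------ I/O
    def to_csv(self, path) -> None:
        rows = [
            {
                "biome": biome,
                "forest_type": ft.name,
                "rf_central": rf.central,
                "rf_min": rf.low,
                "rf_max": rf.high,
            }
            for (biome, ft), rf in sorted(
                self.removal_factor.items(), key=lambda kv: (kv[0][0], int(kv[0][1]))
            )
        ]
        scalars = {
            "root_shoot_ratio": self.root_shoot_ratio
            if not isinstance(self.root_shoot_ratio, Mapping)
            else dict(self.root_shoot_ratio),
            "deadwood_ratio": self.deadwood_ratio,
            "litter_ratio": self.litter_ratio,
            "soil_emission": self.soil_emission,
            "peat_decomposition": self.peat_decomposition,
            "peat_fire": self.peat_fire,
            "flfl_burn_emission": self.flfl_burn_emission,
            "carbon_fraction": self.carbon_fraction,
        }
        with open(path, "w", encoding="utf-8") as fh:
            for line in yaml.safe_dump(scalars, sort_keys=True).splitlines():
                fh.write(f"# {line}\n")
            pd.DataFrame(rows).to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "FactorTable":
        header_lines = []
        body = io.StringIO()
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                if line.startswith("#"):
                    header_lines.append(line[1:].strip("\n").strip())
                else:
                    body.write(line)
        scalars = yaml.safe_load("\n".join(header_lines)) or {}
        body.seek(0)
        df = pd.read_csv(body)
        factors = {}
        for row in df.itertuples(index=False):
            rf = RemovalFactor(
                central=float(row.rf_central),
                low=None if pd.isna(row.rf_min) else float(row.rf_min),
                high=None if pd.isna(row.rf_max) else float(row.rf_max),
            )
            factors[(str(row.biome), ForestType[row.forest_type])] = rf
        return cls(removal_factor=factors, **scalars)


@dataclass(frozen=True)
class AccountingOptions:
    """Flags steering which components the engine books.

    ``removals_on_lost_cells``: whether FL->OL cells accrue removals up to
    (exclusive of) their loss year. ``treat_tree_crops_as_cropland`` follows
    the inventory convention of booking tree crops under cropland categories.
    Soil and peat terms default off (humid-forest, mineral-soil setting) and
    are switched on for peatland-country runs.
    """

    treat_tree_crops_as_cropland: bool = False
    include_soil: bool = False
    include_peat: bool = False
    include_flfl_burning: bool = False
    removals_on_lost_cells: bool = True
    provenance: str = "unadjusted"


@dataclass
class FluxLedger:
    """Gross fluxes disaggregated by region x category x type x component.

    Values are Mg CO2e/yr averaged over the period; removal rows are <= 0,
    emission rows >= 0, and the net flux is the plain algebraic sum.
    """

    table: pd.DataFrame
    period: tuple[int, int]
    provenance: str = "unadjusted"

    def net(self) -> float:
        return float(self.table["value_mg_co2e_per_yr"].sum())

    def gross_emissions(self) -> float:
        emission_names = {c.value for c in EMISSION_COMPONENTS}
        mask = self.table["component"].isin(emission_names)
        return float(self.table.loc[mask, "value_mg_co2e_per_yr"].sum())

    def gross_removals(self) -> float:
        mask = self.table["component"] == FluxComponent.removal.value
        return float(self.table.loc[mask, "value_mg_co2e_per_yr"].sum())

    def country_table(self) -> pd.DataFrame:
        """Aggregate biome rows into a single-country ledger table."""
        grouped = (
            self.table.groupby(["category", "forest_type", "component"], as_index=False)[
                "value_mg_co2e_per_yr"
            ]
            .sum()
        )
        grouped.insert(0, "region", "country")
        grouped["period_start"], grouped["period_end"] = self.period
        grouped["provenance"] = self.provenance
        return grouped[LEDGER_COLUMNS]

    def to_csv(self, path) -> None:
        self.table[LEDGER_COLUMNS].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FluxLedger":
        df = pd.read_csv(path)
        period = (int(df["period_start"].iloc[0]), int(df["period_end"].iloc[0]))
        prov = str(df["provenance"].iloc[0]) if len(df) else "unadjusted"
        return cls(table=df[LEDGER_COLUMNS], period=period, provenance=prov)

    def validate(self) -> None:
        removals = self.table["component"] == FluxComponent.removal.value
        if np.any(self.table.loc[removals, "value_mg_co2e_per_yr"] > 1e-12):
            raise DataError("positive removal row in ledger")
        if np.any(self.table.loc[~removals, "value_mg_co2e_per_yr"] < -1e-12):
            raise DataError("negative emission row in ledger")


# --------------------------------------------------------------- primitives

def classify_transition(
    forest_type_t0: ForestType,
    loss_year: int,
    gain_flag: bool,
    treat_tree_crops_as_cropland: bool = False,
) -> IpccCategory:
    """IPCC transition category of one cell over the period."""
    forest_type_t0 = ForestType(forest_type_t0)
    lost = loss_year != LOSS_NONE
    if forest_type_t0 == ForestType.nonforest:
        if lost:
            raise DataError("nonforest cell carries a loss year")
        return IpccCategory.OL_FL if gain_flag else IpccCategory.FL_FL
    if forest_type_t0 == ForestType.tree_crop and treat_tree_crops_as_cropland:
        return IpccCategory.OL_CL if gain_flag else IpccCategory.CL_CL
    return IpccCategory.FL_OL if lost else IpccCategory.FL_FL


def committed_emission(
    agc: float,
    factors: FactorTable,
    area: float,
    include_soil: bool = False,
    biome: Optional[str] = None,
) -> float:
    """Committed Mg CO2 booked when the full stock of one cell is lost."""
    if agc < 0:
        raise DataError("negative AGC")
    if area <= 0:
        raise DataError("area must be positive")
    pools = agc * (1.0 + factors.root_shoot(biome) + factors.deadwood_ratio + factors.litter_ratio)
    if include_soil:
        pools += factors.soil_emission
    return area * pools * factors.co2_per_c


def removal_flux(
    forest_type: ForestType,
    biome: str,
    loss_year: int,
    factors: FactorTable,
    area: float,
    period: tuple[int, int],
) -> float:
    """Average-annual removal of one cell, Mg CO2/yr (never positive).

    A cell lost in year ``y`` accrues removals for ``y - start`` years (up to,
    exclusive of, the loss year); an unlost cell accrues the full period.
    """
    start, end = period
    length = end - start + 1
    rf = factors.resolve(biome, ForestType(forest_type))
    if loss_year != LOSS_NONE:
        years_forested = max(0, min(loss_year, end + 1) - start)
    else:
        years_forested = length
    return -area * rf * factors.co2_per_c * (years_forested / length)


def convert_units(x: float, mode: str) -> float:
    """Unit conversions: carbon to CO2 (x 44/12) or dry biomass to carbon (x 0.47)."""
    if mode == "c_to_co2":
        return x * CO2_PER_C
    if mode == "biomass_to_c":
        return x * 0.47
    raise ConfigurationError(f"unknown conversion mode {mode!r}")


# ------------------------------------------------------------------- engine

@dataclass
class CellFluxes:
    """Per-cell flux components (flat arrays, Mg CO2e/yr) plus cell labels."""

    category: np.ndarray     # IpccCategory codes, int
    forest_type: np.ndarray  # ForestType codes, int
    biome: np.ndarray        # biome codes, int
    components: dict[FluxComponent, np.ndarray] = field(default_factory=dict)


def _vector_classify(stack: GridStack, options: AccountingOptions) -> np.ndarray:
    ft = stack.forest_type_t0.ravel()
    lost = stack.loss_year.ravel() != LOSS_NONE
    gain = stack.gain_flag.ravel()
    nonforest = ft == int(ForestType.nonforest)
    if np.any(lost & nonforest):
        raise DataError("nonforest cell carries a loss year")
    cat = np.where(lost, int(IpccCategory.FL_OL), int(IpccCategory.FL_FL))
    cat[nonforest & gain] = int(IpccCategory.OL_FL)
    cat[nonforest & ~gain] = int(IpccCategory.FL_FL)
    if options.treat_tree_crops_as_cropland:
        tc = ft == int(ForestType.tree_crop)
        cat[tc & gain] = int(IpccCategory.OL_CL)
        cat[tc & ~gain] = int(IpccCategory.CL_CL)
    return cat


def compute_cell_fluxes(
    stack: GridStack, factors: FactorTable, options: AccountingOptions = AccountingOptions()
) -> CellFluxes:
    """Vectorized per-cell gain-loss arithmetic for one landscape."""
    stack.validate()
    start, end = stack.period
    length = stack.period_length
    area = stack.cell_area
    n = stack.n_cells

    ft = stack.forest_type_t0.ravel().astype(np.int64)
    loss = stack.loss_year.ravel().astype(np.int64)
    gain = stack.gain_flag.ravel()
    biome = stack.biome.ravel().astype(np.int64)
    agc = stack.agc_t0.ravel().astype(np.float64)
    lost = loss != LOSS_NONE
    cat = _vector_classify(stack, options)

    per_biome_rs = isinstance(factors.root_shoot_ratio, Mapping)
    if per_biome_rs:
        rs = np.array(
            [factors.root_shoot(stack.biome_name(b)) for b in range(int(biome.max()) + 1)]
        )[biome]
    else:
        rs = factors.root_shoot()

    # Committed deforestation emissions, annualized over the period.
    pools = agc * (1.0 + rs + factors.deadwood_ratio + factors.litter_ratio)
    if options.include_soil:
        pools = pools + factors.soil_emission
    emis_def = np.where(lost, area * pools * factors.co2_per_c / length, 0.0)

    # Removals: stratum factor x forested-year fraction.
    biome_codes = np.unique(biome)
    rf_lut = np.zeros((int(biome_codes.max()) + 1, max(int(t) for t in ForestType) + 1))
    for b in biome_codes:
        bname = stack.biome_name(int(b))
        for t in ForestType:
            rf_lut[b, int(t)] = factors.resolve(bname, t)
    rf = rf_lut[biome, ft]
    years_forested = np.where(lost, np.clip(loss - start, 0, length), float(length))
    if not options.removals_on_lost_cells:
        years_forested = np.where(lost, 0.0, years_forested)
    nonforest = ft == int(ForestType.nonforest)
    # Gains on other land accrue at the young-secondary stratum factor.
    gained = nonforest & gain
    rf = np.where(
        gained, rf_lut[biome, int(ForestType.young_secondary)], np.where(nonforest, 0.0, rf)
    )
    years_forested = np.where(gained, float(length), years_forested)
    removal = -area * rf * factors.co2_per_c * (years_forested / length)

    components = {
        FluxComponent.emission_deforestation: emis_def,
        FluxComponent.removal: removal,
    }

    if options.include_peat:
        peat = stack.peat.ravel()
        drained = peat & lost
        # Decomposition runs from the loss year through the period end.
        years_drained = np.where(drained, end - loss + 1, 0.0)
        components[FluxComponent.emission_peat_decomposition] = (
            area * factors.peat_decomposition * years_drained / length
        )
        components[FluxComponent.emission_peat_fire] = np.where(
            drained, area * factors.peat_fire / length, 0.0
        )
    if options.include_flfl_burning and stack.burn_flag is not None:
        burn = stack.burn_flag.ravel() & (cat == int(IpccCategory.FL_FL))
        components[FluxComponent.emission_flfl_burning] = np.where(
            burn, area * factors.flfl_burn_emission / length, 0.0
        )

    # Forest type used for booking gained cells: the regrowing stratum.
    book_ft = np.where(gained, int(ForestType.young_secondary), ft)
    return CellFluxes(category=cat, forest_type=book_ft, biome=biome, components=components)


def aggregate_cell_fluxes(
    stack: GridStack,
    cell: CellFluxes,
    options: AccountingOptions = AccountingOptions(),
    emission_mask: Optional[np.ndarray] = None,
    removal_mask: Optional[np.ndarray] = None,
    provenance: Optional[str] = None,
) -> FluxLedger:
    """Book per-cell fluxes into a region x category x type x component ledger.

    Optional boolean masks restrict which cells contribute to emission and
    removal components (the adjustment pipeline's mechanism).
    """
    n = cell.category.size
    emask = np.ones(n, dtype=bool) if emission_mask is None else emission_mask.ravel()
    rmask = np.ones(n, dtype=bool) if removal_mask is None else removal_mask.ravel()

    frames = []
    n_biomes = int(cell.biome.max()) + 1
    n_cats = max(int(c) for c in IpccCategory) + 1
    n_types = max(int(t) for t in ForestType) + 1
    group = (cell.biome * n_cats + cell.category) * n_types + cell.forest_type
    n_groups = n_biomes * n_cats * n_types
    for comp, values in cell.components.items():
        mask = rmask if comp is FluxComponent.removal else emask
        sums = np.bincount(group, weights=values * mask, minlength=n_groups)
        nz = np.flatnonzero(sums)
        if nz.size == 0:
            continue
        b, rem = np.divmod(nz, n_cats * n_types)
        c, t = np.divmod(rem, n_types)
        frames.append(
            pd.DataFrame(
                {
                    "region": [stack.biome_name(int(x)) for x in b],
                    "category": [IpccCategory(int(x)).name for x in c],
                    "forest_type": [ForestType(int(x)).name for x in t],
                    "component": comp.value,
                    "value_mg_co2e_per_yr": sums[nz],
                }
            )
        )
    if frames:
        table = pd.concat(frames, ignore_index=True)
    else:
        table = pd.DataFrame(
            columns=["region", "category", "forest_type", "component", "value_mg_co2e_per_yr"]
        )
    table["period_start"], table["period_end"] = stack.period
    prov = provenance if provenance is not None else options.provenance
    table["provenance"] = prov
    table = table.sort_values(
        ["region", "category", "forest_type", "component"], kind="mergesort"
    ).reset_index(drop=True)
    return FluxLedger(table=table[LEDGER_COLUMNS], period=stack.period, provenance=prov)


def run_gain_loss(
    stack: GridStack, factors: FactorTable, options: AccountingOptions = AccountingOptions()
) -> FluxLedger:
    """Full landscape accounting: per-cell gain-loss summed into a ledger."""
    cell = compute_cell_fluxes(stack, factors, options)
    return aggregate_cell_fluxes(stack, cell, options)


def example_factor_table(
    biome_names=("Amazonia", "Atlantic Forest", "Cerrado", "Pantanal", "Pampa", "Caatinga"),
    **overrides,
) -> FactorTable:
    """EO-style stratum removal factors for the Brazilian biome vocabulary.

    Central values are the modal per-biome factors of the earth-observation
    stratification (old-growth, old/young secondary, plantations); tree crops
    share the plantation factor. Unknown biome names fall back to the Amazonia
    column so synthetic landscapes with generic biome labels still resolve.
    """
    base = {
        "Amazonia": {"og": 0.59, "osf": 1.36, "ysf": 6.4, "pl": 11.2},
        "Atlantic Forest": {"og": 0.59, "osf": 1.36, "ysf": 4.5, "pl": 12.7},
        "Cerrado": {"og": 0.24, "osf": 1.60, "ysf": 4.3, "pl": 16.6},
        "Pantanal": {"og": 0.24, "osf": 1.60, "ysf": 3.6, "pl": 20.2},
        "Pampa": {"og": 0.59, "osf": 0.59, "ysf": 2.8, "pl": 12.9},
        "Caatinga": {"og": 0.95, "osf": 1.60, "ysf": 4.5, "pl": 17.0},
    }
    factors = {}
    for name in biome_names:
        vals = base.get(name, base["Amazonia"])
        factors[(name, ForestType.primary_old_growth)] = RemovalFactor(vals["og"])
        factors[(name, ForestType.old_secondary)] = RemovalFactor(vals["osf"])
        factors[(name, ForestType.young_secondary)] = RemovalFactor(vals["ysf"])
        factors[(name, ForestType.plantation_forest)] = RemovalFactor(vals["pl"])
        factors[(name, ForestType.tree_crop)] = RemovalFactor(vals["pl"])
    return FactorTable(removal_factor=factors, **overrides)
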