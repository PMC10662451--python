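"""Core categorical vocabularies shared across the pipeline.

Forest types follow the earth-observation dataset's stratification of the
tropical landscape; IPCC categories are the land-use transition classes of
the LULUCF reporting frame. Both are small integer enums so they can live in
uint8 raster bands with 255 reserved as the categorical nodata sentinel.
"""

from __future__ import annotations

import enum

#: Categorical raster nodata sentinel (uint8 bands).
NODATA = 255

#: Sentinel in the loss-year band meaning "no loss during the period".
LOSS_NONE = 0

#: Stoichiometric conversion, Mg CO2 per Mg C.
CO2_PER_C = 44.0 / 12.0


class ForestType(enum.IntEnum):
    """Forest strata of the landscape at the start of the accounting period.

    ``old_secondary`` is naturally regenerating forest older than 20 years;
    ``young_secondary`` is regrowth younger than 20 years. ``tree_crop``
    covers perennial plantations (oil palm, rubber, acacia) that national
    inventories book under cropland rather than forest land.
    """

    primary_old_growth = 1
    old_secondary = 2
    young_secondary = 3
    plantation_forest = 4
    tree_crop = 5
    nonforest = 6


#: Forest-land strata (everything a canopy-cover map would call forest).
FOREST_TYPES = (
    ForestType.primary_old_growth,
    ForestType.old_secondary,
    ForestType.young_secondary,
    ForestType.plantation_forest,
    ForestType.tree_crop,
)

#: Strata a national inventory counts as forest land (tree crops are cropland).
INVENTORY_FOREST_TYPES = (
    ForestType.primary_old_growth,
    ForestType.old_secondary,
    ForestType.young_secondary,
    ForestType.plantation_forest,
)


class IpccCategory(enum.IntEnum):
    """IPCC land-use transition category of a cell over the period."""

    FL_FL = 1  # forest land remaining forest land
    FL_OL = 2  # forest land converted to other land (deforestation)
    OL_FL = 3  # other land converted to forest land
    CL_CL = 4  # cropland remaining cropland (tree crops, inventory convention)
    OL_CL = 5  # other land converted to cropland


class FluxComponent(enum.Enum):
    """Ledger flux components; removals are the only negative component."""

    emission_deforestation = "emission_deforestation"
    emission_flfl_burning = "emission_flfl_burning"
    emission_peat_decomposition = "emission_peat_decomposition"
    emission_peat_fire = "emission_peat_fire"
    removal = "removal"


EMISSION_COMPONENTS = (
    FluxComponent.emission_deforestation,
    FluxComponent.emission_flfl_burning,
    FluxComponent.emission_peat_decomposition,
    FluxComponent.emission_peat_fire,
)

#: Default biome labels for synthetic landscapes (Brazilian biome vocabulary).
DEFAULT_BIOME_NAMES = (
    "Amazonia",
    "Atlantic Forest",
    "Cerrado",
    "Pantanal",
    "Pampa",
    "Caatinga",
)
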