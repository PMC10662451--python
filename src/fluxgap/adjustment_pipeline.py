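"""Managed-land adjustment ladder for the earth-observation flux estimate.

National inventories report fluxes on managed land only, while a wall-to-wall
earth-observation product books every cell in the territory. The ladder of
five declarative adjustment configurations narrows the EO accounting domain
step by step toward the inventory's conventions:

``no_adjustment``
    Everything inside the territorial boundary.
``adjustment_1``
    Exclude removals in primary forest (the year-one primary mask as a proxy
    for unmanaged land); keep all emissions country-wide.
``adjustment_2a``
    Restrict both emissions and removals to the inventory's managed land.
``adjustment_2b``
    Emissions on all managed land, removals only in the inventory's managed
    *forest*, and no removals on deforested (FL->OL) cells.
``adjustment_2c``
    As 2b, additionally excluding removals in old secondary forest remaining
    forest, in plantations that saw no loss over the period ("plantations
    remaining plantations"), and in tree crops (cropland in the inventory).

Each spec resolves every (category, forest type, component) the engine can
emit to exactly one include/exclude decision; the complement ledger (the
rows a spec excluded) is a first-class output so that adjusted + complement
reconstructs the unadjusted ledger.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import yaml

from .errors import ConfigurationError
from .gainloss_engine import (
    AccountingOptions,
    FactorTable,
    FluxLedger,
    aggregate_cell_fluxes,
    compute_cell_fluxes,
)
from .synthetic_landscape import GridStack
from .types import LOSS_NONE, ForestType, IpccCategory

__all__ = ["AdjustmentSpec", "builtin_specs", "get_spec", "apply_adjustment"]

BUILTIN_NAMES = (
    "no_adjustment",
    "adjustment_1",
    "adjustment_2a",
    "adjustment_2b",
    "adjustment_2c",
)

_EXTRA_EXCLUSIONS = (
    "old_secondary_flfl_removals",
    "undisturbed_plantation_removals",
    "tree_crop_removals",
)


@dataclass(frozen=True)
class AdjustmentSpec:
    """One declarative include/exclude configuration.

    ``removal_domain`` / ``emission_domain`` name the cell universe each
    component class is restricted to; the extra exclusion flags carve out
    the inventory's net-zero categories on top of that.
    """

    name: str
    removal_domain: str = "all"        # all | nonprimary | managed_land | managed_forest
    emission_domain: str = "all"       # all | managed_land
    exclude_flol_removals: bool = False
    extra_exclusions: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.removal_domain not in ("all", "nonprimary", "managed_land", "managed_forest"):
            raise ConfigurationError(f"unknown removal_domain {self.removal_domain!r}")
        if self.emission_domain not in ("all", "managed_land"):
            raise ConfigurationError(f"unknown emission_domain {self.emission_domain!r}")
        unknown = set(self.extra_exclusions) - set(_EXTRA_EXCLUSIONS)
        if unknown:
            raise ConfigurationError(f"unknown extra exclusions: {sorted(unknown)}")

    @property
    def mask_requirements(self) -> tuple[str, ...]:
        """Boolean stack layers this spec needs."""
        req = []
        if self.removal_domain == "managed_land" or self.emission_domain == "managed_land":
            req.append("managed_land")
        if self.removal_domain == "managed_forest":
            req.extend(["managed_land", "managed_forest"])
        return tuple(dict.fromkeys(req))

    # ------------------------------------------------------------- decisions
    def removal_included(
        self,
        category: IpccCategory,
        forest_type: ForestType,
        *,
        primary: bool = False,
        managed_land: bool = True,
        managed_forest: bool = True,
        lost: bool = False,
    ) -> bool:
        """Single include/exclude decision for one removal cell-context."""
        if self.removal_domain == "nonprimary" and primary:
            return False
        if self.removal_domain == "managed_land" and not managed_land:
            return False
        if self.removal_domain == "managed_forest" and not managed_forest:
            return False
        if self.exclude_flol_removals and category == IpccCategory.FL_OL:
            return False
        ex = self.extra_exclusions
        if (
            "old_secondary_flfl_removals" in ex
            and forest_type == ForestType.old_secondary
            and category == IpccCategory.FL_FL
        ):
            return False
        if (
            "undisturbed_plantation_removals" in ex
            and forest_type == ForestType.plantation_forest
            and not lost
        ):
            return False
        if "tree_crop_removals" in ex and forest_type == ForestType.tree_crop:
            return False
        return True

    def emission_included(self, *, managed_land: bool = True) -> bool:
        return self.emission_domain == "all" or managed_land

    # ----------------------------------------------------------------- masks
    def _require_layers(self, stack: GridStack) -> None:
        for name in self.mask_requirements:
            if getattr(stack, name) is None:
                raise ConfigurationError(
                    f"adjustment {self.name!r} requires stack layer {name!r}"
                )

    def emission_mask(self, stack: GridStack) -> np.ndarray:
        self._require_layers(stack)
        if self.emission_domain == "managed_land":
            return stack.managed_land.ravel().copy()
        return np.ones(stack.n_cells, dtype=bool)

    def removal_mask(self, stack: GridStack, category: np.ndarray) -> np.ndarray:
        self._require_layers(stack)
        ft = stack.forest_type_t0.ravel()
        lost = stack.loss_year.ravel() != LOSS_NONE
        mask = np.ones(stack.n_cells, dtype=bool)
        if self.removal_domain == "nonprimary":
            mask &= ft != int(ForestType.primary_old_growth)
        elif self.removal_domain == "managed_land":
            mask &= stack.managed_land.ravel()
        elif self.removal_domain == "managed_forest":
            mask &= stack.managed_forest.ravel()
        if self.exclude_flol_removals:
            mask &= category != int(IpccCategory.FL_OL)
        ex = self.extra_exclusions
        if "old_secondary_flfl_removals" in ex:
            mask &= ~(
                (ft == int(ForestType.old_secondary))
                & (category == int(IpccCategory.FL_FL))
            )
        if "undisturbed_plantation_removals" in ex:
            mask &= ~((ft == int(ForestType.plantation_forest)) & ~lost)
        if "tree_crop_removals" in ex:
            mask &= ft != int(ForestType.tree_crop)
        return mask

    # ------------------------------------------------------------------- I/O
    def to_yaml(self, path=None) -> str:
        payload = {
            "name": self.name,
            "removal_domain": self.removal_domain,
            "emission_domain": self.emission_domain,
            "exclude_flol_removals": self.exclude_flol_removals,
            "extra_exclusions": sorted(self.extra_exclusions),
        }
        text = yaml.safe_dump(payload, sort_keys=False)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "AdjustmentSpec":
        if hasattr(source, "read"):
            payload = yaml.safe_load(source.read())
        else:
            try:
                with open(source, "r", encoding="utf-8") as fh:
                    payload = yaml.safe_load(fh)
            except (OSError, ValueError):
                payload = yaml.safe_load(source)
        payload["extra_exclusions"] = frozenset(payload.get("extra_exclusions", ()))
        return cls(**payload)


def builtin_specs() -> list[AdjustmentSpec]:
    """The five adjustment configurations, in ladder order."""
    return [
        AdjustmentSpec(name="no_adjustment"),
        AdjustmentSpec(name="adjustment_1", removal_domain="nonprimary"),
        AdjustmentSpec(
            name="adjustment_2a",
            removal_domain="managed_land",
            emission_domain="managed_land",
        ),
        AdjustmentSpec(
            name="adjustment_2b",
            removal_domain="managed_forest",
            emission_domain="managed_land",
            exclude_flol_removals=True,
        ),
        AdjustmentSpec(
            name="adjustment_2c",
            removal_domain="managed_forest",
            emission_domain="managed_land",
            exclude_flol_removals=True,
            extra_exclusions=frozenset(_EXTRA_EXCLUSIONS),
        ),
    ]


def get_spec(name: str) -> AdjustmentSpec:
    for spec in builtin_specs():
        if spec.name == name:
            return spec
    raise ConfigurationError(
        f"unknown adjustment spec {name!r}; builtin specs: {', '.join(BUILTIN_NAMES)}"
    )


def apply_adjustment(
    stack: GridStack,
    factors: FactorTable,
    spec: AdjustmentSpec,
    options: AccountingOptions = AccountingOptions(),
    return_complement: bool = False,
) -> FluxLedger | tuple[FluxLedger, FluxLedger]:
    """Run the engine under one adjustment spec.

    With ``return_complement=True`` also returns the ledger of everything the
    spec excluded; summing the two row-wise reconstructs the unadjusted ledger.
    """
    cell = compute_cell_fluxes(stack, factors, options)
    emask = spec.emission_mask(stack)
    rmask = spec.removal_mask(stack, cell.category)
    ledger = aggregate_cell_fluxes(
        stack, cell, options, emission_mask=emask, removal_mask=rmask, provenance=spec.name
    )
    if not return_complement:
        return ledger
    complement = aggregate_cell_fluxes(
        stack,
        cell,
        options,
        emission_mask=~emask,
        removal_mask=~rmask,
        provenance=f"{spec.name}_complement",
    )
    return ledger, complement
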