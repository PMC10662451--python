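"""Seeded synthetic tropical landscapes for the flux-accounting pipeline.

Real national-scale inputs (wall-to-wall biomass, loss-year and managed-land
rasters) are not redistributable, so the pipeline is exercised on generated
landscapes that reproduce their *structure*: spatially coherent forest-type
patches, a contiguous unmanaged primary block, skewed per-stratum carbon
densities, stochastic annual forest loss over a 20-year period, and a second
inventory-style classification layer with configurable confusion against the
first.

All randomness flows from one integer seed through
:class:`numpy.random.SeedSequence`, with one deterministically spawned
sub-stream per layer, so identical configs yield bit-identical stacks.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, DataError
from .types import (
    DEFAULT_BIOME_NAMES,
    INVENTORY_FOREST_TYPES,
    LOSS_NONE,
    NODATA,
    ForestType,
)

__all__ = [
    "AgcSpec",
    "LandscapeConfig",
    "GridStack",
    "generate_landscape",
    "CONFUSION_TARGET",
]

#: Where a confused cell is relabelled to in the second classification layer.
#: The dominant disagreement mode mirrors inventories classing old secondary
#: regrowth as managed old-growth forest; all targets differ from the source.
CONFUSION_TARGET: Mapping[ForestType, ForestType] = {
    ForestType.primary_old_growth: ForestType.old_secondary,
    ForestType.old_secondary: ForestType.primary_old_growth,
    ForestType.young_secondary: ForestType.old_secondary,
    ForestType.plantation_forest: ForestType.tree_crop,
    ForestType.tree_crop: ForestType.plantation_forest,
    ForestType.nonforest: ForestType.young_secondary,
}


@dataclass(frozen=True)
class AgcSpec:
    """Aboveground-carbon distribution for one stratum.

    family
        ``"lognormal"`` (location = median Mg C/ha, scale = sigma of log) or
        ``"constant"`` (location only).
    """

    family: str
    location: float
    scale: float = 0.0

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "constant":
            return np.full(n, self.location, dtype=np.float64)
        if self.family == "lognormal":
            return rng.lognormal(mean=np.log(self.location), sigma=self.scale, size=n)
        raise ConfigurationError(f"unknown AGC distribution family: {self.family!r}")


def _default_proportions() -> dict[ForestType, float]:
    return {
        ForestType.primary_old_growth: 0.35,
        ForestType.old_secondary: 0.15,
        ForestType.young_secondary: 0.08,
        ForestType.plantation_forest: 0.05,
        ForestType.tree_crop: 0.05,
        ForestType.nonforest: 0.32,
    }


def _default_agc() -> dict[ForestType, AgcSpec]:
    # Skewed (lognormal) densities: primary highest median, regrowth lowest.
    return {
        ForestType.primary_old_growth: AgcSpec("lognormal", 150.0, 0.30),
        ForestType.old_secondary: AgcSpec("lognormal", 90.0, 0.35),
        ForestType.young_secondary: AgcSpec("lognormal", 25.0, 0.50),
        ForestType.plantation_forest: AgcSpec("lognormal", 60.0, 0.40),
        ForestType.tree_crop: AgcSpec("lognormal", 40.0, 0.40),
        ForestType.nonforest: AgcSpec("constant", 0.0),
    }


def _default_loss_prob() -> dict[ForestType, float]:
    return {
        ForestType.primary_old_growth: 0.004,
        ForestType.old_secondary: 0.008,
        ForestType.young_secondary: 0.012,
        ForestType.plantation_forest: 0.030,
        ForestType.tree_crop: 0.020,
        ForestType.nonforest: 0.0,
    }


def _default_confusion() -> dict[ForestType, float]:
    # Old secondary is the dominant disagreement stratum between the
    # EO-style and inventory-style classifications.
    return {
        ForestType.primary_old_growth: 0.05,
        ForestType.old_secondary: 0.65,
        ForestType.young_secondary: 0.10,
        ForestType.plantation_forest: 0.08,
        ForestType.tree_crop: 0.08,
        ForestType.nonforest: 0.05,
    }


@dataclass(frozen=True)
class LandscapeConfig:
    """Full parameterisation of one synthetic landscape.

    ``cell_area`` is hectares per cell (default 0.09 ha, a 30 m pixel).
    ``patch_density`` is expected patch seeds per cell and controls the
    spatial autocorrelation scale of the class mosaic.
    """

    grid_height: int = 160
    grid_width: int = 160
    cell_area: float = 0.09
    period_start: int = 2001
    period_end: int = 2020
    class_proportions: Mapping[ForestType, float] = field(default_factory=_default_proportions)
    agc_distributions: Mapping[ForestType, AgcSpec] = field(default_factory=_default_agc)
    annual_loss_prob: Mapping[ForestType, float] = field(default_factory=_default_loss_prob)
    nonforest_gain_prob: float = 0.05
    unmanaged_block_fraction: float = 0.5
    confusion_rates: Mapping[ForestType, float] = field(default_factory=_default_confusion)
    peat_fraction: float = 0.0
    biome_count: int = 3
    patch_density: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if self.grid_height <= 0 or self.grid_width <= 0:
            raise ConfigurationError("grid dimensions must be positive")
        if self.cell_area <= 0:
            raise ConfigurationError("cell_area must be positive")
        if self.period_end <= self.period_start:
            raise ConfigurationError("period_end must exceed period_start")
        total = sum(self.class_proportions.get(ft, 0.0) for ft in ForestType)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"class_proportions sum to {total}, expected 1")
        for name, mapping in (
            ("class_proportions", self.class_proportions),
            ("annual_loss_prob", self.annual_loss_prob),
            ("confusion_rates", self.confusion_rates),
        ):
            for ft, p in mapping.items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigurationError(f"{name}[{ft.name}] = {p} outside [0, 1]")
        for p, name in (
            (self.nonforest_gain_prob, "nonforest_gain_prob"),
            (self.unmanaged_block_fraction, "unmanaged_block_fraction"),
            (self.peat_fraction, "peat_fraction"),
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} = {p} outside [0, 1]")
        if self.biome_count < 1:
            raise ConfigurationError("biome_count must be >= 1")
        if not 0.0 < self.patch_density <= 1.0:
            raise ConfigurationError("patch_density must be in (0, 1]")

    def with_seed(self, seed: int) -> "LandscapeConfig":
        return replace(self, seed=seed)


@dataclass
class GridStack:
    """Aligned raster layers describing one landscape snapshot plus change.

    Grid convention: row-major, origin top-left, 0-based indices; categorical
    nodata is 255 and the loss-year sentinel (no loss) is 0.
    """

    forest_type_t0: np.ndarray  # uint8, ForestType codes
    agc_t0: np.ndarray          # float32, Mg C/ha
    loss_year: np.ndarray       # int16, calendar year or LOSS_NONE
    gain_flag: np.ndarray       # bool
    alt_class: np.ndarray       # uint8, second (inventory-style) classification
    biome: np.ndarray           # uint8 biome codes
    peat: np.ndarray            # bool
    cell_area: float            # hectares per cell
    period: tuple[int, int]
    managed_land: Optional[np.ndarray] = None   # bool
    managed_forest: Optional[np.ndarray] = None  # bool
    burn_flag: Optional[np.ndarray] = None       # bool, optional FL-FL burn events
    biome_names: tuple[str, ...] = ()

    @property
    def shape(self) -> tuple[int, int]:
        return self.forest_type_t0.shape

    @property
    def n_cells(self) -> int:
        return int(self.forest_type_t0.size)

    @property
    def period_length(self) -> int:
        return self.period[1] - self.period[0] + 1

    def _layers(self):
        named = [
            ("forest_type_t0", self.forest_type_t0),
            ("agc_t0", self.agc_t0),
            ("loss_year", self.loss_year),
            ("gain_flag", self.gain_flag),
            ("alt_class", self.alt_class),
            ("biome", self.biome),
            ("peat", self.peat),
        ]
        for name in ("managed_land", "managed_forest", "burn_flag"):
            layer = getattr(self, name)
            if layer is not None:
                named.append((name, layer))
        return named

    def validate(self) -> None:
        shape = self.forest_type_t0.shape
        for name, layer in self._layers():
            if layer.shape != shape:
                raise DataError(f"layer {name} shape {layer.shape} != {shape}")
        start, end = self.period
        if end <= start:
            raise DataError("period end must exceed period start")
        if self.cell_area <= 0:
            raise DataError("cell_area must be positive")
        codes = np.unique(self.forest_type_t0)
        valid = {int(ft) for ft in ForestType} | {NODATA}
        if not set(codes.tolist()) <= valid:
            raise DataError(f"unknown forest type codes: {set(codes.tolist()) - valid}")
        lossy = self.loss_year != LOSS_NONE
        if np.any(lossy & (self.forest_type_t0 == ForestType.nonforest)):
            raise DataError("loss events assigned to nonforest cells")
        if np.any(lossy & ((self.loss_year < start + 1) | (self.loss_year > end))):
            raise DataError("loss_year outside (period_start, period_end]")
        if np.any(self.agc_t0 < 0):
            raise DataError("negative AGC")
        if np.any((self.forest_type_t0 == ForestType.nonforest) & (self.agc_t0 != 0)):
            raise DataError("nonforest cells must have zero AGC")
        if np.any(self.gain_flag & (self.forest_type_t0 != ForestType.nonforest)):
            raise DataError("gain_flag set on a cell that was forest at t0")
        if self.managed_forest is not None:
            if self.managed_land is None:
                raise DataError("managed_forest requires managed_land")
            if np.any(self.managed_forest & ~self.managed_land):
                raise DataError("managed_forest must imply managed_land")

    def biome_name(self, code: int) -> str:
        if self.biome_names and code < len(self.biome_names):
            return self.biome_names[code]
        return f"biome_{code}"


def _contiguous_fill(start: int, allowed: np.ndarray, target: int, shape) -> np.ndarray:
    """Breadth-first flood over 4-connected ``allowed`` cells up to ``target`` cells."""
    h, w = shape
    selected = np.zeros(allowed.size, dtype=bool)
    if target <= 0 or not allowed[start]:
        return selected
    queue = deque([start])
    selected[start] = True
    count = 1
    while queue and count < target:
        idx = queue.popleft()
        r, c = divmod(idx, w)
        for nr, nc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if 0 <= nr < h and 0 <= nc < w:
                nidx = nr * w + nc
                if allowed[nidx] and not selected[nidx]:
                    selected[nidx] = True
                    queue.append(nidx)
                    count += 1
                    if count >= target:
                        break
    return selected


def _cell_quotas(cfg: LandscapeConfig, n: int) -> dict[ForestType, int]:
    """Largest-remainder apportionment of the grid among the classes."""
    raw = {ft: cfg.class_proportions.get(ft, 0.0) * n for ft in ForestType}
    quotas = {ft: int(np.floor(v)) for ft, v in raw.items()}
    shortfall = n - sum(quotas.values())
    by_remainder = sorted(raw, key=lambda ft: (raw[ft] - quotas[ft], -int(ft)), reverse=True)
    for ft in by_remainder[:shortfall]:
        quotas[ft] += 1
    return quotas


def _assign_classes(cfg: LandscapeConfig, rng: np.random.Generator) -> np.ndarray:
    """Multi-source region growth with exact per-class cell quotas.

    Each class grows breadth-first from seeded cells until its quota is
    filled, yielding spatially coherent patches whose realized fractions
    equal the configured proportions to the cell. Primary old-growth grows
    from a single seed so it forms one massif (the contiguous block the
    managed-land masking assumes); if a class's frontier is walled in before
    its quota is met it restarts from a fresh unclaimed cell.
    """
    h, w = cfg.grid_height, cfg.grid_width
    n = h * w
    quotas = _cell_quotas(cfg, n)
    claimed = np.full(n, -1, dtype=np.int16)

    def neighbors(idx: int):
        r, c = divmod(idx, w)
        if r > 0:
            yield idx - w
        if r < h - 1:
            yield idx + w
        if c > 0:
            yield idx - 1
        if c < w - 1:
            yield idx + 1

    frontiers: dict[ForestType, deque] = {}
    remaining: dict[ForestType, int] = {}
    seed_counts = {}
    for ft in ForestType:
        q = quotas[ft]
        if q <= 0:
            continue
        if ft == ForestType.primary_old_growth:
            seed_counts[ft] = 1
        else:
            seed_counts[ft] = max(1, int(round(cfg.patch_density * q)))
    all_seeds = rng.choice(n, size=sum(seed_counts.values()), replace=False)
    pos = 0
    for ft, k in seed_counts.items():
        cells = all_seeds[pos : pos + k]
        pos += k
        taken = [int(c) for c in cells if claimed[c] < 0][: quotas[ft]]
        for c in taken:
            claimed[c] = int(ft)
        frontiers[ft] = deque(taken)
        remaining[ft] = quotas[ft] - len(taken)

    active = [ft for ft in frontiers if remaining[ft] > 0]
    unclaimed_probe = 0
    while active:
        for ft in list(active):
            if remaining[ft] <= 0:
                active.remove(ft)
                continue
            frontier = frontiers[ft]
            grew = False
            while frontier and not grew:
                idx = frontier[0]
                free = [nb for nb in neighbors(idx) if claimed[nb] < 0]
                if not free:
                    frontier.popleft()
                    continue
                nb = free[rng.integers(len(free))] if len(free) > 1 else free[0]
                claimed[nb] = int(ft)
                frontier.append(nb)
                remaining[ft] -= 1
                grew = True
            if not grew:
                # Walled in: restart from the next unclaimed cell.
                while claimed[unclaimed_probe] >= 0:
                    unclaimed_probe += 1
                claimed[unclaimed_probe] = int(ft)
                frontier.append(unclaimed_probe)
                remaining[ft] -= 1
    return claimed.astype(np.uint8)


def generate_landscape(config: LandscapeConfig) -> GridStack:
    """Generate one seeded synthetic landscape satisfying the stack contract."""
    config.validate()
    h, w = config.grid_height, config.grid_width
    n = h * w
    ss = np.random.SeedSequence(config.seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("patches", "classes", "agc", "loss", "gain", "confusion", "peat", "block"),
            ss.spawn(8),
        )
    }

    forest_type = _assign_classes(config, streams["classes"])

    agc = np.zeros(n, dtype=np.float64)
    for ft in ForestType:
        mask = forest_type == int(ft)
        cnt = int(mask.sum())
        if cnt:
            spec = config.agc_distributions.get(ft, AgcSpec("constant", 0.0))
            agc[mask] = spec.sample(streams["agc"], cnt)
    agc[forest_type == int(ForestType.nonforest)] = 0.0
    agc = np.maximum(agc, 0.0).astype(np.float32)

    start, end = config.period_start, config.period_end
    years = end - start
    loss_year = np.full(n, LOSS_NONE, dtype=np.int16)
    rng_loss = streams["loss"]
    for ft in ForestType:
        if ft == ForestType.nonforest:
            continue  # nonforest never loses forest
        p = config.annual_loss_prob.get(ft, 0.0)
        mask = forest_type == int(ft)
        cnt = int(mask.sum())
        if cnt and p > 0:
            wait = rng_loss.geometric(p, size=cnt)  # first-loss year offset, >= 1
            ly = np.where(wait <= years, start + wait, LOSS_NONE)
            loss_year[mask] = ly.astype(np.int16)

    gain_flag = np.zeros(n, dtype=bool)
    nf = forest_type == int(ForestType.nonforest)
    gain_flag[nf] = streams["gain"].random(int(nf.sum())) < config.nonforest_gain_prob

    alt_class = forest_type.copy()
    rng_conf = streams["confusion"]
    for ft in ForestType:
        rate = config.confusion_rates.get(ft, 0.0)
        mask = forest_type == int(ft)
        cnt = int(mask.sum())
        if cnt and rate > 0:
            fire = rng_conf.random(cnt) < rate
            target = np.where(fire, int(CONFUSION_TARGET[ft]), int(ft))
            alt_class[mask] = target.astype(np.uint8)

    # Contiguous unmanaged block inside the primary blob.
    primary = forest_type == int(ForestType.primary_old_growth)
    managed_land = np.ones(n, dtype=bool)
    n_primary = int(primary.sum())
    target = int(round(config.unmanaged_block_fraction * n_primary))
    if target > 0 and n_primary > 0:
        # Start inside the largest connected primary component so the block
        # can actually reach its target size.
        labels, n_comp = ndimage.label(primary.reshape(h, w))
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        candidates = np.flatnonzero(labels.ravel() == int(np.argmax(sizes)))
        seed_cell = int(candidates[streams["block"].integers(len(candidates))])
        block = _contiguous_fill(seed_cell, primary, target, (h, w))
        managed_land = ~block

    inventory_forest = np.isin(alt_class, [int(ft) for ft in INVENTORY_FOREST_TYPES])
    managed_forest = managed_land & inventory_forest

    peat = np.zeros(n, dtype=bool)
    peat_target = int(round(config.peat_fraction * n))
    if peat_target > 0:
        seed_cell = int(streams["peat"].integers(n))
        peat = _contiguous_fill(seed_cell, np.ones(n, dtype=bool), peat_target, (h, w))

    rows = np.repeat(np.arange(h), w)
    biome = (rows * config.biome_count // h).astype(np.uint8)
    names = tuple(DEFAULT_BIOME_NAMES[: config.biome_count])
    if config.biome_count > len(DEFAULT_BIOME_NAMES):
        names = names + tuple(
            f"biome_{i}" for i in range(len(DEFAULT_BIOME_NAMES), config.biome_count)
        )

    stack = GridStack(
        forest_type_t0=forest_type.reshape(h, w),
        agc_t0=agc.reshape(h, w),
        loss_year=loss_year.reshape(h, w),
        gain_flag=gain_flag.reshape(h, w),
        alt_class=alt_class.reshape(h, w),
        biome=biome.reshape(h, w),
        peat=peat.reshape(h, w),
        cell_area=config.cell_area,
        period=(start, end),
        managed_land=managed_land.reshape(h, w),
        managed_forest=managed_forest.reshape(h, w),
        biome_names=names,
    )
    stack.validate()
    return stack
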