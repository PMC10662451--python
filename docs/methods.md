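# Methods

This note documents the accounting model, the synthetic-landscape
generator, the adjustment semantics, and the numerical and design choices
behind `fluxgap`.

## Accounting model

The engine applies the IPCC gain–loss frame to each grid cell over one
accounting period `(start, end)`, years inclusive, of length
`L = end − start + 1` (the defaults span 2001–2020, L = 20). Each cell
carries a forest type at the period start, an aboveground carbon density
(AGC, Mg C ha⁻¹), an optional loss year, an optional gain flag (for cells
that were other land at the start and gained forest), a biome code, and
boolean managed-land / managed-forest / peat layers.

**Transition category.** Forest at the start with a loss event maps to
FL→OL (deforestation), forest without loss to FL→FL, other land with gain
to OL→FL. Under the inventory convention (`treat_tree_crops_as_cropland`),
tree crops map to CL→CL / OL→CL instead, because national inventories in
all three study countries class perennial tree crops (oil palm, rubber,
acacia) as agricultural cropland. A loss year on a nonforest cell is a
data error.

**Committed emissions.** A loss event books the cell's full stock at the
loss year, expanded from AGC to the other biomass pools:

    E = A · [AGC · (1 + R + D + Λ) + S·1{soil}] · 44/12        (Mg CO₂)

with cell area `A` (ha), root:shoot ratio `R` (default 0.25), deadwood
and litter fractions of AGC `D = 0.10`, `Λ = 0.04`, and an optional
committed soil term `S` (Mg C ha⁻¹, default 0). Ledger values are
average-annual: committed emissions are divided by `L`.

**Removals.** Forested cell-years accrue removals at the stratum removal
factor `RF(biome, type)` in Mg C ha⁻¹ yr⁻¹:

    F = −A · RF · 44/12 · (years forested / L)                 (Mg CO₂ yr⁻¹)

A cell lost in year `y` accrues `y − start` years — removals run up to,
exclusive of, the loss year. Whether lost cells accrue at all is
configurable (`removals_on_lost_cells`, default on): the EO-internal
convention for pre-loss accrual is not externally documented, so both
behaviours are supported and tested. Cells gaining forest accrue the full
period at the young-secondary factor; the stack carries no gain-year
layer, so a partial-period gain accrual is out of scope (a conservative
overstatement of gain removals, stated here rather than hidden).

**Peat and FL→FL burning.** On peat-flagged cells with loss, drained-peat
decomposition accrues at a CO₂e rate from the loss year through the period
end, plus a per-event peat-fire term; both default off and are switched on
for peatland-country (Indonesia/Malaysia-style) runs. FL→FL biomass
burning is a named component with a per-event CO₂e/ha factor applied to
burn-flagged FL→FL cells; the component exists in the reporting vocabulary
but no formula for it is published, so the factor defaults to 0 and the
burn layer is optional.

**Ledger.** Fluxes are aggregated by region (biome) × IPCC category ×
forest type × component with `numpy` pairwise summation; biome rows sum to
the country ledger to double precision, removal rows are ≤ 0, emission
rows ≥ 0, and net flux is the algebraic sum. The vectorized engine is
tested against an independent per-cell loop built from the scalar
primitives (relative tolerance 1e-9; observed agreement is exact).

## Adjustment ladder

The five built-in configurations mirror the sequence used to reconcile an
EO estimate with an inventory that applies the managed-land proxy:

| name | emissions | removals |
|---|---|---|
| `no_adjustment` | territory | territory |
| `adjustment_1` | territory | outside the primary-forest proxy |
| `adjustment_2a` | managed land | managed land |
| `adjustment_2b` | managed land | managed forest, excluding FL→OL |
| `adjustment_2c` | managed land | 2b minus old-secondary FL→FL, undisturbed plantations, tree crops |

"Plantations remaining plantations" is operationalized as plantation
cells with no loss during the period. The primary mask for adjustment 1
is the period-start primary/old-growth layer. Tree-crop removal exclusion
under 2c keys on the forest-type code regardless of the cropland
convention flag, since tree crops are cropland to the inventories either
way. One published tick/cross row is ambiguous (non-managed old-growth
emissions under 2b, where the emission mark is absent); this
implementation excludes them, consistent with the managed-land emission
mask shared by 2a and 2b. Because each step's removal cell-set is a
subset of the previous step's, gross-removal magnitude is non-increasing
along no adjustment → 2a → 2b → 2c (adjustment 1 is a branch compared
only to no adjustment). Every `apply_adjustment` call can return the
complement ledger; adjusted + complement reconstructs the unadjusted
ledger, making "excluded" auditable rather than silent.

## Synthetic landscapes

The generator emulates the *structure* of the real inputs, not their
geography or radiometry.

- **Class mosaic.** Forest types are grown breadth-first from seeded
  cells with exact per-class cell quotas (largest-remainder
  apportionment), so realized fractions equal the configured proportions
  to the cell while patches stay spatially coherent. Patch scale is set
  by `patch_density` (expected seeds per cell, default 0.01); published
  sources do not characterize the spatial autocorrelation of
  classification disagreement, so this is a free, exposed parameter.
  Primary old-growth grows from a single seed and forms one massif,
  which is what makes a contiguous unmanaged block and meaningful mask
  overlaps possible.
- **AGC.** Lognormal per stratum (primary median 150 Mg C ha⁻¹ at the
  default, regrowth lowest, plantations intermediate; nonforest 0),
  reflecting the right-skewed AGC distributions of remote-sensing biomass
  maps. Fully user-configurable per stratum.
- **Loss.** Per-cell geometric waiting time with a per-class annual
  probability (defaults 0.4–3 %/yr); the first success inside the period
  sets the loss year, in `[start+1, end]`. Nonforest never loses.
- **Gains.** Nonforest cells gain forest with period probability
  `nonforest_gain_prob` (default 5 %); gains are what populate OL→FL.
- **Second classification.** `alt_class` relabels each cell with a
  per-class confusion probability toward a fixed, documented target map;
  the default 65 % old-secondary → old-growth rate reproduces the
  dominant disagreement mode between EO and inventory classifications.
  `managed_forest` is managed land whose *inventory-style* class is
  forest (tree crops excluded), so the two masks partially disagree by
  construction.
- **Peat, biomes.** A contiguous flood-filled peat region of configurable
  fraction; biomes are horizontal bands named with the Brazilian biome
  vocabulary.
- **Randomness.** One integer seed feeds a `SeedSequence`; eight spawned
  sub-streams (classes, AGC, loss, gain, confusion, peat, block, spare)
  keep layers independently reproducible. Identical configs give
  bit-identical stacks.

What passing tests on these landscapes show: the accounting, masking,
harmonization and comparison operations are correct on inputs with the
assumed structure. What they do not show: anything about real Landsat
classification error, real biome geometries, or the accuracy of any
particular published flux number.

## Harmonization

`fractional_rescale(x, ref, short, target) = x · mean(ref over target) /
mean(ref over short)`, arithmetic means over calendar years inclusive of
both endpoints. It is applied separately per gross component and per
region; net flux is recomputed afterwards, never rescaled directly. The
operation is linear in `x`, the same-period case is the identity, and
rescaling composes exactly (A→B then B→C equals A→C).
`extend_last_year` repeats the final value and is idempotent.

## Comparison statistics and fixtures

- `pct_difference` rounds half away from zero; this is forced by the
  printed tables (one young-secondary cell prints −13 from an exact
  −12.5 %). Report precisions follow the printed ones: old-growth and
  young-secondary gaps to integers, plantation gaps to one decimal,
  ratios to two decimals.
- `modal_factor` returns the most frequent value in a stratum, ties to
  the smallest member; the result is always an element of the stratum.
- Quantiles use linear interpolation between order statistics (numpy
  default, "type 7"); no source states a convention.
- `overlap_percent(a, b)` normalizes by the *second* mask; callers choose
  the orientation ("non-primary forest overlaps X % of managed forest").
- The packaged CSVs under `fluxgap/data/` transcribe the published
  per-biome removal-factor tables, the Brazil area/removals-by-type
  table, the Indonesia/Malaysia land-area table and the South-East Asia
  factor table. Two printed artefacts are deliberately not asserted: the
  Brazil third-dataset column total (−0.48 printed vs −0.473 from its own
  components) and the Malaysia country total (27,573.2 printed vs
  27,573.05 from its rows) — both upstream rounding. One transcription
  repair: the Malaysian old-growth area is fixed to 12,483.4 kha from its
  printed subtotal. The "28 %/10 %" remaining-gap percentages published
  alongside 0.81/0.72/0.58 are not reproducible from the printed
  (rounded) values and are not asserted anywhere.

## Problem sizes and defaults

Default grids are 160×160 cells of 0.09 ha (a 30 m pixel) over 2001–2020;
engine-vs-oracle checks run at 16–32², ladder properties over twenty
48×48 stacks, and statistical recovery checks at n = 10⁴ — sizes at which
every property is sharp while the whole suite runs in seconds. Raster I/O
uses single-band TIFF per layer with a YAML sidecar (grid geometry, code
tables, config echo); categorical nodata is 255 and the loss-year
sentinel is 0.

## Known limitations

- Sub-pixel degradation is not modeled; loss is binary and
  stand-replacing.
- No uncertainty propagation or statistical overlap testing between flux
  datasets — with component uncertainties of tens of percent such tests
  are uninformative, and they are deliberately out of scope.
- The managed-forest mask is a single snapshot; no temporal mask
  dynamics.
- Gain cells accrue removals over the whole period (no gain-year layer).
- The generator's confusion model relabels toward a single target class
  per source class; real confusion matrices are denser.
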