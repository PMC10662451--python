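# fluxgap

Tools for reconciling forest carbon flux estimates derived from
earth-observation (EO) data with the fluxes countries report in their
National Greenhouse Gas Inventories (NGHGIs).

Wall-to-wall EO flux products book CO₂ emissions and removals for every
forest pixel in a territory. Inventories report fluxes only on *managed*
land, exclude categories they treat as carbon-neutral ("secondary forest
remaining secondary forest", "plantations remaining plantations", tree
crops booked as cropland), use different removal factors per forest
stratum, and often cover a different span of years. The two estimates can
therefore disagree in both magnitude and sign while neither is wrong: the
gap is definitional. `fluxgap` makes each of those definitional steps an
explicit, testable operation:

- **`synthetic_landscape`** — seeded generator of tropical-country
  landscapes: spatially coherent forest-type patches, skewed per-stratum
  aboveground carbon (AGC) densities, stochastic annual forest loss over a
  20-year period, a contiguous unmanaged primary block, and a second
  inventory-style classification layer with configurable confusion against
  the first.
- **`gainloss_engine`** — IPCC gain–loss accounting per grid cell. A loss
  event books a committed emission of the full stock,
  `E = A · [AGC · (1 + R + D + L) + S] · 44/12`, with root:shoot ratio `R`,
  deadwood and litter fractions `D`, `L`, optional soil term `S`, area `A`
  in ha; forested cell-years accrue removals `−A · RF · 44/12` at the
  stratum removal factor `RF` (Mg C ha⁻¹ yr⁻¹). Results are average-annual
  ledgers disaggregated by region × IPCC category × forest type ×
  component.
- **`adjustment_pipeline`** — five declarative inclusion configurations
  (`no_adjustment`, `adjustment_1`, `adjustment_2a/2b/2c`) that narrow the
  EO accounting domain toward the inventory's conventions, with complement
  ledgers so nothing is silently dropped.
- **`harmonization`** — fractional rescaling of short-period averages
  against a reference annual series and last-year series extension.
- **`comparison_reports`** — modal removal factors, rounded percentage
  differences, forest-type cross-tabulations, mask overlap fractions, area
  tables, swamp:dry ratios, AGC distribution summaries, and packaged
  fixtures transcribing published per-biome factor and country area tables.
- **`io_cli`** — GeoTIFF layer I/O, CSV ledgers/series, YAML configs, and
  the `fluxgap` command line.

## Worked example

```python
import fluxgap as fg

stack = fg.generate_landscape(fg.LandscapeConfig(seed=42))   # 160x160 cells, 2001-2020
factors = fg.example_factor_table(stack.biome_names)
for spec in fg.builtin_specs():
    ledger = fg.apply_adjustment(stack, factors, spec)
    print(f"{spec.name:15s} emissions {ledger.gross_emissions():10.1f}  "
          f"removals {ledger.gross_removals():10.1f}  net {ledger.net():10.1f}")
```

prints (Mg CO₂e yr⁻¹, average-annual over 2001–2020):

```
no_adjustment   emissions     5034.9  removals   -16463.5  net   -11428.6
adjustment_1    emissions     5034.9  removals   -14937.0  net    -9902.1
adjustment_2a   emissions     3815.6  removals   -15727.5  net   -11912.0
adjustment_2b   emissions     3815.6  removals    -8518.4  net    -4702.8
adjustment_2c   emissions     3815.6  removals    -3617.0  net      198.6
```

Unadjusted, the landscape is a large net sink because every forest cell
accrues removals. Masking removals outside the primary-forest proxy
(adjustment 1) or restricting both components to managed land (2a) trims
the sink; restricting removals to managed *forest* and dropping removals
on deforested cells (2b) halves it; and excluding the inventory's
net-zero categories (2c) flips the landscape to a small net source — the
same qualitative ladder a country-scale reconciliation exhibits. Removal
magnitudes are non-increasing along no adjustment → 2a → 2b → 2c by
construction, and each adjusted ledger plus its complement reconstructs
the unadjusted ledger exactly.

The same stages run from the shell:

```sh
fluxgap simulate --seed 42 --out stack/
fluxgap account --stack stack/ --out ledger.csv
fluxgap adjust --stack stack/ --spec adjustment_2c --out adjusted.csv
fluxgap harmonize --series seeg.csv --short 2002:2016 --target 2001:2020 --value -0.45
fluxgap compare factors
```

`fluxgap compare factors` recomputes the per-biome removal-factor
percentage gaps from the packaged tables — e.g. old-growth +23 % in
Amazonia and +850 % in Caatinga (EO relative to inventory), plantation
−10.4 % and young secondary +106 % in Amazonia.

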