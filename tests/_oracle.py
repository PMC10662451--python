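"""Naive per-cell reference implementations used only as test oracles.

Everything here iterates cell by cell with the scalar primitives (or plain
arithmetic) and must stay independent of the vectorized engine paths it
checks.
"""

from collections import defaultdict

from fluxgap import (
    AccountingOptions,
    ForestType,
    classify_transition,
    committed_emission,
    removal_flux,
)
from fluxgap.types import LOSS_NONE


def ledger_oracle(stack, factors, options=AccountingOptions()):
    """Brute-force ledger: dict (region, category, type, component) -> value."""
    start, end = stack.period
    length = end - start + 1
    area = stack.cell_area
    rows = defaultdict(float)
    ft_layer = stack.forest_type_t0.ravel()
    loss = stack.loss_year.ravel()
    gain = stack.gain_flag.ravel()
    agc = stack.agc_t0.ravel()
    biome = stack.biome.ravel()
    peat = stack.peat.ravel()
    for i in range(stack.n_cells):
        ft = ForestType(int(ft_layer[i]))
        ly = int(loss[i])
        region = stack.biome_name(int(biome[i]))
        cat = classify_transition(ft, ly, bool(gain[i]), options.treat_tree_crops_as_cropland)
        lost = ly != LOSS_NONE
        if lost:
            emitted = committed_emission(
                float(agc[i]), factors, area, options.include_soil
            )
            rows[(region, cat.name, ft.name, "emission_deforestation")] += emitted / length
        if ft == ForestType.nonforest:
            if gain[i]:
                rows[
                    (region, cat.name, "young_secondary", "removal")
                ] += removal_flux(
                    ForestType.young_secondary,
                    region,
                    LOSS_NONE,
                    factors,
                    area,
                    stack.period,
                )
        else:
            ly_eff = ly if options.removals_on_lost_cells else (start + 1 if lost else ly)
            value = removal_flux(ft, region, ly_eff, factors, area, stack.period)
            if lost and not options.removals_on_lost_cells:
                value = 0.0
            rows[(region, cat.name, ft.name, "removal")] += value
        if options.include_peat and peat[i] and lost:
            years_drained = end - ly + 1
            rows[(region, cat.name, ft.name, "emission_peat_decomposition")] += (
                area * factors.peat_decomposition * years_drained / length
            )
            rows[(region, cat.name, ft.name, "emission_peat_fire")] += (
                area * factors.peat_fire / length
            )
    return {k: v for k, v in rows.items() if v != 0.0}


def ledger_to_dict(ledger):
    """Flatten a FluxLedger into the oracle's key -> value form."""
    out = {}
    for row in ledger.table.itertuples(index=False):
        key = (row.region, row.category, row.forest_type, row.component)
        out[key] = out.get(key, 0.0) + row.value_mg_co2e_per_yr
    return {k: v for k, v in out.items() if v != 0.0}


def assert_ledgers_match(ledger, oracle_rows, rel=1e-9):
    got = ledger_to_dict(ledger)
    assert set(got) == set(oracle_rows), (
        set(got) ^ set(oracle_rows)
    )
    for key, expected in oracle_rows.items():
        assert got[key] == __import__("pytest").approx(expected, rel=rel), key
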