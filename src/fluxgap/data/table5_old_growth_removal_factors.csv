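biome,nghgi_rf,eo_rf_modal,eo_rf_secondary,eo_comparison,printed_pct_diff
Amazonia,0.48,0.59,0.24,0.59,23
Atlantic Forest,0.44,0.59,0.24,0.59,34
Cerrado,0.2,0.24,0.59,0.24,20
Pantanal,0.2,0.24,,0.24,20
Pampa,0.44,,0.59,0.59,34
Caatinga,0.1,0.95,,0.95,850
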