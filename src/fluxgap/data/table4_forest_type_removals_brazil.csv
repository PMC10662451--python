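dataset,forest_type,area_kha,gross_removals_gtco2_yr
global_eo,managed_old_growth,195954,-0.42
global_eo,secondary_forest,23998,-0.16
global_eo,plantation,6779,-0.19
global_eo,other_land,31732,
nghgi,managed_old_growth,220158,-0.32
nghgi,secondary_forest,21877,-0.05
nghgi,plantation,11144,-0.08
nghgi,other_land,5284,
seeg,managed_old_growth,217702,-0.31
seeg,secondary_forest,8547,-0.16
seeg,plantation,6311,-0.003
seeg,other_land,25903,
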