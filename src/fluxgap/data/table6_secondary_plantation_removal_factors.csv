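stratum,biome,nghgi_rf,nghgi_min,nghgi_max,eo_rf,eo_min,eo_max,printed_pct_diff,printed_decimals
plantation,Amazonia,12.5,8.3,12.66,11.2,4.72,20.3,-10.4,1
plantation,Atlantic Forest,11.6,10.5,12.6,12.7,4.72,20.3,9.5,1
plantation,Cerrado,12.6,11.1,12.6,16.6,4.72,20.3,31.7,1
plantation,Pantanal,12.7,12.7,12.7,20.2,4.72,20.3,59.1,1
plantation,Pampa,11.0,11.0,11.0,12.9,4.72,20.3,17.3,1
plantation,Caatinga,12.6,12.1,12.7,17.0,4.72,20.3,34.9,1
young_secondary,Amazonia,3.1,0.6,5.2,6.4,3.9,8.0,106,0
young_secondary,Atlantic Forest,1.7,1.7,1.7,4.5,2.0,7.6,165,0
young_secondary,Cerrado,2.7,0.6,4.7,4.3,2.5,7.3,59,0
young_secondary,Pantanal,2.8,0.6,4.7,3.6,2.3,5.5,29,0
young_secondary,Pampa,3.2,0.6,4.7,2.8,1.6,5.1,-13,0
young_secondary,Caatinga,0.7,0.6,1.0,4.5,2.5,7.2,543,0
old_secondary,Amazonia,,,,1.36,,,,
old_secondary,Atlantic Forest,,,,1.36,,,,
old_secondary,Cerrado,,,,1.60,,,,
old_secondary,Pantanal,,,,1.60,,,,
old_secondary,Pampa,,,,0.59,,,,
old_secondary,Caatinga,,,,1.60,,,,
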