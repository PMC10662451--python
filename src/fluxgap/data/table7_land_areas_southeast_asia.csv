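country,dataset,land_type,land_class,wetness,area_kha
Indonesia,global_eo,primary_dry_forest,natural_forest,dry,72109.1
Indonesia,global_eo,primary_swamp_forest,natural_forest,swamp,9017.7
Indonesia,global_eo,old_secondary_dry_forest,natural_forest,dry,33168.4
Indonesia,global_eo,old_secondary_swamp_forest,natural_forest,swamp,5220.0
Indonesia,global_eo,young_secondary_dry_forest,natural_forest,dry,1772.8
Indonesia,global_eo,young_secondary_swamp_forest,natural_forest,swamp,197.5
Indonesia,global_eo,forest_plantation,plantation,,358.7
Indonesia,global_eo,tree_plantation,plantation,,26127.6
Indonesia,global_eo,other_land,nonforest,,40890.0
Indonesia,nghgi,primary_dry_forest,natural_forest,dry,41029
Indonesia,nghgi,primary_swamp_forest,natural_forest,swamp,4852
Indonesia,nghgi,secondary_dry_forest,natural_forest,dry,36469
Indonesia,nghgi,secondary_swamp_forest,natural_forest,swamp,6924
Indonesia,nghgi,forest_plantation,plantation,,5551
Indonesia,nghgi,tree_plantation,plantation,,20564
Indonesia,nghgi,other_land,nonforest,,76809
Malaysia,global_eo,old_growth_forest,natural_forest,,12483.4
Malaysia,global_eo,old_secondary_forest,natural_forest,,4595.9
Malaysia,global_eo,young_secondary_forest,natural_forest,,361.9
Malaysia,global_eo,forest_plantation,plantation,,0.0
Malaysia,global_eo,tree_plantation,plantation,,10613.8
Malaysia,global_eo,other_land,nonforest,,4922.5
Malaysia,nghgi,forest_land_remaining_forest_land,natural_forest,,17735.3
Malaysia,nghgi,cropland_remaining_cropland,cropland,,7037.9
Malaysia,nghgi,forest_land_converted_to_cropland,cropland,,0.85
Malaysia,nghgi,settlement_remaining_settlement,settlement,,2327.1
Malaysia,nghgi,forest_land_converted_to_settlement,settlement,,137.1
Malaysia,nghgi,cropland_converted_to_settlement,settlement,,21.9
Malaysia,nghgi,grassland_remaining_grassland,grassland,,313.0
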