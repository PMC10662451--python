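country,dataset,factor_kind,label,value,value_min,value_max,unit,note
Indonesia,global_eo,emission,primary_forest_country_average,197.7,,,Mg C/ha,
Indonesia,nghgi,emission,primary_dryland_forest,176.6,,,Mg C/ha,converted from biomass with carbon fraction 0.47
Indonesia,nghgi,emission,primary_swamp_forest,142.7,,,Mg C/ha,converted from biomass with carbon fraction 0.47
Malaysia,global_eo,emission,primary_forest_country_average,159.3,,,Mg C/ha,
Malaysia,nghgi,emission,inland_state_land_forest,140,,,Mg C/ha,
Malaysia,nghgi,emission,prf_inland,194,,,Mg C/ha,
Malaysia,global_eo,removal,old_growth,0.41,,,Mg C/ha/yr,
Malaysia,global_eo,removal,old_secondary_forest,1.60,,,Mg C/ha/yr,
Malaysia,global_eo,removal,young_secondary_forest,4.2,1.3,10.6,Mg C/ha/yr,
Malaysia,global_eo,removal,plantation_forest,,3.0,14.1,Mg C/ha/yr,
Malaysia,global_eo,removal,rubber,3.4,,,Mg C/ha/yr,
Malaysia,global_eo,removal,oil_palm,3.02,,,Mg C/ha/yr,
Malaysia,nghgi,removal,inland_forest,4.37,,,Mg C/ha/yr,
Malaysia,nghgi,removal,peat_swamp,4.32,,,Mg C/ha/yr,
Malaysia,nghgi,removal,state_land,2.02,,,Mg C/ha/yr,
Malaysia,nghgi,removal,plantation_forest,2.44,,,Mg C/ha/yr,
Malaysia,nghgi,removal,rubber,1.95,,,Mg C/ha/yr,
Malaysia,nghgi,removal,oil_palm,1.84,,,Mg C/ha/yr,
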