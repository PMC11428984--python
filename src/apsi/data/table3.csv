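test_id,category,scheme,max_score,A6,FZB42,DSM7,D747
root_length_pgpr,growth,tiered,5,5,3.75,3.75,3.75
stem_length_pgpr,growth,tiered,5,5,5,3.75,2.5
dry_weight_pgpr,growth,tiered,5,5,5,2.5,3.75
rwc_pgpr,growth,tiered,5,5,5,5,5
rwc_drought,drought,tiered,9,9,6.75,6.75,6.75
root_length_drought,drought,tiered,9,9,6.75,6.75,4.5
dry_weight_drought,drought,tiered,9,9,6.75,6.75,6.75
antagonism_b_cinerea,fungal,tiered,7,7,7,1.75,7
antagonism_f_oxysporum,fungal,probit,7,5.95,3.5,0,5.25
antibiosis_b_cinerea,fungal,tiered,7,3.5,3.5,1.75,3.5
antibiosis_f_oxysporum,fungal,tiered,7,3.5,1.75,1.75,3.5
siderophores,siderophore,binary,4,4,4,4,4
phosphate_solubilization,solubilization,tiered,4,1,2,4,2
potassium_solubilization,solubilization,binary,4,4,4,4,4
iaa_production,hormone,tiered,3,0.75,0.75,3,0.75
iba_production,hormone,tiered,3,2.25,2.25,3,2.25
ga3_production,hormone,tiered,3,0,0,3,0
urea_hydrolysis,urease,binary,4,0,,0,0
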