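ligand,conc_range_mM,aggregate,kd_mM,kd_err_mM,binding_detected
[C2C1Im][C4F9SO3],"]0, 14.40[",monomer,,,False
[C2C1Im][C4F9SO3],"[14.4, 34.48[",1st CAC,1.27,0.64,True
[C2C1Im][C4F9SO3],"[34.48, 76.54[",2nd CAC,0.87,0.36,True
[N1112(OH)][C4F9SO3],"]0, 16.02[",monomer,,,False
[N1112(OH)][C4F9SO3],"[16.02, 35.17[",1st CAC,6.05,1.67,True
[N1112(OH)][C4F9SO3],"[35.17, 185.65[",2nd CAC,6.25,1.47,True
[C4C1Im][CF3SO3],"]0, 100]",monomer,,,False
[N1112(OH)][H2PO4],"]0, 100]",monomer,,,False
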