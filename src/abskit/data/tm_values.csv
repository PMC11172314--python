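sample,conc_mg_ml,tm_C,tm_err_C
lysozyme in water (DSC control),1.0,73.71,0.004
lysozyme in water,1.0,74.56,0.835
lysozyme resuspended from FIL-rich phase BP#5,1.0,69.04,0.005
lysozyme resuspended from FIL-rich phase BP#7,1.0,68.43,0.004
lysozyme resuspended from FIL-rich phase BP#8,1.0,69.15,0.013
lysozyme in [N1112(OH)][H2PO4]-rich phase BP#10,1.0,76.31,0.005
lysozyme in [N1112(OH)][H2PO4]-rich phase BP#12,0.5,66.70,0.008
lysozyme in [N1112(OH)][H2PO4]-rich phase BP#11,1.0,54.89,0.012
lysozyme + [N1112(OH)][C4F9SO3] transition 1,1.0,80.04,
lysozyme + [N1112(OH)][C4F9SO3] transition 2,1.0,83.39,
lysozyme + [N1112(OH)][C4F9SO3] transition 3,1.0,86.40,
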