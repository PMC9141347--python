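species	has_te
B_ovata	1
B_bigemina	1
B_bovis	0
B_divergens	1
T_equi	1
C_felis	0
T_orientalis	0
T_parva	0
T_annulata	0
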