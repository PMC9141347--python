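species	has_te
E_tenella	1
E_necatrix	1
E_mitis	1
E_brunetti	1
E_praecox	1
E_maxima	1
E_acervulina	1
E_falciformis	1
E_nieschulzi	1
C_cayetanensis	1
C_suis	1
H_hammondi	0
T_gondii	0
N_caninum	0
B_besnoiti	0
S_neurona	0
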