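((((((((E_tenella,E_necatrix),E_mitis),E_brunetti),E_praecox),E_maxima),(E_acervulina,(E_falciformis,E_nieschulzi))),C_cayetanensis),(C_suis,(S_neurona,(B_besnoiti,(N_caninum,(T_gondii,H_hammondi))))));
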