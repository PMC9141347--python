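((((B_ovata,B_bigemina),B_bovis),B_divergens),(T_equi,(C_felis,(T_orientalis,(T_parva,T_annulata)))));
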