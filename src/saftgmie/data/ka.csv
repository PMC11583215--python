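compound,K_A1_298,dh_A1_kJmol,K_A2_298,dh_A2_kJmol
glycine,4.525e-3,61.101,2.54e-10,44.780
alanine,4.535e-3,61.101,2.06e-10,47.919
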