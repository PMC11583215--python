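solute,T_fus_K,dh_fus_kJmol,dcp_JmolK
glycine,569,22,
alanine,608,23,
valine,529,44,
leucine,518,43,
serine,519,28,
gly-gly,593,40,51
gly-gly-gly,594,54,57
ala-ala,606,54,62
ala-ala-ala,606,72,124
gly-ala,551,41,55
ala-gly,611,52,57
gly-gly-ala,592,70,66
gly-ala-gly,623,61,78
ala-gly-ala,557,58,98
leu-gly-gly,530,74,111
gly-leu-gly,545,60,139
gly-gly-leu,521,55,160
gly-ala-leu,578,77,112
gly-ser,530,49,67
ser-gly,553,62,61
ala-ser,556,43,48
ser-ala,609,73,55
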