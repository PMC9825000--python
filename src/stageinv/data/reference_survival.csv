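stage,survival_2yr,survival_5yr
IA,0.93,0.82
IB,0.85,0.66
IIA,0.74,0.52
IIB,0.64,0.47
IIIA,0.55,0.36
IIIB,0.34,0.19
IV,0.17,0.06
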