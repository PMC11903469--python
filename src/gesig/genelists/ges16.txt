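IL18R1
GPC4
KIR3DL2
ITGB8
PSMB5
RPS6KB1
BCL2
TNFSF4
SERPINA9
DUSP5
NBN
GLUD1
ESR1
ARID1A
KLRB1
SLC16A1
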