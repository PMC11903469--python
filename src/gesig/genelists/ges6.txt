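CD19
PTPRC-RA
CCL22
KLRK1
SIGLEC5
SOX11
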