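# Thyroid differentiation score panel (TCGA-style defaults, editable).
# 16 thyroid metabolism and function genes; one gene id per line.
DIO1
DIO2
DUOX1
DUOX2
FOXE1
GLIS3
NKX2-1
PAX8
SLC26A4
SLC5A5
SLC5A8
TG
THRA
THRB
TPO
TSHR
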