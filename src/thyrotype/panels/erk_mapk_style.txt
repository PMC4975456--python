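# ERK score panel (TCGA-style defaults, editable).
# 52 MAPK signaling pathway genes; one gene id per line.
ARAF
BRAF
RAF1
MAP2K1
MAP2K2
MAPK1
MAPK3
DUSP1
DUSP2
DUSP4
DUSP5
DUSP6
ETV1
ETV4
ETV5
SPRY1
SPRY2
SPRY4
SPRED1
SPRED2
FOS
FOSB
JUN
JUNB
EGR1
ELK1
ELK3
ELK4
MYC
CCND1
RPS6KA1
RPS6KA2
RPS6KA3
EPHA2
EPHA4
FGFR1
GRB2
SOS1
SOS2
HRAS
KRAS
NRAS
SHC1
KSR1
KSR2
RASGRP1
PEA15
PHLDA1
EFNA1
EFNA5
TRIB2
IER3
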