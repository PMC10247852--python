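# Synthetic placeholder gene list (AORTA, 27 genes).
# Plausible symbols for exercising the triage logic; substitute the
# laboratory's curated panel for real use.
FBN1
FBN2
TGFBR1
TGFBR2
TGFB2
TGFB3
SMAD2
SMAD3
SMAD4
ACTA2
MYH11
MYLK
PRKG1
LOX
COL3A1
COL5A1
COL5A2
EFEMP2
ELN
SLC2A10
SKI
FLNA
NOTCH1
BGN
FOXE3
MAT2A
TGFBR3
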