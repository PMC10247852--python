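# Synthetic placeholder gene list (SDGP, 166 genes).
# Plausible symbols for exercising the triage logic; substitute the
# laboratory's curated panel for real use.
MYH7
MYBPC3
TNNT2
TNNI3
TPM1
MYL2
MYL3
ACTC1
PLN
CSRP3
TNNC1
ACTN2
NEXN
VCL
JPH2
KCNQ1
KCNH2
SCN5A
KCNE1
KCNE2
KCNJ2
KCNJ5
CACNA1C
CACNB2
CACNA2D1
SCN1B
SCN3B
SCN4B
SCN10A
GPD1L
HCN4
TRPM4
KCND3
KCNE3
AKAP9
SNTA1
CAV3
ANK2
RYR2
CASQ2
TRDN
TECRL
CALM1
CALM2
CALM3
LMNA
DES
FLNC
BAG3
RBM20
TTN
LDB3
TCAP
ANKRD1
MYOZ2
MYH6
MYPN
TMPO
PSEN1
PSEN2
CTNNA3
DSP
PKP2
DSG2
DSC2
JUP
TMEM43
PRKAG2
GLA
LAMP2
TTR
EMD
DMD
TAZ
CRYAB
FHL1
ABCC9
SGCD
MYLK2
ALPK3
PRDM16
EYA4
TBX20
NKX2-5
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
PTPN11
SOS1
SOS2
RAF1
RIT1
KRAS
NRAS
HRAS
BRAF
MAP2K1
MAP2K2
SHOC2
CBL
LZTR1
RRAS2
LDLR
APOB
PCSK9
LDLRAP1
APOE
GATA4
GATA5
GATA6
TBX5
NODAL
CITED2
CRELD1
PLEKHM2
TMEM70
DOLK
DNAJC19
AGL
GAA
GBE1
FXN
ATP5F1E
ELAC2
MRPL3
MRPL44
TSFM
AARS2
COX15
SCO2
NDUFAF1
ACAD9
ACADVL
HADHA
MLYCD
SLC22A5
CPT2
KCNA5
KCNE5
KCNK3
NPPA
GJA1
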