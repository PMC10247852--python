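# Synthetic placeholder gene list (CDGP, 84 genes).
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
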