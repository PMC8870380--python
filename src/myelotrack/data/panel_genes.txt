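ACTG1
ARID1A
ARID2
ATM
BCL7A
BHLHE41
BIRC2
BIRC3
BRAF
BTG1
CCND1
CDKN1B
CDKN2A
CDKN2C
CRBN
CUL4A
CUL4B
CYLD
DIS3
DNMT3A
DTX1
DUSP2
EGR1
FAM46C
FGFR3
FUBP1
HIST1H1B
HIST1H1D
HIST1H1E
HIST1H2BK
IDH1
IDH2
IGLL5
IKBKB
IKZF1
IKZF3
IRF1
IRF4
KDM6A
KLHL6
KMT2D
KRAS
LCE1D
LTB
MAF
MAFB
MAP3K1
MAX
MYC
MYD88
NFKB2
NFKBIA
NRAS
PABPC1
PIM1
POT1
PRDM1
PRKD2
PSMB5
PTPN11
RASA2
RB1
RFTN1
RIPK1
RPL10
RPL5
RPRD1B
RPS3A
SAMHD1
SETD2
SP140
STAT3
TBC1D29
TCL1A
TGDS
TP53
TRAF2
TRAF3
XBP1
ZNF292
ZNF462
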