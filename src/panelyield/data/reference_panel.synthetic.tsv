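symbol	mode	category
ZNF644	AD	nonsyndromic_HM
SCO2	AD	nonsyndromic_HM
P4HA2	AD	nonsyndromic_HM
CPSF1	AD	nonsyndromic_HM
TNFRSF21	AD	nonsyndromic_HM
DZIP1	AD	nonsyndromic_HM
XYLT1	AD	nonsyndromic_HM
BSG	AD	nonsyndromic_HM
NDUFAF7	AD	nonsyndromic_HM
CCDC111	AD	nonsyndromic_HM
UNC5D	AD	nonsyndromic_HM
SLC39A5	AD	nonsyndromic_HM
ARR3	XL	nonsyndromic_HM
LOXL3	AR	nonsyndromic_HM
LRPAP1	AR	nonsyndromic_HM
CTSH	AR	nonsyndromic_HM
RPGR	XL	eye_syndrome
OPN1LW	XL	eye_syndrome
OPN1MW	XL	eye_syndrome
CACNA1F	XL	eye_syndrome
NYX	XL	eye_syndrome
RP2	XL	eye_syndrome
NDP	XL	eye_syndrome
FZD4	AD	eye_syndrome
LRP5	AR	eye_syndrome
TSPAN12	AD	eye_syndrome
CEP290	AR	eye_syndrome
BBS1	AR	eye_syndrome
BBS2	AR	eye_syndrome
BBS4	AR	eye_syndrome
BBS7	AR	eye_syndrome
BBS10	AR	eye_syndrome
TRPM1	AR	eye_syndrome
GRM6	AR	eye_syndrome
LRIT3	AR	eye_syndrome
GPR179	AR	eye_syndrome
RPE65	AR	eye_syndrome
CRB1	AR	eye_syndrome
ABCA4	AR	eye_syndrome
BEST1	AD	eye_syndrome
PDE6B	AR	eye_syndrome
GUCY2D	AD	eye_syndrome
PRPH2	AD	eye_syndrome
COL2A1	AD	systemic_syndrome
COL11A1	AD	systemic_syndrome
COL11A2	AD	systemic_syndrome
COL9A1	AR	systemic_syndrome
COL9A2	AR	systemic_syndrome
COL9A3	AR	systemic_syndrome
COL18A1	AR	systemic_syndrome
FBN1	AD	systemic_syndrome
FBN2	AD	systemic_syndrome
LRP2	AD	systemic_syndrome
LTBP2	AR	systemic_syndrome
TGFBR1	AD	systemic_syndrome
TGFBR2	AD	systemic_syndrome
SMAD3	AD	systemic_syndrome
TGFB2	AD	systemic_syndrome
SKI	AD	systemic_syndrome
COL1A1	AD	systemic_syndrome
COL3A1	AD	systemic_syndrome
COL5A1	AD	systemic_syndrome
COL5A2	AD	systemic_syndrome
PLOD1	AR	systemic_syndrome
B3GALT6	AR	systemic_syndrome
B4GALT7	AR	systemic_syndrome
ZNF469	AR	systemic_syndrome
PRDM5	AR	systemic_syndrome
P3H2	AR	systemic_syndrome
SLC39A13	AR	systemic_syndrome
ADAMTS10	AR	systemic_syndrome
ADAMTS17	AR	systemic_syndrome
ADAMTSL4	AR	systemic_syndrome
FBLN5	AR	systemic_syndrome
ELN	AD	systemic_syndrome
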