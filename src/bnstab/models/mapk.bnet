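# Boolean model of the MAPK signalling network governing cancer cell fate
# (logical rules after Grieco et al. 2013, PLoS Comput Biol 9:e1003286).
# Inputs: DNA_damage, EGFR_stimulus, FGFR3_stimulus, TGFBR_stimulus.
# Outputs: Proliferation, Apoptosis, Growth_Arrest.
targets, factors
DNA_damage, DNA_damage
EGFR_stimulus, EGFR_stimulus
FGFR3_stimulus, FGFR3_stimulus
TGFBR_stimulus, TGFBR_stimulus
AKT, PI3K & PDK1 & !PTEN
AP1, JUN & (FOS | ATF2)
ATF2, JNK | p38
ATM, DNA_damage
Apoptosis, FOXO3 & p53 & !BCL2 & !ERK
BCL2, AKT & CREB
CREB, MSK
DUSP1, CREB
EGFR, (EGFR_stimulus | SPRY) & !(FGFR3 | GRB2)
ELK1, ERK | JNK | p38
ERK, MEK1_2
FGFR3, FGFR3_stimulus & !(EGFR | GRB2)
FOS, ERK & RSK & (ELK1 | CREB)
FOXO3, JNK & !AKT
FRS2, FGFR3 & !(SPRY | GRB2)
GAB1, GRB2 | PI3K
GADD45, SMAD | p53
GRB2, EGFR | FRS2 | TGFBR
Growth_Arrest, p21
JNK, (TAOK & TAK1) | (TAOK & MTK1) | (TAOK & MAP3K1_3) | (TAK1 & MTK1) | (TAK1 & MAP3K1_3) | (MTK1 & MAP3K1_3) | ((TAOK | TAK1 | MTK1 | MAP3K1_3) & !DUSP1)
JUN, JNK
MAP3K1_3, RAS
MAX, p38
MDM2, (p53 | AKT) & !p14 & !ATM
MEK1_2, (RAF | MAP3K1_3) & !(PPP2CA | AP1)
MSK, ERK | p38
MTK1, GADD45
MYC, MAX & (MSK | AKT)
PDK1, PI3K
PI3K, GAB1 | (RAS & SOS)
PKC, PLCG
PLCG, EGFR | FGFR3
PPP2CA, p38
PTEN, p53 & !MDM2
Proliferation, p70 & MYC & !p21 & !GADD45
RAF, (RAS | PKC) & !(ERK | AKT)
RAS, SOS | PLCG
RSK, ERK
SMAD, TGFBR
SOS, GRB2 & !RSK
SPRY, ERK
TAK1, TGFBR
TAOK, ATM
TGFBR, TGFBR_stimulus
p14, MYC
p21, p53 & !AKT
p38, (TAOK & TAK1) | (TAOK & MTK1) | (TAOK & MAP3K1_3) | (TAK1 & MTK1) | (TAK1 & MAP3K1_3) | (MTK1 & MAP3K1_3) | ((TAOK | TAK1 | MTK1 | MAP3K1_3) & !DUSP1)
p53, (ATM | p38) & !MDM2
p70, PDK1 & ERK
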