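# Boolean model of the tumour-cell metastasis influence network
# (logical rules after Cohen et al. 2015, PLoS Comput Biol 11:e1004571).
# Inputs: ECMicroenv, DNADamage (self-identity).  Output: Metastasis.
targets, factors
ECMicroenv, ECMicroenv
DNADamage, DNADamage
AKT1, CTNNB1 & (NICD | TGFbeta | GF | CDH2) & !p53 & !miR34 & !CDH1
AKT2, TWIST1 & (TGFbeta | GF | CDH2) & !(miR203 | miR34 | p53)
CDH1, !TWIST1 & !SNAI2 & !ZEB1 & !ZEB2 & !SNAI1 & !AKT2
CDH2, TWIST1
CTNNB1, !DKK1 & !p53 & !AKT1 & !miR34 & !miR200 & !CDH1 & !CDH2 & !p63
DKK1, CTNNB1 | NICD
ERK, (SMAD | CDH2 | GF | NICD) & !AKT1
GF, !CDH1 & (GF | CDH2)
miR200, (p63 | p53 | p73) & !(AKT2 | SNAI1 | SNAI2 | ZEB1 | ZEB2)
miR203, p53 & !(SNAI1 | ZEB1 | ZEB2)
miR34, !(SNAI1 | ZEB1 | ZEB2) & (p53 | p63 | p73) & AKT2 & !AKT1
NICD, !p53 & !p63 & !p73 & !miR200 & !miR34 & ECMicroenv
p21, ((SMAD & NICD) | p63 | p53 | p73 | AKT2) & !(AKT1 | ERK)
p53, (DNADamage | CTNNB1 | NICD | miR34) & !SNAI2 & !p73 & !AKT1 & !AKT2
p63, DNADamage & !NICD & !AKT1 & !AKT2 & !p53 & !miR203
p73, DNADamage & !p53 & !ZEB1 & !AKT1 & !AKT2
SMAD, TGFbeta & !miR200 & !miR203
SNAI1, (NICD | TWIST1) & !miR203 & !miR34 & !p53 & !CTNNB1
SNAI2, (TWIST1 | CTNNB1 | NICD) & !miR200 & !p53 & !miR203
TGFbeta, (ECMicroenv | NICD) & !CTNNB1
TWIST1, CTNNB1 | NICD | SNAI1
VIM, CTNNB1 | ZEB2
ZEB1, ((TWIST1 & SNAI1) | CTNNB1 | SNAI2 | NICD) & !miR200
ZEB2, (SNAI1 | (SNAI2 & TWIST1) | NICD) & !miR200 & !miR203
CellCycleArrest, (miR203 | miR200 | miR34 | ZEB2 | p21) & !AKT1
Apoptosis, (p53 | p63 | p73 | miR200 | miR34) & !ZEB2 & !AKT1 & !ERK
EMT, CDH2 & !CDH1
Invasion, (SMAD & CDH2) | CTNNB1
Migration, VIM & AKT2 & ERK & !miR200 & !AKT1 & EMT & Invasion & !p63
Metastasis, Migration
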