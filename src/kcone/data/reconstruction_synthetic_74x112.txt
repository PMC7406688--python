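# SYNTHETIC STAND-IN reconstruction (not a published network).
# A hand-curated central-metabolism network at the scale of a medium-size
# NSCLC reconstruction: 74 internal metabolites and 112 reactions spanning
# glycolysis, pentose phosphate, TCA cycle, amino acid, one-carbon,
# glutathione, fatty acid and polyamine chemistry.  Species suffixed _ext
# are boundary (implicit uptake/secretion) and excluded from steady-state
# balance.  Format: 'ID: substrates -> products genes=... pathways=...'
# glycolysis
GLC_UPT: glc_ext -> glc
HEX: glc -> g6p genes=HK1,HK2 pathways=glycolysis
PGI: g6p <=> f6p genes=GPI pathways=glycolysis
PFK: f6p -> fbp genes=PFKL,PFKM pathways=glycolysis
ALD: fbp <=> dhap + g3p genes=ALDOA pathways=glycolysis
TPI: dhap <=> g3p genes=TPI1 pathways=glycolysis
GAPDH: g3p <=> bpg13 genes=GAPDH pathways=glycolysis
PGK: bpg13 <=> pg3 genes=PGK1 pathways=glycolysis
PGM: pg3 <=> pg2 genes=PGAM1 pathways=glycolysis
ENO: pg2 <=> pep genes=ENO1 pathways=glycolysis
PYK: pep -> pyr genes=PKM pathways=glycolysis
LDH: pyr <=> lac genes=LDHA pathways=glycolysis
LAC_EX: lac -> lac_ext
# pentose phosphate
G6PD: g6p -> pgl6 genes=G6PD pathways=ppp
PGL: pgl6 -> pg6 genes=PGLS pathways=ppp
GND: pg6 -> ru5p genes=PGD pathways=ppp
RPI: ru5p <=> r5p genes=RPIA pathways=ppp
RPE: ru5p <=> x5p genes=RPE pathways=ppp
TKT1: x5p + r5p <=> s7p + g3p genes=TKT pathways=ppp
TAL: s7p + g3p <=> e4p + f6p genes=TALDO1 pathways=ppp
TKT2: x5p + e4p <=> f6p + g3p genes=TKT pathways=ppp
R5P_EX: r5p -> r5p_ext
# TCA cycle
PDH: pyr -> accoa genes=PDHA1 pathways=tca
CS: accoa + oaa -> cit genes=CS pathways=tca
ACO: cit <=> icit genes=ACO2 pathways=tca
IDH: icit -> akg genes=IDH1,IDH2 pathways=tca
AKGDH: akg -> succoa genes=OGDH pathways=tca
SCS: succoa <=> succ genes=SUCLA2 pathways=tca
SDH: succ <=> fum genes=SDHA pathways=tca
FH: fum <=> mal genes=FH pathways=tca
MDH: mal <=> oaa genes=MDH2 pathways=tca
PC: pyr -> oaa genes=PC pathways=anaplerosis
ME: mal -> pyr genes=ME1 pathways=anaplerosis
# glutaminolysis and amino acids
GLN_UPT: gln_ext -> gln
GLS: gln -> glu genes=GLS,GLS2 pathways=glutaminolysis
GDH: glu <=> akg genes=GLUD1 pathways=glutaminolysis
ALT: pyr + glu <=> ala + akg genes=GPT pathways=amino_acid
AST: oaa + glu <=> asp + akg genes=GOT1,GOT2 pathways=amino_acid
ASNS: asp -> asn genes=ASNS pathways=amino_acid
PSP: pg3 -> ser genes=PHGDH,PSAT1,PSPH pathways=amino_acid
SHMT: ser <=> gly genes=SHMT1,SHMT2 pathways=amino_acid
CYS_UPT: cys_ext -> cys
P5CS: glu -> pro genes=ALDH18A1,PYCR1 pathways=amino_acid
ARG_UPT: arg_ext -> arg
ARGASE: arg -> orn + urea_ext genes=ARG2 pathways=urea_cycle
OAT: orn <=> glu genes=OAT pathways=amino_acid
GLU_EX: glu -> glu_ext
ALA_EX: ala -> ala_ext
ASN_EX: asn -> asn_ext
PRO_EX: pro -> pro_ext
# glutathione
GCL: glu + cys -> glucys genes=GCLC,GCLM pathways=glutathione
GSS: glucys + gly -> gsh genes=GSS pathways=glutathione
GPX: 2 gsh -> gssg genes=GPX1,GPX2,GPX3 pathways=glutathione
GSR: gssg -> 2 gsh genes=GSR pathways=glutathione
GGT: gsh -> cysgly + glu pathways=glutathione genes=GGT1
APN: cysgly -> cys + gly genes=ANPEP pathways=glutathione
GSH_EX: gsh -> gsh_ext
# branched chain
LEU_UPT: leu_ext -> leu
LEU_DEG: leu -> accoa genes=BCAT1 pathways=bcaa
ILE_UPT: ile_ext -> ile
ILE_DEG: ile -> succoa genes=BCAT1 pathways=bcaa
VAL_UPT: val_ext -> val
VAL_DEG: val -> succoa genes=BCAT1 pathways=bcaa
# aromatic
PHE_UPT: phe_ext -> phe
PAH: phe -> tyr genes=PAH pathways=amino_acid
TYR_DEG: tyr -> fum genes=TAT pathways=amino_acid
# fatty acid
ACC: accoa -> malcoa genes=ACACA pathways=fatty_acid
FAS: 8 malcoa -> palm genes=FASN pathways=fatty_acid
PALM_EX: palm -> palm_ext
BOX: palm -> 8 accoa genes=CPT1A pathways=fatty_acid
# one carbon / methionine
MET_UPT: met_ext -> met
MAT: met -> sam genes=MAT2A pathways=one_carbon
MTASE: sam -> sah pathways=one_carbon
SAHH: sah -> hcys + ado genes=AHCY pathways=one_carbon
MS: hcys -> met genes=MTR pathways=one_carbon
CBS: hcys + ser -> cysta genes=CBS pathways=transsulfuration
CTH: cysta -> cys + akg genes=CTH pathways=transsulfuration
ADA: ado -> ino genes=ADA pathways=nucleotide
PNP: ino -> r5p + hyp_ext genes=PNP pathways=nucleotide
# other amino acids
THR_UPT: thr_ext -> thr
THR_GLY: thr -> gly genes=GLYAT pathways=amino_acid
LYS_UPT: lys_ext -> lys
LYS_DEG: lys -> akg genes=AASS pathways=amino_acid
HIS_UPT: his_ext -> his
HIS_GLU: his -> glu genes=HAL pathways=amino_acid
TRP_UPT: trp_ext -> trp
TRP_KYN: trp -> kyn genes=IDO1 pathways=amino_acid
KYN_ALA: kyn -> ala genes=KYNU pathways=amino_acid
# taurine
CDO: cys -> hyptau genes=CDO1 pathways=taurine
HTD: hyptau -> tau genes=FMO1 pathways=taurine
TAU_EX: tau -> tau_ext
# choline / betaine
CHOL_UPT: chol_ext -> chol
CHDH: chol -> bet genes=CHDH pathways=one_carbon
BHMT: bet + hcys -> met genes=BHMT pathways=one_carbon
# carnitine
CARN_SYN: lys -> carn genes=BBOX1 pathways=carnitine
CARN_UPT: carn_ext -> carn
CARN_EX: carn -> carn_ext
# glycerol
GLYC_UPT: glyc_ext -> glyc
GK: glyc -> gl3p genes=GK pathways=glycerolipid
GPD: gl3p <=> dhap genes=GPD1 pathways=glycerolipid
# urea cycle / polyamines
ORN_CITR: orn -> citr genes=OTC pathways=urea_cycle
ASS: citr + asp -> argsucc genes=ASS1 pathways=urea_cycle
ASL: argsucc -> arg + fum genes=ASL pathways=urea_cycle
ODC: orn -> putr genes=ODC1 pathways=polyamine
SPDS: putr + sam -> spd genes=SRM pathways=polyamine
SPMS: spd + sam -> spm genes=SMS pathways=polyamine
SPM_EX: spm -> spm_ext
# additional exchanges
GLY_UPT: gly_ext -> gly
SER_EX: ser -> ser_ext
ASP_EX: asp -> asp_ext
PYR_EX: pyr -> pyr_ext
CIT_EX: cit -> cit_ext
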