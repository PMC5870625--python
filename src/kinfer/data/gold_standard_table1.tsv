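kinase	condition	direction
AKT1	AKTi (Akt inhibitor VIII)	down
AKT1	AKTi (MK-2206)	down
AKT1	PI3Ki (GDC-0941)	down
AKT1	PI3Ki (PI-103)	down
AKT1	PIK3CA activation (H1047R) + inhibitor	down
AKT1	PIK3CA activation (E545K)	up
AKT1	PIK3CA activation (H1047R)	up
AKT1	RG7356	up
PRKCA	Anti-CD3	up
PRKCA	anti-CD3 + anti-CD28	up
PRKCA	Differentiation (PMA)	up
PRKCA	PKCi (BIM-1)	down
PRKCA	PKCi (Go-6976)	down
ATR	ATR inhibitor (VE-821)	down
CAMK2A	CAMK2i (KN-62)	down
CAMK2A	CAMK2i (KN-93)	down
ALK	Crizotinib	down
MAPK3	Dasatinib (50 nM)	down
ABL	Dasatinib (50 nM)	down
LCK	Dasatinib (50 nM)	down
ATR	DNA damage (Etoposide)	up
ATR	DNA damage (Ionizing radiation)	up
ATR	Early S (Thymidine)	up
ATR	G1_S (Thymidine)	up
ATR	Late S (Thymidine)	up
ATM	DNA damage (Etoposide)	up
ATM	DNA damage (Ionizing radiation)	up
ATM	Early S (Thymidine)	up
ATM	G1_S (Thymidine)	up
ATM	Late S (Thymidine)	up
AKT1	EGF	up
BRAF	EGF	up
EGFR	EGF	up
MAP2K1	EGF	up
MAP2K2	EGF	up
MAPK1	EGF	up
MAPK3	EGF	up
RAF1	EGF	up
EGFR	EGFRi (PD-153035)	down
EGFR	EGFRi (PD-168393)	down
EGFR	Erlotinib	down
EGFR	Gefitinib	down
MAPK14	EGF + SB202190	down
MAP2K1	EGF + U0126	down
MAP2K1	MEKi (GSK-1120212)	down
MAP2K1	MEKi (U0126)	down
MAP2K1	Selumetinib (AZD6244)	down
MAP2K2	EGF + U0126	down
MAP2K2	MEKi (GSK-1120212)	down
MAP2K2	MEKi (U0126)	down
MAP2K2	Selumetinib (AZD6244)	down
MAPK1	ERKi (ERK inhibitor)	down
MAPK1	ERKi (ERK inhibitor II)	down
MAPK1	Dasatinib (50 nM)	down
PRKACA	Iloprost (5 nM)	up
AURKA	Mitosis (AZD1152)	down
AURKA	Mitosis (MLN8054)	down
AURKB	Mitosis (AZD1152)	down
PLK1	Mitosis (BI2536)	down
PLK1	Mitosis (short Taxol + BI2536)	down
PLK1	BI 4834 (on Mitosis Nocodazole)	down
PLK1	PLK1 Inhibitor (G2r - BI2536)	down
MTOR	mTORi (KU-0063794)	down
MTOR	mTORi (Torin-1)	down
MTOR	Rapamycin	down
MTOR	Starved	down
MTOR	Torin1	down
PIK3CA	PIK3CA activation (H1047R)	up
PIK3CA	PIK3CA activation (E545K)	up
RPS6KB1	P70S6K1i (DG2)	down
RPS6KB1	P70S6K1i (PF-4708671)	down
ROCK1	ROCKi (H-1152)	down
ROCK1	ROCKi (Y-27632)	down
PDGFRB	Sorafinib	down
PDGFRA	Sorafinib	down
BRAF	Sorafinib	down
RAF1	Sorafinib	down
FLT1	Sorafinib	down
FLT3	Sorafinib	down
FLT4	Sorafinib	down
PDGFRA	Quizartinib	down
FLT3	Quizartinib	down
LRKK2	LRRK2-IN-1 (Endogenous LRRK2)	down
LRKK2	LRRK2-IN-1 (LRRK2 overexpression)	down
FLT4	VEGF	up
FLT1	VEGF	up
BRAF	Vemurafenib (PLX4032)	down
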