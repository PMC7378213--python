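TP53	TP53
FLT3	FLT3
KIT	KIT
DNMT3A	DNMT3A
IDH1	IDH1
IDH2	IDH2
RUNX1	RUNX1
NPM1	NPM1
TYMS	TYMS
COX8A	COX8A
SLC29A1	SLC29A1
CEBPA	CEBPA
TET2	TET2
ASXL1	ASXL1
WT1	WT1
KRAS	KRAS
NRAS	NRAS
BRAF	BRAF
EGFR	EGFR
ERBB2	ERBB2
BRCA1	BRCA1
BRCA2	BRCA2
PALB2	PALB2
ESR1	ESR1
PIK3CA	PIK3CA
PTEN	PTEN
AKT1	AKT1
CDH1	CDH1
CHEK2	CHEK2
ATM	ATM
AR	AR
KLK3	KLK3
RNASEL	RNASEL
SPOP	SPOP
HOXB13	HOXB13
MYC	MYC
RB1	RB1
APC	APC
MLH1	MLH1
MSH2	MSH2
VHL	VHL
RET	RET
ALK	ALK
ROS1	ROS1
MET	MET
JAK2	JAK2
ABL1	ABL1
NOTCH1	NOTCH1
SF3B1	SF3B1
GATA2	GATA2
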