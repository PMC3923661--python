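#target=TERT
#nodes=AR,JUN,TP53,SP1,E2F1,MYCN,MXD1,RELA,MYC,FOS,HIF1A,SP3,STAT3,NR2F2,TERT
source	target	sign
AR	TP53	-1
AR	TERT	-1
JUN	JUN	+1
JUN	TERT	-1
TP53	MYC	-1
TP53	E2F1	-1
TP53	SP1	-1
TP53	FOS	-1
TP53	TERT	-1
SP1	JUN	+1
SP1	MYCN	+1
SP1	FOS	+1
SP1	TERT	+1
E2F1	E2F1	+1
E2F1	HIF1A	+1
E2F1	AR	-1
E2F1	MYC	+1
E2F1	TERT	-1
MYCN	TP53	+1
MYCN	E2F1	+1
MYCN	TERT	+1
MXD1	TERT	-1
RELA	JUN	+1
RELA	TP53	+1
RELA	FOS	+1
RELA	TERT	+1
MYC	JUN	-1
MYC	TERT	+1
HIF1A	TERT	+1
SP3	SP1	-1
SP3	TERT	-1
STAT3	JUN	+1
STAT3	FOS	+1
STAT3	MXD1	+1
NR2F2	TERT	-1
JUN	AR	+1
JUN	FOS	+1
TP53	NR2F2	-1
TP53	STAT3	-1
E2F1	TP53	-1
E2F1	SP1	-1
E2F1	SP3	+1
MYCN	MYCN	+1
HIF1A	MXD1	-1
STAT3	TP53	+1
NR2F2	E2F1	-1
FOS	TERT	+1
AR	RELA	-1
AR	HIF1A	-1
JUN	STAT3	+1
TP53	JUN	-1
TP53	MXD1	-1
TP53	RELA	-1
TP53	HIF1A	-1
TP53	SP3	-1
SP1	STAT3	+1
E2F1	MXD1	-1
E2F1	RELA	-1
E2F1	JUN	-1
E2F1	STAT3	-1
MYCN	AR	+1
MYCN	JUN	+1
MYCN	SP1	+1
MYCN	MYC	+1
MYCN	HIF1A	+1
MYCN	FOS	+1
MYCN	SP3	+1
MYCN	STAT3	+1
MXD1	MYCN	+1
RELA	NR2F2	+1
MYC	SP1	-1
MYC	MXD1	-1
MYC	RELA	-1
MYC	FOS	-1
MYC	SP3	-1
MYC	NR2F2	-1
HIF1A	MYC	+1
HIF1A	NR2F2	+1
HIF1A	AR	+1
FOS	AR	+1
FOS	MXD1	+1
FOS	RELA	+1
FOS	STAT3	+1
FOS	NR2F2	+1
SP3	NR2F2	-1
STAT3	AR	+1
STAT3	RELA	+1
NR2F2	JUN	-1
NR2F2	NR2F2	-1
STAT3	TERT	+1
RELA	STAT3	+1
TP53	MYCN	-1
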