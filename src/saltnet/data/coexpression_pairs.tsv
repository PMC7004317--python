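gene_1	gene_2	r_obese	r_normal
WNK1	CALM1	0.9439	0.5472
ENPEP	C1QBP	0.9417	-0.2225
ENPEP	PCNA	0.9240	-0.2255
ENPEP	MBNL1	0.9156	0.5669
WNK1	CEP104	0.9145	0.2931
ENPEP	XRCC5	0.9110	-0.1939
CYP3A5	HIST1H2BD	0.9040	0.2237
CYP3A5	C3	0.9015	0.6306
CLCNKB	MAS1	0.9001	0.4543
ENPEP	CAST	0.8897	0.3039
CYP3A5	CFH	0.8787	0.5056
CYP3A5	KRT18	0.8696	0.1807
ENPEP	SNX1	0.8659	0.3880
SLC24A3	RTN4	0.8625	0.7491
ENPEP	MID2	0.8569	0.3283
ENPEP	GNAQ	0.8480	0.5793
WNK1	SPTBN1	0.8469	0.3412
SLC24A3	LNPEP	0.8434	0.6549
WNK1	OPTN	0.8420	0.3940
ENPEP	MAP1LC3B	0.8410	0.4832
WNK1	ST13	0.8377	0.4385
WNK1	LIN7C	0.8362	0.2726
WNK1	DLG1	0.8352	0.3487
ENPEP	PPP2CB	0.8341	0.2886
WNK1	BCL2L2	0.8338	0.7179
ENPEP	AGFG1	0.8333	0.2477
SLC24A3	ADM	0.8324	0.5586
ENPEP	MLH1	0.8309	0.2835
WNK1	RNF11	0.8297	0.3692
CTSA	POLDIP2	0.8285	0.1705
CTSA	DERL1	0.8279	0.1225
ENPEP	YAP1	0.8258	0.1928
WNK1	SMAD7	0.8237	0.2519
ENPEP	KCMF1	0.8225	-0.0395
WNK1	YWHAG	0.8217	0.5680
SCNN1G	GNB3	0.8216	0.5586
ENPEP	PRKAR1A	0.8215	0.7386
CYP3A5	PRKCZ	0.8213	0.1144
ENPEP	RDH11	0.8198	-0.0770
WNK1	COL4A1	0.8191	0.3485
CTSA	DHX30	0.8171	0.2648
WNK1	EBF1	0.8168	0.3779
ENPEP	ATG5	0.8151	0.2386
ENPEP	AGTR1	0.8149	0.4997
ENPEP	EPS15	0.8134	0.5767
WNK1	AGTR1	0.8124	0.4890
WNK1	MBNL1	0.8123	0.5277
WNK1	RTN4	0.8121	0.4261
ENPEP	PDIA6	0.8111	-0.2465
CYP3A5	CHEK2	0.8098	0.0108
WNK1	PPP2CB	0.8077	0.4375
WNK1	SCARB2	0.8059	0.1818
THOP1	CSK	0.8058	0.3290
WNK1	MID2	0.8047	0.3940
ENPEP	TANK	0.8027	0.3945
WNK1	GTF2I	0.8001	0.1125
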