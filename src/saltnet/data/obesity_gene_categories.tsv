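gene	category
ACE	salt_sensitivity
ACE2	salt_sensitivity
ADD1	salt_sensitivity
ADRB2	salt_sensitivity
AGT	salt_sensitivity
AGTR1	salt_sensitivity
AGTR2	salt_sensitivity
ANPEP	salt_sensitivity
ATP6AP2	salt_sensitivity
CMA1	salt_sensitivity
CYP17A1	salt_sensitivity
GNB3	salt_sensitivity
GRK4	salt_sensitivity
KLK1	salt_sensitivity
LNPEP	salt_sensitivity
MAS1	salt_sensitivity
MME	salt_sensitivity
NEDD4L	salt_sensitivity
PRCP	salt_sensitivity
PRKG1	salt_sensitivity
REN	salt_sensitivity
SGK1	salt_sensitivity
TH	salt_sensitivity
EGR1	hub
JUND	hub
FOS	hub
APP	hub
STAT3	hub
JUN	hub
STAT1	hub
ATF3	hub
SIRT7	hub
FOXM1	hub
TBL1XR1	hub
BAG3	hub
HSPB1	hub
CEBPD	hub
HNRNPA1	hub
VCAM1	hub
CALM1	bottleneck
PCNA	bottleneck
JUNB	bottleneck
CRK	bottleneck
SHC1	bottleneck
GAPDH	bottleneck
WWOX	bottleneck
ITCH	bottleneck
HSPA1A	bottleneck
CRY2	bottleneck
NFKB1	bottleneck
MLH1	bottleneck
PKM	bottleneck
HSPD1	bottleneck
PTPN11	bottleneck
MAP1LC3B	bottleneck
TUFM	bottleneck
APC	bottleneck
SNRNP200	bottleneck
CDK5	bottleneck
CALR	bottleneck
HLA-C	bottleneck
GTF2I	bottleneck
PRKAR1A	bottleneck
BCL2L1	bottleneck
TNF	bottleneck
IGF1R	bottleneck
ZFP36	bottleneck
NR4A1	bottleneck
TANK	bottleneck
SOD2	bottleneck
KRT18	bottleneck
JAK3	bottleneck
SMARCA2	bottleneck
NUP62	bottleneck
PRKCZ	bottleneck
DNMT1	bottleneck
ATG5	bottleneck
DNAJB1	bottleneck
STAT5B	bottleneck
LEPR	bottleneck
VDR	bottleneck
PIK3CA	bottleneck
PPIA	bottleneck
FOXO3	bottleneck
MYD88	bottleneck
CAST	bottleneck
DDAH2	bottleneck
VEGFA	bottleneck
SOCS3	bottleneck
PINK1	bottleneck
COL1A1	bottleneck
THBS1	bottleneck
ACAT2	bottleneck
THRA	bottleneck
SNAP29	bottleneck
VTI1B	bottleneck
PER1	bottleneck
TPI1	bottleneck
RGS2	bottleneck
BMPR1A	bottleneck
NPHP1	bottleneck
FTL	bottleneck
GTF2H1	bottleneck
APOE	bottleneck
CYCS	bottleneck
ABCA1	bottleneck
CSK	bottleneck
TIMM44	bottleneck
GNAQ	bottleneck
C3	bottleneck
POLDIP2	bottleneck
SLU7	bottleneck
ST13	bottleneck
COL4A1	bottleneck
LAMA1	bottleneck
SDC2	bottleneck
IGF1	bottleneck
BGN	bottleneck
CFH	bottleneck
ADM	bottleneck
WASF1	bottleneck
HGF	bottleneck
C1QTNF6	bottleneck
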