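gene	role_in_obesity
ACE2	Reported
ADD1	Reported
ADRB2	Reported
AGT	Reported
AGTR1	Reported
ANPEP	Reported
ATP6AP2	Reported
CYP17A1	Reported
GNB3	Reported
LNPEP	Reported
MAS1	Reported
MME	Reported
NEDD4L	Reported
PRKG1	Reported
SGK1	Reported
CLCNKB	Unreported
CTSA	Unreported
CYP3A5	Unreported
ENPEP	Unreported
SCNN1G	Unreported
SLC24A3	Unreported
THOP1	Unreported
WNK1	Unreported
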