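gene	bc	dc
ADD1	0.001	17
ADRB2	0.00305	62
AGT	0.00105	16
AGTR1	0.00097	9
ATP6AP2	0.00102	20
CYP11B2	0.00084	4
GNAI2	0.00283	31
GNB3	0.00041	10
MME	0.00047	22
NEDD4L	0.00216	46
PRCP	0.00052	9
PREP	0.00048	11
SCNN1A	0.00043	12
SGK1	0.00149	32
WNK1	0.00096	33
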