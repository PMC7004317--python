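gene	bc	dc
PHF8	0.260	882
EGR1	0.091	504
JUND	0.089	462
FOS	0.076	438
CHD2	0.051	371
APP	0.070	366
IRF1	0.036	306
STAT3	0.049	295
TEAD4	0.042	292
RELA	0.039	278
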