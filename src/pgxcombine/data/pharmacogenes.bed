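7	87133178	87342639	ABCB1
2	29415639	30144477	ALK
10	45869623	45941567	ALOX5
11	23522551	23660224	BCR
17	41196311	41277500	BRCA
19	19929262	19957498	COMT
19	41349442	41356352	CYP2A6
19	15988833	16008884	CYP4F2
X	31137344	33229673	DMD
7	55086724	55275031	EGFR
6	152128813	152424408	ESR1
X	153759605	153775233	G6PD
6	31237742	31324989	HLA-B
6	32489682	32557613	HLA-DRB1
4	55524094	55606881	KIT
X	38211735	38280703	OTC
4	55095263	55164412	PDGFRA
19	38924339	39078204	RYR1
5	70220767	70248842	SMN2
16	28616907	28620649	SULT1A1
6	18128544	18155374	TPMT
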