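# Star-allele definition table: one row per defining SNV.
# *1 (all-reference haplotype) is implicit. alt = defining alternative allele.
gene	allele	rsid	alt
CYP4F2	*2	rs3093105	G
CYP4F2	*3	rs2108622	T
TPMT	*3C	rs1142345	G
CYP2C19	*2	rs4244285	A
CYP2C19	*3	rs4986893	A
CYP3A5	*3	rs776746	G
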