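label	genes	stuck_values	role	provenance
BRAF	BRAF	1	oncogene	NM_004333.4 c.1799T>G p.Val600Gly
RAF	RAF	1	oncogene	NM_001654.4(ARAF) c.640T>G p.Ser214Ala
NRAS	NRAS	1	oncogene	NM_002524.4 c.182_183delAAinsGG p.Gln61Arg
RAS	KRAS	1	oncogene	NM_004985.4(KRAS) c.351A>C p.Lys117Asn
AKT	AKT	1	oncogene	NM_005163.2(AKT1) c.235C>A p.Gln79Lys
PI3K	PI3K	1	oncogene	NM_006218.3(PIK3CA) c.3140A>T p.His1047Leu
MEK	MEK	1	oncogene	NM_002755.3(MAP2K1) c.157T>C p.Phe53Leu
CDK4/6	CDKN2A	0	tumor_suppressor	NM_000077.4(CDKN2A) c.148C>T p.Gln50Ter
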