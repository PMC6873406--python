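label	genes	stuck_values	role	provenance
EGFR	EGFR	1	oncogene	NM_005228.4 c.2573T>G p.Leu858Arg
ERBB2	ERBB2	1	oncogene	NM_001005862.2 c.2223_2234dup
EML4-ALK	EML4-ALK	1	oncogene	NM_004304.4(ALK) c.3522C>A p.Phe1174Leu
PTEN	PTEN	0	tumor_suppressor	NM_000314.6 c.697C>T p.Arg233Ter
KRAS	KRAS	1	oncogene	NM_004985.4 c.437C>T p.Ala146Val
BRAF	BRAF	1	oncogene	NM_004333.5 c.1794_1796dup
PIK3CA	PI3K	1	oncogene	NM_006218.3 c.3140A>G p.His1047Arg
AKT	AKT	1	oncogene	NM_005163.2 c.49G>A p.Glu17Lys
MEK	MEK	1	oncogene	NM_002755.3 c.167A>C p.Gln56Pro
EML4-ALK+p16	EML4-ALK;p16	1;0	compound	chr2:29446394..42552694 inversion
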