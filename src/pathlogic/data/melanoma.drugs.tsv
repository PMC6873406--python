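name	targets	unmapped
Omacetaxine	CCND1	
Ribociclib	CDK4/6	
Dabrafenib	BRAF;RAF	
Trametinib	BRAF;MEK	
Everolimus	AKT	
BKM120	PI3K	
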