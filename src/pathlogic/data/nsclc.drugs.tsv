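name	targets	unmapped
Osimertinib	EGFR	
Alectinib	EML4-ALK	
Dabrafenib	BRAF	
Trametinib	BRAF;MEK	
Everolimus	AKT	
BKM120	PI3K	
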