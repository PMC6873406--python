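name	targets	unmapped
mir-124	CDK4/6;AKT;NRAS;RAF;PI3K	
mir-145	CDK4/6;NRAS;BRAF	
mir-155	CDK4/6;KRAS;AKT;PI3K	
mir-497	CDK4/6;AKT;MEK;RAF;PI3K	
let-7a	CDK4/6;KRAS;NRAS;PI3K	
mir-16	CDK4/6;KRAS;AKT;RAF;PI3K	
let-7b	CDK4/6;AKT;NRAS;KRAS;MEK	
mir-143	KRAS;AKT;PI3K;BRAF	
mir-429	CDK4/6;KRAS;RAF	
mir-7	KRAS;AKT;RAF;PI3K;MEK	
mir-302a	CDK4/6;AKT	
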