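name	targets	unmapped
let-7c	CCND1;KRAS	
let-7g	AKT;CCND1	
mir-130b	RASSF1;STAT3/5	
mir-142	CCND1;FORKHEAD;ERK	
mir-15a	AKT;CCND1	
mir-17	PKC;STAT3/5	
mir-18a	CCND1;TGA	
mir-191	BRAF	
mir-193b	CCND1;PKC	
mir-27a	SOS	
mir-27b		PDK1
mir-29a	AKT;CDK4/6	
mir-30e	KRAS;TGA	
mir-330	BAD	
mir-335	FORKHEAD;JAK3	
mir-34a	CDK4/6;MEK	
mir-375	PI3K;PKC	
mir-4778	PKC;STAT3/5	
mir-4789	CCND1;STAT3/5	
mir-497	CDK4/6;GRB2	
mir-20a		(unknown)
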