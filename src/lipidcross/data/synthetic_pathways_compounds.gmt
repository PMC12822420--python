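hsa00564	Glycerophospholipid metabolism	PC	PC O-	PE	PE O-	PI	LPC	LPC O-	LPE	DAG
hsa00600	Sphingolipid metabolism	SM	Cer
hsa00561	Glycerolipid metabolism	TAG	DAG
hsa00100	Steroid biosynthesis	Chol	CE
hsa00565	Ether lipid metabolism	PC O-	PE O-	LPC O-
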