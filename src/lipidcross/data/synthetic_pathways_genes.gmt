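hsa00564	Glycerophospholipid metabolism	PLB1	PLA2G6	PLA2G4B	CHPT1	CEPT1	PCYT1A	PCYT2	GPD1	LPCAT1	LPCAT2	PLD1	PLD2	ETNK1	CHKA
hsa00600	Sphingolipid metabolism	SPTLC1	SPTLC2	CERS2	CERS6	SGMS1	SGMS2	SMPD1	UGCG	ASAH1
hsa00561	Glycerolipid metabolism	DGAT1	DGAT2	LIPE	PNPLA2	MGLL	GPAM	AGPAT2
hsa00100	Steroid biosynthesis	DHCR7	DHCR24	SQLE	LSS	HMGCR	SOAT1
hsa00565	Ether lipid metabolism	AGPS	FAR1	FAR2	PLA2G7	ENPP2
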