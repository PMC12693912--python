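name	iupac	description
ABRE	ACGTG	ABA-responsive element core
DRE_core	RCCGAC	dehydration-responsive element core
MBS	CAACTG	MYB binding site
MYC	CANNTG	MYC recognition site (E-box family)
ARE	AAACCA	anaerobic-responsive element
Wbox	TTGACC	WRKY binding W-box
as1	TGACG	activation sequence-1
Gbox	CACGTG	G-box core
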