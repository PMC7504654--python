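name	category	consensus
CAT-box	meristem_expression	GCCACT
G-box	light_responsive	CACGTG
LTR	low_temperature	CCGAAA
ABRE	ABA_responsive	ACGTG
MBS	MYB_drought	CAACTG
TCA-element	salicylic_acid	CCATCTTTTT
MBSI	MYB_flavonoid	AAAAAACSGTTA
TGA-element	IAA_responsive	AACGAC
CGTCA-motif	MeJA_responsive	CGTCA
GARE-motif	GA_responsive	TCTGTTG
ARE	anaerobic_induction	AAACCA
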