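# Default cis-element dictionary (PlantCARE-style consensi).
# TC-rich repeats, WUN-motif and O2-site have no published consensus in
# this dictionary's sources and are left for user-supplied entries.
name	pattern	functional_class
G-box	CACGTG	light
ABRE	ACGTG	hormone
CGTCA-motif	CGTCA	hormone
TGACG-motif	TGACG	hormone
ERE	ATTTCAAA	hormone
MBS	CAACTG	stress
LTR	CCGAAA	stress
ARE	AAACCA	development
CAT-box	GCCACT	development
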