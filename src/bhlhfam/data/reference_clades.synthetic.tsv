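# synthetic clade-labelled reference set (clade ancestors)
id	clade
ATREF01	1
ATREF02	2
ATREF03	3
ATREF04	4
ATREF05	5
ATREF06	6
ATREF07	7
ATREF08	8
ATREF09	9
ATREF10	10
ATREF11	11
ATREF12	12
ATREF13	13
ATREF14	14
ATREF15	15
ATREF16	16
ATREF17	17
ATREF18	18
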