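# Synthetic stand-in reference interaction edge list between the packaged
# clade reference proteins (undirected; a self pair marks a homodimer).
# Shaped like curated plant bHLH interactomes: one hub with many partners,
# a few pairwise interactions, and one homodimer.
protein_a	protein_b
ATREF03	ATREF01
ATREF03	ATREF06
ATREF03	ATREF13
ATREF03	ATREF14
ATREF03	ATREF17
ATREF06	ATREF06
ATREF08	ATREF11
ATREF10	ATREF12
ATREF14	ATREF15
ATREF15	ATREF11
ATREF17	ATREF18
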