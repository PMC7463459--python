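# Methods

## Scope and data model

The package reimplements a genome-wide bHLH transcription-factor family
survey as a deterministic pipeline over standard formats. Internally all
coordinates are 0-based half-open; conversion to the 1-based inclusive
convention happens only when writing GFF3 or reports. All randomised
operations take an explicit seed; there is no global random state, and a
rerun with identical inputs and configuration is byte-identical.

## Domain model and detection

The bHLH domain is treated as a fixed 55-column block: basic region
(columns 1–17), helix 1 (18–32), loop (33–40), helix 2 (41–55). The
17/15/8/15 partition is what the four-region arithmetic requires — the
classifier's rule positions 16 and 17 only exist if the basic region
has 17 columns, and the loop length (8) is the remainder
55 − 17 − 15 − 15.

Detection uses an ungapped position-specific scoring matrix built from
a packaged seed alignment (`seed_domain_alignment.synthetic.fasta`, a
constructed stand-in: a designed 55-mer consensus with basic-rich basic
region plus 15 rows mutated at 10% per site). Column weights are
`log2(((count + pc·bg) / (n + pc)) / bg)` with uniform background
(bg = 0.05) and pseudocount pc = 1. Every window start is scored;
windows that run past the C-terminus are padded with `-`, and a gap or
unknown residue (X) scores the column minimum. Ties on the best score
break to the leftmost start.

The detection threshold is not hard-coded: it is calibrated per profile
as the 99.9th percentile of best-window scores over 1000 random
500-residue proteins of uniform composition, giving a ~0.1%
false-positive rate per random protein. No insert/delete states are
modelled: the surveyed domain is a fixed-width block and gaps occur only
at protein termini, so a full profile HMM would add complexity without
changing the calls.

## DNA-binding classification

Within the 17-column basic region (positions 1-based):

1. fewer than `basic_cutoff` (default 6) residues from the basic set
   (default {R, K, H}) → non-DNA-binding;
2. otherwise, Glu at 13 and Arg at 16 → E-box binder; refined to G-box
   iff position 9 is His/Lys **and** position 17 is Arg, else
   E-box/non-G-box;
3. otherwise non-E-box binder.

A gap at a rule position fails that position's test. Both the basic set
and the cutoff are configuration-exposed because the source rules name
"basic residues" without enumerating them; {R, K, H} is the standard
definition. The E-box rule tests Arg-16 while the G-box refinement
tests Arg-17; both are applied literally as published, despite the
apparent off-by-one between the two rules. Percentages in summaries are
exact rationals rounded half-up to two decimals; for the published
category counts (61/4/11/22 of 98) this reproduces 62.24%, 4.08%,
11.22%, 77.55% and 22.45%. The published E-box row prints 62.25% for
65/98; the exact ratio is 66.33% and the package reports the exact
value.

## Physical properties

Molecular weight is the sum of Expasy average residue masses plus one
water (18.02 Da); X contributes the mean residue mass. The isoelectric
point solves net charge = 0 by bisection on pH ∈ (0, 14) to
|charge| < 1e-4, with Henderson–Hasselbalch terms for the termini and
D, E, C, Y, H, K, R using Bjellqvist pKa values (the set ProtParam-style
tools use); agreement with other pI implementations is expected to
within a few tenths of a pH unit, not bit-exact, because pKa tables
differ.

## Conservation

Per column of the aligned 55-mers: the majority residue (ties broken
alphabetically), its identity computed with all sequences in the
denominator (gap rows count against identity), and a consensus flag at
identity > 0.5.

## Phylogeny

Distances are p-distances on the 55-column domain alignment with
pairwise deletion of gapped columns — a deliberate design choice over a
full-length progressive MSA: the domain carries the clade signal, and
the package does not attempt to reproduce any specific MSA tool's
topology. Neighbor joining follows Saitou–Nei: minimise
Q(i,j) = (m−2)·d(i,j) − r(i) − r(j), branch lengths from the standard
two-point formulas, ties on Q broken by the smallest (i, j) pair in
current label order, negative branch lengths clamped to zero with a log
message, and the final three lineages joined at a trifurcating root
(the tree is unrooted). On additive inputs this reconstructs the
generating tree exactly. Bootstrap support resamples alignment columns
with replacement (default 1000 replicates; the bundled pipeline
configuration uses 100, which is sufficient to rank edges on the
synthetic families while keeping the end-to-end run interactive) and
reports, per internal edge of the full-data tree, the fraction of
replicate trees containing the same leaf bipartition.

Clade assignment is nearest-labelled-reference by p-distance (ties by
reference order) rather than tree traversal: it is deterministic,
independently testable, and the tree remains available for
visualisation. The packaged reference set is a constructed stand-in
(`reference_clades.synthetic.fasta`): 18 clade ancestors derived from
the profile consensus (see below), not real Arabidopsis sequences.

## Promoter scanning

Promoters are the 2000 bp upstream of the TSS on the coding strand
(reverse-complemented for minus-strand genes), with a truncation flag
when the contig is shorter. Scanning matches IUPAC patterns on both
strands; overlapping occurrences all count (published totals such as
"201 ABRE" imply occurrence counting); a site matched identically on
both strands (palindromic pattern) is reported once, as `+`; an `N` in
the promoter matches nothing, so masked regions cannot inflate counts.
The packaged dictionary holds PlantCARE-style consensi (G-box CACGTG,
ABRE ACGTG, CGTCA/TGACG, ERE ATTTCAAA, MBS CAACTG, LTR CCGAAA, ARE
AAACCA, CAT-box GCCACT); TC-rich repeats, WUN-motif and O2-site have no
published consensus in the dictionary's sources and are deliberately
left to user-supplied entries. Reproducing any specific server's counts
would require that server's exact (unpublished) definitions.

## Gene structure

Exon–intron structure is inferred by exact spliced matching of the CDS
against its genomic sequence — both come from the same assembly, so
mismatch tolerance is out of scope. Among decompositions whose gaps are
all ≥ `min_intron` (default 20 nt; the shortest plausible plant intron
is well above that), the search prefers (1) fewest introns, (2) most
GT..AG-compliant introns, (3) leftmost exon starts. Candidate exon
starts are located by a 12-mer seed, so internal exons shorter than
12 nt are not supported; exon extension is maximal with a 30-nt
boundary backoff, which suffices because shifting an exon/intron
boundary preserves the intron count and GT..AG can survive a shift only
across a sequence repeat longer than the backoff. The fewest-introns
criterion outranks GT..AG compliance so conflicts are visible in the
per-intron splice flags rather than silently resolved.

## Expression and qPCR

Tier bins on FPKM are half-open: [0, 2) not expressed, [2, 10) low,
[10, 50) moderate, [50, ∞) abundant. The lower bound (2) is the
published detection rule and the low band matches published usage
("5 < FPKM < 10" called low); 50 for abundant is inferred from usage
(values near 60 called abundant, near 40 moderate) and
configuration-exposed. Heatmap grouping clusters log2(FPKM + 0.01) rows
(the published transform) with average-linkage Euclidean agglomeration
cut to k groups (default 5, the published group count); group labels
are renumbered by first appearance so the partition is order-stable.
Exact reproduction of any published gene-to-group mapping is not a
contract — clustering heuristics differ and the published groups may
include manual curation.

qPCR: technical replicates are averaged to one CT per (gene, condition,
timepoint, biological replicate); ΔCT = CT_gene − CT_reference per
replicate; ΔΔCT = mean ΔCT(condition) − mean ΔCT(baseline); fold =
2^−ΔΔCT and log2 fold change = −ΔΔCT. The baseline is a required
parameter defaulting to (control, 0 h), since published descriptions of
"control" are ambiguous between the 0-h sample and mock-sprayed plants.
Significance is a two-sided pooled-variance Student's t-test on the
replicate ΔCT values (pooled because the named test with equal n = 3 is
the classical equal-variance form; Welch is available by flag), starred
at p < 0.05 and p < 0.01 on the raw p values. No multiple-testing
correction is applied to the stars, matching raw-p reporting practice;
a Benjamini–Hochberg column is emitted alongside for transparency.

## Interaction projection

Each query maps to its minimum-p-distance reference (ties by reference
order); every reference edge (A, B) induces edges between all queries
mapped to A and all mapped to B, deduplicated, self-edges dropped. A
reference self-loop (homodimer) yields a per-query "potential
homodimer" annotation plus edges between distinct queries sharing that
reference. Domain p-distance stands in for alignment bitscore to keep
the step self-contained and offline; users with their own similarity
scores can supply their own homolog map. The packaged edge list is a
synthetic stand-in shaped like curated plant bHLH interactomes (a hub
with several partners, a few pairwise edges, one homodimer) and names
the packaged reference ids.

## Synthetic data: what it emulates and what it does not

The generators produce every input the pipeline consumes, with the
planted truth recorded next to each artifact:

* **Families** — 98 proteins in 18 clades by default, clade sizes
  mirroring the surveyed family except that the two singleton clades
  borrow one member each from the two nine-member clades (within-clade
  divergence requires ≥ 2 members). Clade ancestors are the profile
  consensus mutated at 30% per site outside the basic region, generated
  from a fixed constant seed so the packaged reference set matches any
  run seed. Members mutate their ancestor at the requested rate
  (default 5%) but never at the four classifier rule positions, and
  substitutions inside the basic region preserve basic/non-basic class,
  so the planted DNA-binding category (default mix 61:4:11:22, the
  surveyed proportions) is exact by construction. Substitutions only —
  no indels, no domain shuffling, no compositional bias in the flanks.
* **Genes** — random exons (50–300 nt) interleaved with GT..AG introns
  of requested lengths. Real intron length distributions, splice-site
  context beyond GT/AG, and alternative isoforms are not emulated.
* **Promoters** — i.i.d. background at a requested GC content with
  planted, non-overlapping motif instances on random strands. The
  background is optionally "cleaned": positions where a cleaned motif
  matches by chance are resampled until scanner counts equal the
  planted truth exactly. Cleaning requires the cleaned motif set to be
  containment-free (planting G-box while cleaning ABRE is rejected:
  ACGTG sits inside CACGTG and cannot be resampled away). Repeat
  structure and nucleosome-scale composition are not emulated, so the
  chance-match rate is analytically boundable.
* **Expression** — FPKM drawn uniformly inside the tier bounds per a
  group pattern (the tier bounds mirror the calling thresholds exactly,
  so zero-noise recovery is exact), with multiplicative log-normal
  noise. The default study pattern has five expressed groups
  (flower-restricted, sparse/low, root-specific, broadly moderate,
  ubiquitous/abundant; 75 genes) plus a 23-gene silent block.
* **qPCR** — CT = per-gene baseline − planted log2 fold change +
  Gaussian noise per measurement, reference gene flat at CT 20.
  Amplification-efficiency variation and plate effects are not
  emulated.

Passing recovery tests on these inputs demonstrates that the
implementations are correct under their stated models; it does not
demonstrate robustness to the real-data features deliberately left out
(assembly errors, domain divergence beyond the block model, repeat-rich
promoters, efficiency-biased qPCR).

## Problem sizes and numerical choices

The bundled checks use the study-scale fixtures: the 98-protein family,
200 genes with 0–11 introns, 100 promoters of 2000 nt, 50–60 qPCR
replicates, and 50 random additive trees of ≤ 10 taxa for NJ
exactness. NJ branch-length agreement is asserted to 1e-9 via
patristic-distance comparison; profile probabilities must sum to 1
within 1e-9; pI bisection converges to |charge| < 1e-4. Degenerate
inputs are defined rather than accidental: an all-gap conservation
column reports identity 0, a constant expression matrix clusters by
merge order (label order), and an absent domain hit is a valid scan
outcome, not an error.

## Known limitations

Real-data reproduction of the published accession-level numbers
(conservation percentages of specific residues, per-gene promoter
counts, FPKM values) requires the original downloads and the exact
external tool versions, which are outside this package's offline scope.
The NJ implementation targets correctness on additive inputs and
deterministic tie-breaks, not agreement with any particular GUI tool's
tie-break order. Gene-structure inference assumes exact CDS/genomic
agreement and internal exons of at least the seed length (12 nt).
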