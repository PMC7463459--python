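"""Seeded generators for every input the pipeline consumes.

Each generator returns both the artifact (sequences, tables) and a
:class:`SyntheticTruth` recording every planted feature, so recovery is a
testable property.  Identical seed and arguments give byte-identical
output; there is no global random state.

Protein families are grown from per-clade ancestor 55-mers derived from
the packaged domain profile consensus, with clade-specific mutations, so
inter-clade distance exceeds intra-clade distance by construction.
Within-member mutations never touch the four classifier rule positions of
the basic region and preserve basic/non-basic residue class there, so the
planted DNA-binding category is exact at any mutation rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .domain import AA, DOMAIN_LEN, REGION_BOUNDS, load_packaged_profile
from .io import IUPAC_DNA, SequenceRecord, reverse_complement

# Fixed so the packaged clade reference set is reproducible regardless of
# the user-facing seed.
_ANCESTOR_SEED = 20_200_817

BASIC_SET = "RKH"
# 0-based domain columns of the basic-region rule positions 9/13/16/17
RULE_COLS = (8, 12, 15, 16)
BASIC_LO, BASIC_HI = 0, 17  # 0-based half-open basic-region columns

DEFAULT_TISSUES = [
    "column", "flower_buds", "lip", "sepal",
    "leaf", "stem", "white_root", "green_root_tip",
]

TIER_BOUNDS = {  # sampling bounds per expression tier (FPKM)
    "not": (0.0, 2.0),
    "low": (2.0, 10.0),
    "moderate": (10.0, 50.0),
    "abundant": (50.0, 300.0),
}

_DNA = np.array(list("ACGT"))
_AA_ARR = np.array(list(AA))


@dataclass
class SyntheticTruth:
    """Ground truth for every planted feature of one generator call."""

    seed: int
    planted_domains: dict[str, dict] = field(default_factory=dict)
    planted_clades: dict[str, str] = field(default_factory=dict)
    planted_introns: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    planted_exons: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    planted_motifs: dict[str, list[dict]] = field(default_factory=dict)
    planted_tiers: dict[tuple[str, str], str] = field(default_factory=dict)
    planted_groups: dict[str, str] = field(default_factory=dict)
    planted_log2fc: dict[tuple[str, str, str], float] = field(default_factory=dict)

    def write_tsv(self, path) -> None:
        """Long-format (section, entity, key, value) dump with a seed header."""
        rows = []
        for pid, d in self.planted_domains.items():
            for k, v in d.items():
                rows.append(("domain", pid, k, v))
        for pid, c in self.planted_clades.items():
            rows.append(("clade", pid, "clade", c))
        for gid, ivs in self.planted_introns.items():
            for i, (s, e) in enumerate(ivs):
                rows.append(("intron", gid, f"intron{i}", f"{s}-{e}"))
        for pid, hits in self.planted_motifs.items():
            for h in hits:
                rows.append(("motif", pid, h["motif"], f"{h['position']}{h['strand']}"))
        for (g, t), tier in self.planted_tiers.items():
            rows.append(("tier", g, t, tier))
        for g, grp in self.planted_groups.items():
            rows.append(("group", g, "group", grp))
        for (g, c, tp), fc in self.planted_log2fc.items():
            rows.append(("log2fc", g, f"{c}:{tp}", fc))
        with open(path, "w") as fh:
            fh.write(f"# seed={self.seed}\n")
            pd.DataFrame(rows, columns=["section", "entity", "key", "value"]).to_csv(
                fh, sep="\t", index=False
            )


# ---------------------------------------------------------------------------
# Protein families with planted domains
# ---------------------------------------------------------------------------

def clade_ancestors(n_clades: int, divergence: float = 0.3) -> list[str]:
    """Deterministic per-clade ancestor 55-mers.

    Each ancestor is the packaged profile consensus mutated at
    ``divergence`` per site outside the basic region; the basic region is
    kept intact so every ancestor is a G-box binder.  The RNG seed is a
    fixed constant, making ancestors (and the packaged clade reference
    set built from them) independent of any run seed.
    """
    consensus = load_packaged_profile().consensus
    rng = np.random.default_rng(_ANCESTOR_SEED)
    out = []
    for _ in range(n_clades):
        row = list(consensus)
        for j in range(BASIC_HI, DOMAIN_LEN):
            if rng.random() < divergence:
                row[j] = rng.choice([a for a in AA if a != row[j]])
        out.append("".join(row))
    return out


def _apply_category(domain: list[str], category: str, rng: np.random.Generator) -> None:
    """Edit basic-region residues in place to force a DNA-binding category."""
    if category == "G_box":
        if domain[8] not in "HK":
            domain[8] = "H"
        domain[12], domain[15], domain[16] = "E", "R", "R"
    elif category == "E_box_non_G_box":
        domain[12], domain[15] = "E", "R"
        domain[8] = "S"  # not His/Lys -> fails the G-box refinement
        domain[16] = "R"
    elif category == "non_E_box":
        domain[12] = "A"  # position 13 is not Glu
    elif category == "non_DNA_binding":
        # thin the basic region to 3 basic residues (< 6 cutoff)
        basic_pos = [j for j in range(BASIC_LO, BASIC_HI) if domain[j] in BASIC_SET]
        for j in basic_pos[3:]:
            domain[j] = rng.choice(["S", "A", "N", "Q"])
    else:
        raise ValueError(f"unknown binding category {category!r}")


def _mutate_member(domain: list[str], rate: float, rng: np.random.Generator) -> None:
    """Point mutations that leave rule positions and basic counts intact."""
    for j in range(DOMAIN_LEN):
        if j in RULE_COLS or rng.random() >= rate:
            continue
        if BASIC_LO <= j < BASIC_HI:
            pool = BASIC_SET if domain[j] in BASIC_SET else "ASNQGTVDMLFP"
            choices = [a for a in pool if a != domain[j]]
        else:
            choices = [a for a in AA if a != domain[j]]
        if choices:
            domain[j] = rng.choice(choices)


def default_clade_spec() -> dict[str, int]:
    """18-clade composition for the standard 98-member synthetic family.

    Mirrors the surveyed family's clade sizes, except that the two
    singleton clades borrow one member each from the two largest
    nine-member clades (the generator requires >= 2 members per clade so
    that within-clade divergence is defined)."""
    sizes = [8, 3, 5, 4, 3, 8, 3, 4, 3, 8, 3, 4, 4, 14, 14, 2, 6, 2]
    return {str(i): s for i, s in enumerate(sizes, start=1)}


def default_categories(n: int) -> list[str]:
    """Category mix mirroring the surveyed family's proportions
    (G-box 61 : E-box-non-G-box 4 : non-E-box 11 : non-binder 22 of 98),
    apportioned by largest remainder."""
    weights = {"G_box": 61, "E_box_non_G_box": 4, "non_E_box": 11, "non_DNA_binding": 22}
    total = sum(weights.values())
    quotas = {k: n * w / total for k, w in weights.items()}
    counts = {k: int(q) for k, q in quotas.items()}
    short = n - sum(counts.values())
    for k in sorted(quotas, key=lambda k: quotas[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    out = []
    for k in ("G_box", "E_box_non_G_box", "non_E_box", "non_DNA_binding"):
        out.extend([k] * counts[k])
    return out


def make_family(
    n_proteins: int,
    clade_spec: Mapping[str, int],
    mutation_rate: float = 0.05,
    seed: int = 0,
    categories: Sequence[str] | None = None,
    flank_range: tuple[int, int] = (20, 80),
) -> tuple[list[SequenceRecord], SyntheticTruth]:
    """Generate a protein family with one planted 55-residue domain each.

    ``clade_spec`` maps clade label to member count (sizes must sum to
    ``n_proteins``); ``categories`` lists the intended DNA-binding call per
    protein (default: the family-survey mix from :func:`default_categories`).
    """
    if not 0 <= mutation_rate <= 0.3:
        raise ValueError("mutation_rate must be in [0, 0.3]")
    if sum(clade_spec.values()) != n_proteins:
        raise ValueError("clade sizes must sum to n_proteins")
    if any(size < 2 for size in clade_spec.values()):
        raise ValueError("every clade needs at least 2 members")
    if categories is None:
        categories = default_categories(n_proteins)
    if len(categories) != n_proteins:
        raise ValueError("categories must have one entry per protein")

    rng = np.random.default_rng(seed)
    ancestors = dict(zip(clade_spec, clade_ancestors(len(clade_spec))))
    truth = SyntheticTruth(seed=seed)
    records = []
    i = 0
    for clade, size in clade_spec.items():
        for _ in range(size):
            pid = f"SYN{i + 1:03d}"
            domain = list(ancestors[clade])
            _mutate_member(domain, mutation_rate, rng)
            _apply_category(domain, categories[i], rng)
            dom = "".join(domain)
            left = int(rng.integers(flank_range[0], flank_range[1] + 1))
            right = int(rng.integers(flank_range[0], flank_range[1] + 1))
            seq = (
                "".join(rng.choice(_AA_ARR, size=left))
                + dom
                + "".join(rng.choice(_AA_ARR, size=right))
            )
            records.append(SequenceRecord(pid, seq, f"clade={clade}", "protein"))
            truth.planted_domains[pid] = {
                "offset": left,
                "domain": dom,
                "basic_region": dom[BASIC_LO:BASIC_HI],
                "category": categories[i],
            }
            truth.planted_clades[pid] = clade
            i += 1
    return records, truth


# ---------------------------------------------------------------------------
# Genes with GT..AG introns
# ---------------------------------------------------------------------------

def make_gene(
    n_introns: int,
    exon_len_range: tuple[int, int] = (50, 300),
    intron_len_range: tuple[int, int] = (44, 2000),
    seed: int = 0,
    gene_id: str = "SYNG001",
) -> tuple[SequenceRecord, SequenceRecord, SyntheticTruth]:
    """Genomic/CDS pair: interleaved random exons and GT..AG introns."""
    if n_introns < 0:
        raise ValueError("n_introns must be >= 0")
    if exon_len_range[0] > exon_len_range[1] or intron_len_range[0] > intron_len_range[1]:
        raise ValueError("length ranges must be (min, max) with min <= max")
    if intron_len_range[0] < 20:
        raise ValueError("minimum intron length must be >= 20")
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(seed=seed)
    pieces, exons, introns = [], [], []
    pos = 0
    for i in range(n_introns + 1):
        elen = int(rng.integers(exon_len_range[0], exon_len_range[1] + 1))
        exon = "".join(rng.choice(_DNA, size=elen))
        pieces.append(exon)
        exons.append((pos, pos + elen))
        pos += elen
        if i < n_introns:
            ilen = int(rng.integers(intron_len_range[0], intron_len_range[1] + 1))
            intron = "GT" + "".join(rng.choice(_DNA, size=ilen - 4)) + "AG"
            pieces.append(intron)
            introns.append((pos, pos + ilen))
            pos += ilen
    genomic = "".join(pieces)
    cds = "".join(genomic[s:e] for s, e in exons)
    truth.planted_exons[gene_id] = exons
    truth.planted_introns[gene_id] = introns
    return (
        SequenceRecord(gene_id, genomic, "synthetic genomic", "dna"),
        SequenceRecord(gene_id, cds, "synthetic CDS", "dna"),
        truth,
    )


# ---------------------------------------------------------------------------
# Promoters with planted IUPAC motifs
# ---------------------------------------------------------------------------

def _instantiate(pattern: str, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(IUPAC_DNA[c])) for c in pattern)


def make_promoters(
    n: int,
    length: int = 2000,
    plant: Mapping[str, int] | None = None,
    gc: float = 0.4,
    seed: int = 0,
    library: Mapping[str, str] | None = None,
    clean_background: bool = True,
    clean_against: Mapping[str, str] | None = None,
) -> tuple[list[SequenceRecord], SyntheticTruth]:
    """Promoters with i.i.d. background and planted, non-overlapping motifs.

    ``plant`` maps motif name to copies per promoter; ``library`` maps name
    to IUPAC pattern (default: packaged dictionary).  With
    ``clean_background`` the background is resampled wherever a motif from
    ``clean_against`` (default: the planted motifs) matches by chance on
    either strand, so scanner counts for those motifs equal the planted
    truth exactly.  Cleaning requires the cleaned motif set to be free of
    containment collisions (no pattern matching inside another's planted
    site); planting, say, a G-box (CACGTG) while cleaning against ABRE
    (ACGTG) is rejected because the chance match sits inside the planted
    site and cannot be resampled away.
    """
    from .promoter import find_matches, load_motif_library

    plant = dict(plant or {})
    if library is None:
        library = {m.name: m.pattern for m in load_motif_library()}
    missing = set(plant) - set(library)
    if missing:
        raise ValueError(f"planted motifs missing from library: {sorted(missing)}")
    total_footprint = sum(len(library[m]) * k for m, k in plant.items())
    if total_footprint > length // 2:
        raise ValueError("planted motifs do not plausibly fit without overlap")

    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    truth = SyntheticTruth(seed=seed)
    records = []
    for i in range(n):
        pid = f"SYNP{i + 1:03d}"
        seq = list(rng.choice(_DNA, size=length, p=p))
        occupied: list[tuple[int, int]] = []
        planted: list[dict] = []
        for name, count in plant.items():
            pat = library[name]
            m = len(pat)
            for _ in range(count):
                for _attempt in range(10_000):
                    pos = int(rng.integers(0, length - m + 1))
                    if all(pos + m <= s or pos >= e for s, e in occupied):
                        break
                else:
                    raise ValueError("could not place planted motifs without overlap")
                strand = "+" if rng.random() < 0.5 else "-"
                inst = _instantiate(pat, rng)
                site = inst if strand == "+" else reverse_complement(inst)
                seq[pos : pos + m] = list(site)
                occupied.append((pos, pos + m))
                # a palindromic instance reads identically on both strands
                # and is reported once, on +
                if reverse_complement(site) == site:
                    strand = "+"
                planted.append({"motif": name, "position": pos, "strand": strand})
        if clean_background:
            check = dict(clean_against) if clean_against is not None else {
                m: library[m] for m in plant
            }
            planted_keys = {(h["motif"], h["position"]) for h in planted}
            for _round in range(100):
                s = "".join(seq)
                spurious = []
                for name, pat in check.items():
                    for pos, strand in find_matches(s, pat):
                        if (name, pos) not in planted_keys:
                            spurious.append((pos, pos + len(pat)))
                if not spurious:
                    break
                for s0, e0 in spurious:
                    mutable = [
                        j for j in range(s0, e0)
                        if all(j < a or j >= b for a, b in occupied)
                    ]
                    if not mutable:
                        raise ValueError(
                            "cleaned motif set has a containment collision "
                            "with a planted site; choose non-nested motifs"
                        )
                    for j in mutable:
                        seq[j] = rng.choice(_DNA, p=p)
            else:
                raise RuntimeError("background cleaning did not converge")
        records.append(SequenceRecord(pid, "".join(seq), "synthetic promoter", "dna"))
        truth.planted_motifs[pid] = sorted(planted, key=lambda h: h["position"])
    return records, truth


# ---------------------------------------------------------------------------
# Tissue expression matrices
# ---------------------------------------------------------------------------

def make_expression(
    n_genes: int,
    tissues: Sequence[str] | None = None,
    group_spec: Sequence[tuple[str, int, Mapping[str, str]]] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """FPKM matrix with tier-structured groups.

    ``group_spec`` is a list of ``(group_name, size, {tissue: tier})``;
    tissues absent from a pattern default to the ``not`` tier.  Values are
    drawn uniformly inside each tier's bounds, then perturbed
    multiplicatively by ``exp(N(0, noise_sd))`` and clipped at 0.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    tissues = list(tissues or DEFAULT_TISSUES)
    if group_spec is None:
        group_spec = [("ubiquitous", n_genes, {t: "moderate" for t in tissues})]
    if sum(size for _, size, _ in group_spec) != n_genes:
        raise ValueError("group sizes must sum to n_genes")
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(seed=seed)
    rows, index = [], []
    g = 0
    for group, size, pattern in group_spec:
        bad = set(pattern.values()) - set(TIER_BOUNDS)
        if bad:
            raise ValueError(f"unknown tier name(s): {sorted(bad)}")
        for _ in range(size):
            gid = f"SYNE{g + 1:03d}"
            vals = []
            for t in tissues:
                tier = pattern.get(t, "not")
                lo, hi = TIER_BOUNDS[tier]
                v = rng.uniform(lo, hi)
                if noise_sd > 0:
                    v *= float(np.exp(rng.normal(0.0, noise_sd)))
                vals.append(max(v, 0.0))
                truth.planted_tiers[(gid, t)] = tier
            rows.append(vals)
            index.append(gid)
            truth.planted_groups[gid] = group
            g += 1
    matrix = pd.DataFrame(rows, index=index, columns=tissues)
    matrix.index.name = "gene"
    return matrix, truth


# ---------------------------------------------------------------------------
# qPCR CT tables
# ---------------------------------------------------------------------------

def make_qpcr(
    genes: Sequence[str],
    log2fc_spec: Mapping[str, Mapping[tuple[str, str], float]],
    conditions: Sequence[str] = ("control", "MeJA", "ABA"),
    timepoints: Sequence[str] = ("0h", "3h", "6h"),
    baseline: tuple[str, str] = ("control", "0h"),
    ct_noise_sd: float = 0.1,
    n_bio: int = 3,
    n_tech: int = 3,
    seed: int = 0,
    reference_gene: str = "DoActin",
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Long-format CT table with planted log2 fold changes.

    CT for a target gene is ``baseline_ct - log2fc + N(0, ct_noise_sd)``
    per measurement; the reference gene has log2fc 0 everywhere, as the
    relative-quantification model requires.
    """
    if n_bio < 2:
        raise ValueError("need at least 2 biological replicates for a t-test")
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(seed=seed)
    base_ct = {g: float(rng.uniform(22.0, 28.0)) for g in genes}
    base_ct[reference_gene] = 20.0
    rows = []
    for cond in conditions:
        for tp in timepoints:
            for g in list(genes) + [reference_gene]:
                fc = 0.0
                if g != reference_gene and (cond, tp) != baseline:
                    fc = float(log2fc_spec.get(g, {}).get((cond, tp), 0.0))
                if g != reference_gene:
                    truth.planted_log2fc[(g, cond, tp)] = fc
                for b in range(1, n_bio + 1):
                    for t in range(1, n_tech + 1):
                        ct = base_ct[g] - fc
                        if ct_noise_sd > 0:
                            ct += float(rng.normal(0.0, ct_noise_sd))
                        rows.append(
                            {
                                "condition": cond,
                                "timepoint": tp,
                                "gene": g,
                                "bio_rep": b,
                                "tech_rep": t,
                                "ct": ct,
                            }
                        )
    return pd.DataFrame(rows), truth
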