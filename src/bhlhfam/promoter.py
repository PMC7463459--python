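"""Promoter extraction and cis-regulatory element scanning.

Promoters are the 2000 bp upstream of the transcription start site on the
gene's coding strand.  Scanning matches IUPAC patterns on both strands;
overlapping occurrences all count, a site matched by a palindromic
pattern on both strands is reported once (as +), and an ``N`` in the
promoter matches nothing (masked regions do not inflate counts).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import IUPAC_DNA, SequenceRecord, reverse_complement


@dataclass(frozen=True)
class MotifDef:
    """A named cis-element: IUPAC pattern plus broad functional class."""

    name: str
    pattern: str
    functional_class: str  # light / hormone / stress / development

    def __post_init__(self) -> None:
        if len(self.pattern) < 4:
            raise ValueError(f"{self.name}: pattern must be >= 4 nt")
        bad = set(self.pattern) - set(IUPAC_DNA)
        if bad:
            raise ValueError(f"{self.name}: non-IUPAC characters {sorted(bad)}")


@dataclass(frozen=True)
class MotifHit:
    promoter_id: str
    motif: str
    position: int   # 0-based start on the forward (as-stored) promoter
    strand: str     # '+' or '-'


@dataclass(frozen=True)
class PromoterRecord:
    gene_id: str
    sequence: str
    truncated: bool = False


def load_motif_library(path=None) -> list[MotifDef]:
    """Packaged PlantCARE-style consensus dictionary (TSV: name, pattern, class)."""
    if path is None:
        with resources.as_file(resources.files("bhlhfam") / "data" / "motifs.tsv") as p:
            df = pd.read_csv(p, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    return [
        MotifDef(r["name"], r["pattern"], r["functional_class"])
        for _, r in df.iterrows()
    ]


def extract_promoter(
    contig: SequenceRecord, tss: int, strand: str, window: int = 2000
) -> PromoterRecord:
    """Upstream ``window`` nt of the TSS, 5'->3' on the coding strand.

    For a minus-strand gene "upstream" lies downstream in forward
    coordinates and is returned reverse-complemented.  The truncated flag
    is set when the contig end leaves fewer than ``window`` bases.
    """
    if not 0 <= tss <= len(contig):
        raise ValueError(f"tss {tss} outside contig {contig.id}")
    if strand == "+":
        seq = contig.sequence[max(0, tss - window) : tss]
    elif strand == "-":
        seq = reverse_complement(contig.sequence[tss + 1 : tss + 1 + window])
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    return PromoterRecord(contig.id, seq, truncated=len(seq) < window)


def _iupac_regex(pattern: str) -> re.Pattern:
    # N in the *promoter* must match nothing, so character classes never
    # include N (an N in the pattern still matches any real base).
    parts = []
    for code in pattern:
        opts = IUPAC_DNA[code]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return re.compile("(?=(" + "".join(parts) + "))")


def find_matches(sequence: str, pattern: str) -> list[tuple[int, str]]:
    """All (forward-coordinate start, strand) matches of an IUPAC pattern.

    Overlaps included; a palindromic double-strand match at one site is
    reported once as '+'.  Results are sorted by position then strand.
    """
    m = len(pattern)
    fwd = {mm.start() for mm in _iupac_regex(pattern).finditer(sequence)}
    rc = reverse_complement(sequence)
    n = len(sequence)
    rev = {
        n - (mm.start() + m)
        for mm in _iupac_regex(pattern).finditer(rc)
    }
    # a position present on both strands is the same forward interval
    # (palindromic site) and collapses to a single '+' hit
    hits = [(pos, "+") for pos in fwd]
    hits += [(pos, "-") for pos in rev - fwd]
    return sorted(hits)


def scan_motifs(
    promoter: PromoterRecord | SequenceRecord, library: Sequence[MotifDef]
) -> list[MotifHit]:
    """All occurrences of every library motif in one promoter."""
    if not library:
        raise ValueError("empty motif library")
    seq = promoter.sequence
    if not seq:
        raise ValueError("empty promoter")
    pid = getattr(promoter, "gene_id", None) or promoter.id
    hits = []
    for motif in library:
        for pos, strand in find_matches(seq, motif.pattern):
            hits.append(MotifHit(pid, motif.name, pos, strand))
    return hits


def summarize_motifs(
    hits: Iterable[MotifHit], genes: Sequence[str], motifs: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-motif table: genes with >= 1 occurrence, and total occurrences."""
    if not genes:
        raise ValueError("gene list must be non-empty")
    gene_set = set(genes)
    hits = list(hits)
    for h in hits:
        if h.promoter_id not in gene_set:
            raise ValueError(f"hit references unknown gene {h.promoter_id!r}")
    if motifs is None:
        motifs = sorted({h.motif for h in hits})
    rows = []
    for m in motifs:
        mine = [h for h in hits if h.motif == m]
        rows.append(
            {
                "motif": m,
                "genes_with_hit": len({h.promoter_id for h in mine}),
                "total_occurrences": len(mine),
            }
        )
    return pd.DataFrame(rows, columns=["motif", "genes_with_hit", "total_occurrences"])
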