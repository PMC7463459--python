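"""Exon–intron structure inference by exact spliced matching.

The CDS and genomic sequence come from the same assembly, so exons must
match the genomic sequence exactly (no mismatches or indels).  Among all
decompositions of the CDS into genomic substrings separated by gaps of at
least ``min_intron`` nt, the inference prefers (1) fewest introns,
(2) most GT..AG-compliant introns, (3) leftmost exon starts, found by a
memoized search over exact-match candidate segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd

from .io import SequenceRecord

_SEED_LEN = 12  # k-mer used to locate candidate exon starts
_BACKOFF = 30   # boundary backoff searched below the maximal exon extension


@dataclass(frozen=True)
class GeneModel:
    """Exon intervals (0-based half-open) whose concatenation is the CDS."""

    gene_id: str
    exons: tuple[tuple[int, int], ...]
    splice_flags: tuple[bool, ...]  # per intron: begins GT and ends AG

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1


def _occurrences(haystack: str, needle: str, start: int) -> list[int]:
    out = []
    pos = haystack.find(needle, start)
    while pos != -1:
        out.append(pos)
        pos = haystack.find(needle, pos + 1)
    return out


def _extension(cds: str, genomic: str, i: int, j: int) -> int:
    """Length of the exact match between cds[i:] and genomic[j:]."""
    k = 0
    n, m = len(cds), len(genomic)
    while i + k < n and j + k < m and cds[i + k] == genomic[j + k]:
        k += 1
    return k


def infer_structure(
    cds: SequenceRecord, genomic: SequenceRecord, min_intron: int = 20
) -> GeneModel:
    """Infer the exon–intron decomposition of ``cds`` on ``genomic``.

    Raises ``ValueError`` when the CDS is not derivable from the genomic
    sequence under the exact-match model.
    """
    c, g = cds.sequence, genomic.sequence
    if len(c) > len(g):
        raise ValueError(f"{cds.id}: CDS longer than genomic sequence")
    n = len(c)

    # Candidate start positions in the genomic sequence for the exon
    # beginning at CDS offset i: occurrences of the next seed k-mer (or of
    # the whole remainder when it is shorter than the seed).
    def candidates(i: int, jmin: int) -> list[int]:
        seed = c[i : i + _SEED_LEN]
        return _occurrences(g, seed, jmin)

    # best decomposition of cds[i:] with its first exon starting at or
    # after genomic position jmin: minimise (introns, non-GT..AG introns,
    # exon start tuple) lexicographically
    @lru_cache(maxsize=None)
    def solve(i: int, jmin: int):
        best = None
        for j in candidates(i, jmin):
            ext = _extension(c, g, i, j)
            if ext == 0:
                continue
            # final exon: consumes the rest of the CDS
            if ext == n - i:
                cand = (0, 0, ((j, j + n - i),))
                if best is None or cand < best:
                    best = cand
            # Internal exon of length e followed by an intron >= min_intron.
            # If any decomposition starts with an exon at (i, j), one with
            # the *maximal* extension has the same intron count (shifting
            # the boundary right shifts the intron by the same amount), so
            # only a bounded backoff below the maximum is searched — it
            # exists solely to restore GT..AG boundaries where a repeat
            # makes the split ambiguous.
            upper = min(ext, n - i - 1)
            for e in range(upper, max(0, upper - _BACKOFF), -1):
                sub = solve(i + e, j + e + min_intron)
                if sub is None:
                    continue
                introns, bad, exons = sub
                gap_start = j + e
                gap_end = exons[0][0]
                gtag = g[gap_start : gap_start + 2] == "GT" and g[gap_end - 2 : gap_end] == "AG"
                cand = (
                    introns + 1,
                    bad + (0 if gtag else 1),
                    ((j, j + e),) + exons,
                )
                if best is None or cand < best:
                    best = cand
        return best

    result = solve(0, 0)
    solve.cache_clear()
    if result is None:
        raise ValueError(f"{cds.id}: CDS not derivable from genomic sequence")
    _, _, exons = result
    assert "".join(g[s:e] for s, e in exons) == c
    flags = tuple(
        g[e0:e0 + 2] == "GT" and g[s1 - 2 : s1] == "AG"
        for (_, e0), (s1, _) in zip(exons, exons[1:])
    )
    return GeneModel(cds.id, exons, flags)


def intron_stats(models: Sequence[GeneModel]) -> dict:
    """Per-cohort intron summary: count histogram and length extremes."""
    if not models:
        raise ValueError("no gene models")
    counts = [m.n_introns for m in models]
    lengths = [e - s for m in models for s, e in m.introns]
    hist: dict[int, int] = {}
    for k in counts:
        hist[k] = hist.get(k, 0) + 1
    stats = {
        "n_genes": len(models),
        "intron_count_histogram": dict(sorted(hist.items())),
        "per_gene_counts": {m.gene_id: m.n_introns for m in models},
    }
    if lengths:
        stats.update(
            min_intron_length=int(min(lengths)),
            max_intron_length=int(max(lengths)),
            mean_intron_length=float(np.mean(lengths)),
        )
    return stats


def structure_table(models: Sequence[GeneModel]) -> pd.DataFrame:
    """Per-gene TSV-ready summary (exon/intron counts and spans)."""
    rows = []
    for m in models:
        rows.append(
            {
                "gene_id": m.gene_id,
                "n_exons": len(m.exons),
                "n_introns": m.n_introns,
                "all_gt_ag": all(m.splice_flags) if m.splice_flags else True,
                "exons": ";".join(f"{s}-{e}" for s, e in m.exons),
            }
        )
    return pd.DataFrame(rows)
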