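"""Readers/writers for the formats the pipeline touches, plus run configuration.

Internal coordinates are 0-based half-open everywhere; conversion to the
1-based inclusive convention happens only at the GFF3/report boundary.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("bhlhfam")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(levelname)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
# IUPAC nucleotide codes, including ambiguity codes.
DNA_ALPHABET = frozenset("ACGTRYSWKMBDHVN")

IUPAC_DNA = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes supported)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence over a declared alphabet (``protein`` or ``dna``)."""

    id: str
    sequence: str
    description: str = ""
    alphabet: str = "protein"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"{self.id}: sequence must be non-empty")
        allowed = PROTEIN_ALPHABET if self.alphabet == "protein" else DNA_ALPHABET
        for pos, ch in enumerate(self.sequence):
            if ch not in allowed:
                raise ValueError(
                    f"{self.id}: illegal {self.alphabet} character {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class RunConfig:
    """Thresholds, resource paths and the seed governing one pipeline run."""

    seed: int = 0
    out_dir: Path = Path("bhlhfam_out")
    # domain detection / classification
    domain_threshold: float | None = None  # None -> calibrate from the profile
    basic_set: str = "RKH"
    basic_cutoff: int = 6
    # expression tiers (FPKM)
    t_expr: float = 2.0
    t_low: float = 10.0
    t_mod: float = 50.0
    heatmap_k: int = 5
    # phylogeny
    n_bootstrap: int = 100
    # resources (None -> packaged defaults)
    motif_library: Path | None = None
    reference_set: Path | None = None
    reference_edges: Path | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("out_dir", "motif_library", "reference_set", "reference_edges"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        return cls(**raw)

    def with_(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)


def read_fasta(path: str | Path, alphabet: str = "protein") -> list[SequenceRecord]:
    """Read a FASTA file into validated :class:`SequenceRecord` objects.

    Line-wrapped sequences are concatenated, order is preserved, and ids
    must be unique. Protein records carrying ``*`` (stop) have it stripped
    with a warning. An empty file is an error ("no records").
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if alphabet == "protein" and "*" in seq:
            logger.warning("%s: stripping %d stop character(s)", rec.id, seq.count("*"))
            seq = seq.replace("*", "")
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(SequenceRecord(rec.id, seq, desc, alphabet))
    if not records:
        raise ValueError(f"no records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description) for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def write_tsv(rows: Sequence[dict], path: str | Path, header_comment: str | None = None) -> None:
    """Write a list of dict rows as a TSV with a header row.

    ``header_comment`` (e.g. ``seed=42``) is emitted as a leading ``#`` line
    so every output records the run provenance.
    """
    import pandas as pd

    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def write_gff3(models: Sequence, path: str | Path, source: str = "bhlhfam") -> None:
    """Write gene models (0-based half-open exons) as GFF3 (1-based inclusive).

    Emits one ``gene`` row spanning the model plus one ``exon`` row per exon,
    exons sorted by start.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            exons = sorted(m.exons)
            gstart, gend = exons[0][0], exons[-1][1]
            strand = getattr(m, "strand", "+")
            fh.write(
                f"{m.gene_id}\t{source}\tgene\t{gstart + 1}\t{gend}\t.\t{strand}\t.\tID={m.gene_id}\n"
            )
            for i, (s, e) in enumerate(exons, 1):
                fh.write(
                    f"{m.gene_id}\t{source}\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                    f"ID={m.gene_id}.exon{i};Parent={m.gene_id}\n"
                )


def read_gff3_exons(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Parse exon intervals back to 0-based half-open, keyed by gene id."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9 or cols[2] != "exon":
                continue
            gene = cols[0]
            out.setdefault(gene, []).append((int(cols[3]) - 1, int(cols[4])))
    for exons in out.values():
        exons.sort()
    return out


def write_newick(newick: str, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(newick.rstrip() + "\n")
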