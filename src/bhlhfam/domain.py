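"""bHLH domain detection, partitioning, conservation and DNA-binding rules.

The domain is modelled as a fixed 55-column block: a 17-residue basic
region, two 15-residue helices and an 8-residue loop between them
(17 + 15 + 8 + 15 = 55).  Detection uses an ungapped log-odds profile
(PSSM) scan; windows truncated at a protein terminus are padded with
``-`` and gap columns score the column minimum.

DNA-binding type is predicted from the basic region alone:

* fewer than six basic residues (R/K/H by default) -> non-DNA-binding;
* basic-region position 13 = Glu and position 16 = Arg -> E-box binder,
  refined to a G-box binder iff position 9 is His/Lys and position 17 is
  Arg; otherwise an E-box (non-G-box) binder;
* anything else -> non-E-box binder.

Positions are 1-based within the 17-column basic region; a gap at a rule
position fails that position's test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .io import SequenceRecord, logger

AA = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA)}

# 1-based inclusive column bounds of the four structural regions.
REGION_BOUNDS = {"basic": (1, 17), "helix1": (18, 32), "loop": (33, 40), "helix2": (41, 55)}
DOMAIN_LEN = 55

BINDING_CATEGORIES = ("non_DNA_binding", "G_box", "E_box_non_G_box", "non_E_box")


# ---------------------------------------------------------------------------
# Profile
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DomainProfile:
    """55-column log-odds profile with its consensus and region partition."""

    weights: np.ndarray          # (55, 20) log2 odds, bits
    probs: np.ndarray            # (55, 20) smoothed per-column probabilities
    background: np.ndarray       # (20,)
    consensus: str
    pseudocount: float

    def __post_init__(self) -> None:
        assert self.weights.shape == (DOMAIN_LEN, len(AA))
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("per-column probabilities must sum to 1")

    @property
    def min_weights(self) -> np.ndarray:
        """Per-column minimum weight; the score a gap column receives."""
        return self.weights.min(axis=1)


def build_profile(
    rows: list[str], pseudocount: float = 1.0, background: np.ndarray | None = None
) -> DomainProfile:
    """Build a log-odds profile from a gapless 55-column protein alignment.

    Column weight for residue a:
    ``log2(((count_a + pseudocount * bg_a) / (n + pseudocount)) / bg_a)``.
    Consensus is the per-column majority residue, ties broken alphabetically.
    """
    if not rows:
        raise ValueError("empty seed alignment")
    if any(len(r) != DOMAIN_LEN for r in rows):
        raise ValueError("seed alignment rows must all be 55 columns")
    if background is None:
        background = np.full(len(AA), 1.0 / len(AA))
    counts = np.zeros((DOMAIN_LEN, len(AA)))
    for row in rows:
        for j, ch in enumerate(row):
            if ch not in AA_INDEX:
                raise ValueError(f"non-amino-acid character {ch!r} in seed alignment")
            counts[j, AA_INDEX[ch]] += 1
    n = len(rows)
    probs = (counts + pseudocount * background) / (n + pseudocount)
    weights = np.log2(probs / background)
    consensus = "".join(
        AA[min(np.flatnonzero(col == col.max()))] for col in counts
    )
    return DomainProfile(weights, probs, background, consensus, pseudocount)


def load_packaged_profile(pseudocount: float = 1.0) -> DomainProfile:
    """Profile built from the packaged synthetic seed alignment."""
    from .io import read_fasta

    with resources.as_file(
        resources.files("bhlhfam") / "data" / "seed_domain_alignment.synthetic.fasta"
    ) as p:
        rows = [r.sequence for r in read_fasta(p, "protein")]
    return build_profile(rows, pseudocount=pseudocount)


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DomainHit:
    """Best 55-column domain window of one protein."""

    protein_id: str
    start: int          # 0-based offset in the protein
    aligned55: str      # 55 characters, '-' padding at a terminus
    score: float        # bits

    def __post_init__(self) -> None:
        assert len(self.aligned55) == DOMAIN_LEN

    @property
    def regions(self) -> dict[str, str]:
        return partition_regions(self)


def _window_scores(seq: str, profile: DomainProfile) -> np.ndarray:
    """Score of every 55-column window starting at 0..len(seq)-1.

    Windows running past the C-terminus are padded with gaps, which score
    each column's minimum weight.
    """
    n = len(seq)
    idx = np.array([AA_INDEX.get(c, -1) for c in seq])
    # per-position per-column weight lookup; unknown residues (X) score
    # the column minimum, like a gap
    minw = profile.min_weights
    scores = np.zeros(n)
    # suffix sums of min-weights for terminal padding
    pad = np.concatenate([np.cumsum(minw[::-1])[::-1], [0.0]])
    for j in range(DOMAIN_LEN):
        col = profile.weights[j]
        pos = np.arange(n) + j
        valid = pos < n
        contrib = np.full(n, 0.0)
        vi = idx[pos[valid]]
        w = np.where(vi >= 0, col[np.clip(vi, 0, None)], minw[j])
        contrib[valid] = w
        scores += contrib
    # add padding penalty for windows shorter than 55
    overhang = np.clip(np.arange(n) + DOMAIN_LEN - n, 0, DOMAIN_LEN)
    scores += np.where(overhang > 0, pad[DOMAIN_LEN - overhang], 0.0)
    return scores


def scan_domain(
    protein: SequenceRecord, profile: DomainProfile, threshold: float
) -> DomainHit | None:
    """Best-scoring ungapped 55-residue window, or None below threshold.

    Ties are broken by the leftmost start.
    """
    if len(protein) < 20:
        raise ValueError(f"{protein.id}: protein shorter than 20 residues")
    scores = _window_scores(protein.sequence, profile)
    best = int(np.argmax(scores))  # argmax returns the first (leftmost) maximum
    if scores[best] < threshold:
        return None
    window = protein.sequence[best : best + DOMAIN_LEN]
    window = window + "-" * (DOMAIN_LEN - len(window))
    return DomainHit(protein.id, best, window, float(scores[best]))


def calibrate_threshold(
    profile: DomainProfile,
    n_proteins: int = 1000,
    length: int = 500,
    quantile: float = 0.999,
    seed: int = 0,
) -> float:
    """Detection threshold: the ``quantile`` of best-window scores over
    random i.i.d. proteins (uniform residue composition).

    At the default 99.9th percentile a random protein exceeds the threshold
    in roughly 0.1% of cases.
    """
    rng = np.random.default_rng(seed)
    best = np.empty(n_proteins)
    letters = np.array(list(AA))
    for i in range(n_proteins):
        seq = "".join(rng.choice(letters, size=length))
        best[i] = _window_scores(seq, profile).max()
    return float(np.quantile(best, quantile))


def partition_regions(hit: DomainHit) -> dict[str, str]:
    """Split aligned55 into basic / helix1 / loop / helix2 (17/15/8/15)."""
    out = {}
    for name, (lo, hi) in REGION_BOUNDS.items():
        out[name] = hit.aligned55[lo - 1 : hi]
    return out


# ---------------------------------------------------------------------------
# Conservation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConservationColumn:
    column: int          # 1-based
    region: str
    top_residue: str
    identity: float      # fraction of all sequences (gaps in denominator)
    consensus_flag: bool


def conservation(domains: list[str]) -> list[ConservationColumn]:
    """Per-column identity of the majority residue over aligned 55-mers.

    The denominator is the total number of sequences (gap rows count
    against identity); the consensus flag marks identity > 0.5; ties on
    the top residue are broken alphabetically.
    """
    if not domains:
        raise ValueError("no domains")
    if any(len(d) != DOMAIN_LEN for d in domains):
        raise ValueError("all domains must be 55 columns")
    n = len(domains)
    out = []
    for j in range(DOMAIN_LEN):
        col = [d[j] for d in domains]
        residues = sorted(set(c for c in col if c != "-"))
        if residues:
            best_count = max(col.count(a) for a in residues)
            top = min(a for a in residues if col.count(a) == best_count)
            identity = best_count / n
        else:
            top, identity = "-", 0.0
        region = next(
            name for name, (lo, hi) in REGION_BOUNDS.items() if lo <= j + 1 <= hi
        )
        out.append(ConservationColumn(j + 1, region, top, identity, identity > 0.5))
    return out


# ---------------------------------------------------------------------------
# DNA-binding classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BindingCall:
    protein_id: str
    category: str
    basic_count: int
    rule_residues: dict[int, str]  # residues at basic-region positions 9/13/16/17

    @property
    def is_dna_binding(self) -> bool:
        return self.category != "non_DNA_binding"

    @property
    def is_e_box(self) -> bool:
        return self.category in ("G_box", "E_box_non_G_box")


def classify_binding(
    hit: DomainHit, basic_set: str = "RKH", basic_cutoff: int = 6
) -> BindingCall:
    """Four-way DNA-binding call from the basic region (see module docs)."""
    basic = partition_regions(hit)["basic"]
    basic_count = sum(1 for c in basic if c in basic_set)
    rule = {p: basic[p - 1] for p in (9, 13, 16, 17)}
    if basic_count < basic_cutoff:
        category = "non_DNA_binding"
    elif rule[13] == "E" and rule[16] == "R":
        if rule[9] in "HK" and rule[17] == "R":
            category = "G_box"
        else:
            category = "E_box_non_G_box"
    else:
        category = "non_E_box"
    return BindingCall(hit.protein_id, category, basic_count, rule)


# ---------------------------------------------------------------------------
# Protein physical properties
# ---------------------------------------------------------------------------

# Expasy average residue masses (Da); a peptide adds one water (18.02).
RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.02
MEAN_RESIDUE_MASS = sum(RESIDUE_MASS.values()) / len(RESIDUE_MASS)

# Bjellqvist pKa values as used by Expasy ProtParam-style pI calculations.
PKA_POSITIVE = {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98}
PKA_NEGATIVE = {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}


@dataclass(frozen=True)
class ProteinProperties:
    length: int
    mw: float   # Daltons, average isotopic
    pi: float   # pH units


def molecular_weight(sequence: str) -> float:
    """Sum of average residue masses plus one water; X counts the mean mass."""
    if not sequence:
        raise ValueError("empty sequence")
    return sum(RESIDUE_MASS.get(c, MEAN_RESIDUE_MASS) for c in sequence) + WATER_MASS


def net_charge(sequence: str, ph: float) -> float:
    """Henderson–Hasselbalch net charge at a given pH (termini + DECYHKR)."""
    pos = [PKA_POSITIVE["Nterm"]] + [PKA_POSITIVE[c] for c in sequence if c in "KRH"]
    neg = [PKA_NEGATIVE["Cterm"]] + [PKA_NEGATIVE[c] for c in sequence if c in "DECY"]
    charge = sum(1.0 / (1.0 + 10 ** (ph - pka)) for pka in pos)
    charge -= sum(1.0 / (1.0 + 10 ** (pka - ph)) for pka in neg)
    return charge


def isoelectric_point(sequence: str, tol: float = 1e-4) -> float:
    """pI by bisection on the net-charge curve over pH (0, 14)."""
    if not sequence:
        raise ValueError("empty sequence")
    if any(c not in RESIDUE_MASS for c in sequence):
        raise ValueError("ambiguity codes not allowed for pI")
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = (lo + hi) / 2
        q = net_charge(sequence, mid)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def protein_properties(protein: SequenceRecord) -> ProteinProperties:
    seq = protein.sequence
    return ProteinProperties(len(seq), molecular_weight(seq), isoelectric_point(seq))
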