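"""Domain-anchored distances, neighbor-joining trees, bootstrap, clades.

Distances are p-distances on the 55-column domain alignment (fraction of
mismatched columns with pairwise deletion of gapped columns).  Trees are
built with the Saitou–Nei neighbor-joining agglomeration; ties on the
Q-criterion break deterministically on the smallest (i, j) pair in input
label order, and negative branch lengths are clamped to zero.  Bootstrap
support of an internal edge is the fraction of column-resampled replicate
trees containing the same leaf bipartition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .io import logger


@dataclass
class TreeNode:
    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class PhyloTree:
    """Unrooted tree, represented with a trifurcating root node."""

    root: TreeNode
    supports: dict[frozenset, float] | None = None

    def leaf_names(self) -> list[str]:
        return self.root.leaves()

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial leaf bipartitions, one per internal edge, each
        canonicalised as the smaller side (ties: lexicographic)."""
        all_leaves = frozenset(self.leaf_names())
        out: set[frozenset] = set()

        def walk(node: TreeNode) -> frozenset:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset()
            for child, _ in node.children:
                side = walk(child)
                if 1 < len(side) < len(all_leaves) - 1:
                    out.add(_canon(side, all_leaves))
                below |= side
            return below

        walk(self.root)
        return out

    def newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return node.name
            parts = []
            for child, length in node.children:
                label = fmt(child)
                if not child.is_leaf and self.supports is not None:
                    side = _canon(
                        frozenset(child.leaves()), frozenset(self.leaf_names())
                    )
                    sup = self.supports.get(side)
                    if sup is not None:
                        label += f"[&support={sup:.3f}]"
                parts.append(f"{label}:{length:.6f}")
            return "(" + ",".join(parts) + ")"

        return fmt(self.root) + ";"


def _canon(side: frozenset, universe: frozenset) -> frozenset:
    other = universe - side
    if len(side) < len(other):
        return side
    if len(other) < len(side):
        return other
    return min(side, other, key=lambda s: sorted(s))


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def _encode(seqs: list[str]) -> np.ndarray:
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), -1)
    codes = arr.astype(np.int16)
    codes[arr == ord("-")] = -1
    return codes


def p_distance_matrix(labels: list[str], seqs: list[str]) -> tuple[list[str], np.ndarray]:
    """Pairwise p-distances with pairwise deletion of gapped columns."""
    if len(labels) < 2:
        raise ValueError("need at least 2 sequences")
    if len(set(map(len, seqs))) != 1:
        raise ValueError("sequences must be aligned to equal length")
    X = _encode(seqs)
    valid = (X[:, None, :] >= 0) & (X[None, :, :] >= 0)
    comp = valid.sum(-1)
    mism = ((X[:, None, :] != X[None, :, :]) & valid).sum(-1)
    iu = np.triu_indices(len(labels), 1)
    if (comp[iu] == 0).any():
        raise ValueError("a sequence pair shares no comparable columns")
    with np.errstate(invalid="ignore"):
        d = np.where(comp > 0, mism / np.maximum(comp, 1), 0.0)
    np.fill_diagonal(d, 0.0)
    return list(labels), d


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(labels: list[str], d: np.ndarray) -> PhyloTree:
    """Saitou–Nei neighbor joining with deterministic tie-breaks."""
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.allclose(d, d.T) or (np.diag(d) != 0).any():
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    nodes = [TreeNode(name) for name in labels]
    D = d.astype(float).copy()
    active = list(range(n))

    clamped = 0
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # smallest Q; ties -> smallest (i, j) in current label order
        qmin = Q.min()
        ties = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        ti, tj = min((min(a, b), max(a, b)) for a, b in ties)
        dij = sub[ti, tj]
        li = dij / 2 + (r[ti] - r[tj]) / (2 * (m - 2))
        lj = dij - li
        if li < 0 or lj < 0:
            clamped += 1
        li, lj = max(li, 0.0), max(lj, 0.0)
        gi, gj = active[ti], active[tj]
        new = TreeNode(children=[(nodes[gi], li), (nodes[gj], lj)])
        nodes.append(new)
        # distances of the new node to remaining taxa
        newrow = np.zeros(D.shape[0] + 1)
        for tk in range(m):
            if tk in (ti, tj):
                continue
            gk = active[tk]
            newrow[gk] = (sub[ti, tk] + sub[tj, tk] - dij) / 2
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :] = newrow
        D[:, -1] = newrow
        active = [g for g in active if g not in (gi, gj)] + [len(nodes) - 1]

    # final three lineages join at the trifurcating root
    a, b, c = active
    dab, dac, dbc = D[a, b], D[a, c], D[b, c]
    la = (dab + dac - dbc) / 2
    lb = (dab + dbc - dac) / 2
    lc = (dac + dbc - dab) / 2
    lengths = [max(x, 0.0) for x in (la, lb, lc)]
    if any(x < 0 for x in (la, lb, lc)):
        clamped += 1
    if clamped:
        logger.info("clamped %d negative NJ branch length(s) to 0", clamped)
    root = TreeNode(children=list(zip((nodes[a], nodes[b], nodes[c]), lengths)))
    return PhyloTree(root)


def bootstrap_support(
    labels: list[str], seqs: list[str], n_replicates: int = 1000, seed: int = 0
) -> PhyloTree:
    """NJ tree on the full alignment with bootstrap supports per edge."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    L = len(seqs[0])
    _, d = p_distance_matrix(labels, seqs)
    tree = nj_tree(labels, d)
    target = tree.bipartitions()
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        cols = rng.integers(0, L, size=L)
        resampled = ["".join(s[c] for c in cols) for s in seqs]
        _, dr = p_distance_matrix(labels, resampled)
        reps = nj_tree(labels, dr).bipartitions()
        for bp in target & reps:
            counts[bp] += 1
    tree.supports = {bp: counts[bp] / n_replicates for bp in target}
    return tree


# ---------------------------------------------------------------------------
# Clade assignment
# ---------------------------------------------------------------------------

def assign_clades(
    queries: list[tuple[str, str]],
    references: list[tuple[str, str, str]],
) -> dict[str, tuple[str, str, float]]:
    """Nearest-labelled-reference clade assignment.

    ``queries``: (id, aligned55); ``references``: (id, aligned55, clade).
    Returns query id -> (clade, nearest reference id, p-distance); ties
    break by reference list order.
    """
    if not references:
        raise ValueError("reference set must be non-empty")
    out: dict[str, tuple[str, str, float]] = {}
    ref_codes = _encode([s for _, s, _ in references])
    for qid, qseq in queries:
        q = _encode([qseq])[0]
        valid = (ref_codes >= 0) & (q[None, :] >= 0)
        comp = valid.sum(-1)
        if (comp == 0).all():
            raise ValueError(f"{qid}: no comparable columns to any reference")
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = np.where(comp > 0, ((ref_codes != q[None, :]) & valid).sum(-1) / np.maximum(comp, 1), np.inf)
        best = int(np.argmin(dist))  # argmin: first minimum -> reference order
        rid, _, clade = references[best]
        out[qid] = (clade, rid, float(dist[best]))
    return out


def load_packaged_references() -> list[tuple[str, str, str]]:
    """Packaged synthetic clade-labelled reference domain set."""
    from .io import read_fasta

    with resources.as_file(
        resources.files("bhlhfam") / "data" / "reference_clades.synthetic.fasta"
    ) as p:
        seqs = {r.id: r.sequence for r in read_fasta(p, "protein")}
    with resources.as_file(
        resources.files("bhlhfam") / "data" / "reference_clades.synthetic.tsv"
    ) as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    return [(r["id"], seqs[r["id"]], str(r["clade"])) for _, r in df.iterrows()]


def write_phylip(labels: list[str], d: np.ndarray, path) -> None:
    """Square PHYLIP-style distance matrix."""
    with open(path, "w") as fh:
        fh.write(f"{len(labels)}\n")
        for lab, row in zip(labels, d):
            fh.write(lab + "  " + "  ".join(f"{x:.6f}" for x in row) + "\n")
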