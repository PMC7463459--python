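"""Homolog-projected protein–protein interaction networks.

A reference edge list (e.g. curated Arabidopsis bHLH interactions) is
projected onto the query family through best-homolog mapping: each query
maps to its nearest reference by domain p-distance, and every reference
edge (A, B) induces query edges between all queries mapped to A and all
mapped to B.  Self-edges are dropped; a reference self-loop (homodimer)
instead yields a per-query "potential homodimer" annotation plus edges
between distinct queries sharing that reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .phylo import assign_clades


@dataclass
class ProjectedNetwork:
    edges: dict[tuple[str, str], list[tuple[str, str]]] = field(default_factory=dict)
    homodimer_candidates: set[str] = field(default_factory=set)

    @property
    def edge_list(self) -> list[tuple[str, str]]:
        return sorted(self.edges)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "query_a": a,
                "query_b": b,
                "via": ";".join(f"{ra}-{rb}" for ra, rb in sorted(set(refs))),
            }
            for (a, b), refs in sorted(self.edges.items())
        ]
        return pd.DataFrame(rows, columns=["query_a", "query_b", "via"])

    def to_graphml(self, path) -> None:
        import networkx as nx

        G = nx.Graph()
        for (a, b), refs in self.edges.items():
            G.add_edge(a, b, via=";".join(f"{ra}-{rb}" for ra, rb in sorted(set(refs))))
        for q in self.homodimer_candidates:
            if q not in G:
                G.add_node(q)
            G.nodes[q]["potential_homodimer"] = True
        nx.write_graphml(G, path)


def best_hits(
    queries: list[tuple[str, str]], references: list[tuple[str, str]]
) -> dict[str, tuple[str, float]]:
    """Map each query domain to its minimum-p-distance reference.

    Ties break by reference list order; raises on an empty reference set
    or a query with no comparable columns.
    """
    if not references:
        raise ValueError("reference set must be non-empty")
    labelled = [(rid, seq, rid) for rid, seq in references]
    assigned = assign_clades(queries, labelled)
    return {qid: (rid, dist) for qid, (_, rid, dist) in assigned.items()}


def project_network(
    homolog_map: dict[str, tuple[str, float]],
    reference_edges: list[tuple[str, str]],
    valid_references: set[str] | None = None,
) -> ProjectedNetwork:
    """Project reference edges onto queries through the homolog map.

    When ``valid_references`` is given, an edge naming an id outside it is
    an error (guards against typos in user-supplied edge lists).
    """
    by_ref: dict[str, list[str]] = {}
    for qid, (rid, _) in homolog_map.items():
        by_ref.setdefault(rid, []).append(qid)
    net = ProjectedNetwork()
    for ra, rb in reference_edges:
        if valid_references is not None and (
            ra not in valid_references or rb not in valid_references
        ):
            raise ValueError(f"edge ({ra}, {rb}) names an unknown reference")
        qa = by_ref.get(ra, [])
        qb = by_ref.get(rb, [])
        if ra == rb:
            net.homodimer_candidates.update(qa)
        for a in qa:
            for b in qb:
                if a == b:
                    continue
                key = (min(a, b), max(a, b))
                net.edges.setdefault(key, []).append((ra, rb))
    return net


def load_packaged_edges() -> list[tuple[str, str]]:
    """Packaged Arabidopsis bHLH interaction edge list (literature-derived)."""
    with resources.as_file(resources.files("bhlhfam") / "data" / "reference_edges.tsv") as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    return [(r["protein_a"], r["protein_b"]) for _, r in df.iterrows()]
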