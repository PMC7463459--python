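"""Family-level summaries and the end-to-end pipeline orchestrator.

The orchestrator runs identify -> classify -> conserve -> tree/clades ->
promoters -> gene structure -> expression -> qPCR -> network on whatever
inputs are supplied (stages without inputs are skipped), writing every
table as TSV stamped with the run seed and a config hash so a rerun with
identical inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import domain as dm
from . import expression as ex
from . import genestruct as gs
from . import network as nw
from . import phylo as ph
from . import promoter as pr
from .io import RunConfig, SequenceRecord, logger, write_fasta, write_gff3, write_newick

BINDING_ROW_ORDER = [
    "G_box", "E_box_non_G_box", "E_box", "non_E_box", "DNA_binding", "non_DNA_binding",
]


def percent_half_up(count: int, total: int) -> float:
    """Exact count/total as a percentage, rounded half-up to 2 decimals."""
    exact = Fraction(count * 100, total)
    d = Decimal(exact.numerator) / Decimal(exact.denominator)
    return float(d.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def summarize_binding(calls: Sequence[dm.BindingCall] | Mapping[str, int]) -> pd.DataFrame:
    """Category counts and exact percentages, with derived aggregate rows.

    ``calls`` may be BindingCall objects or a category->count mapping.
    Derived rows: E_box = G_box + E_box_non_G_box; DNA_binding = E_box +
    non_E_box.  Percentages are count/total rounded half-up to 2 decimals
    (exact rationals internally).
    """
    if isinstance(calls, Mapping):
        counts = {c: int(calls.get(c, 0)) for c in dm.BINDING_CATEGORIES}
    else:
        calls = list(calls)
        counts = {c: 0 for c in dm.BINDING_CATEGORIES}
        for call in calls:
            counts[call.category] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no binding calls to summarize")
    derived = {
        "E_box": counts["G_box"] + counts["E_box_non_G_box"],
        "DNA_binding": counts["G_box"] + counts["E_box_non_G_box"] + counts["non_E_box"],
    }
    rows = []
    for name in BINDING_ROW_ORDER:
        c = derived.get(name, counts.get(name))
        rows.append({"type": name, "count": c, "percent": percent_half_up(c, total)})
    df = pd.DataFrame(rows)
    df.attrs["total"] = total
    return df


def load_family_table() -> pd.DataFrame:
    """Packaged gene/locus/accession/clade table of the surveyed
    *D. officinale* bHLH family (98 members, 18 clades)."""
    with resources.as_file(resources.files("bhlhfam") / "data" / "table1_members.tsv") as p:
        return pd.read_csv(p, sep="\t", comment="#", dtype={"clade": int})


def family_bookkeeping(table: pd.DataFrame) -> dict:
    """Member/clade counts and the share of the two expanded clades (14, 15)."""
    clade_sizes = table["clade"].value_counts().sort_index()
    n = len(table)
    expanded = int(clade_sizes.get(14, 0) + clade_sizes.get(15, 0))
    return {
        "n_members": n,
        "n_clades": int(table["clade"].nunique()),
        "clade_sizes": clade_sizes.to_dict(),
        "clades_14_15_members": expanded,
        "clades_14_15_percent": percent_half_up(expanded, n),
    }


# ---------------------------------------------------------------------------
# Synthetic study conditions
# ---------------------------------------------------------------------------

#: tier patterns of the five expression groups the generator emulates:
#: flower-restricted, sparse/low, root-specific, broadly moderate, and
#: ubiquitous/abundant — plus a silent block (below detection everywhere)
_FLOWER = ("column", "flower_buds", "lip", "sepal")
_ROOT = ("white_root", "green_root_tip")
EXPRESSION_GROUP_SPEC = [
    ("flower_restricted", 6, {t: "moderate" for t in _FLOWER}),
    ("sparse_low", 13, {"stem": "low"}),
    ("root_specific", 4, {t: "abundant" for t in _ROOT}),
    ("broad_moderate", 40, {t: "moderate" for t in _FLOWER + _ROOT + ("leaf", "stem")}),
    ("ubiquitous_abundant", 12, {t: "abundant" for t in _FLOWER + _ROOT + ("leaf", "stem")}),
    ("silent", 23, {}),
]


def simulate_inputs(
    seed: int,
    n_genes: int = 20,
    n_promoters: int = 30,
    mutation_rate: float = 0.05,
) -> tuple[PipelineInputs, dict]:
    """Full synthetic input bundle at the standard study conditions.

    98 proteins in 18 clades with the survey's DNA-binding category mix,
    genes cycling through 0–11 introns, 2000-nt promoters with planted
    non-nested motifs, a 98-gene x 8-tissue FPKM matrix in five expressed
    groups plus a silent block, and a qPCR table with a planted log2
    fold-change grid.  Returns the inputs plus the per-stage truths.
    """
    from . import synth

    proteins, fam_truth = synth.make_family(
        98, synth.default_clade_spec(), mutation_rate=mutation_rate, seed=seed
    )
    pairs, gene_truths = [], {}
    for i in range(n_genes):
        gid = f"SYNG{i + 1:03d}"
        genomic, cds, t = synth.make_gene(
            i % 12, intron_len_range=(44, 800), seed=seed * 1000 + i, gene_id=gid
        )
        pairs.append((cds, genomic))
        gene_truths[gid] = t
    plant = {"G-box": 2, "ERE": 2, "MBS": 1}
    lib = {m.name: m.pattern for m in pr.load_motif_library()}
    promoters, prom_truth = synth.make_promoters(
        n_promoters,
        plant=plant,
        seed=seed + 1,
        library=lib,
        clean_against={m: lib[m] for m in plant},
    )
    matrix, expr_truth = synth.make_expression(
        98, group_spec=EXPRESSION_GROUP_SPEC, noise_sd=0.0, seed=seed + 2
    )
    genes = [f"SYNQ{i:02d}" for i in range(1, 17)]
    grid = [-2.0, -1.0, 0.0, 1.0, 2.0]
    log2fc_spec = {
        g: {
            (cond, tp): grid[(i + j) % len(grid)]
            for j, (cond, tp) in enumerate(
                (c, t) for c in ("MeJA", "ABA") for t in ("3h", "6h")
            )
        }
        for i, g in enumerate(genes)
    }
    qpcr, qpcr_truth = synth.make_qpcr(
        genes, log2fc_spec, ct_noise_sd=0.1, seed=seed + 3
    )
    inputs = PipelineInputs(
        proteins=proteins,
        gene_pairs=pairs,
        promoters=promoters,
        expression=matrix,
        qpcr=qpcr,
    )
    truths = {
        "family": fam_truth,
        "genes": gene_truths,
        "promoters": prom_truth,
        "expression": expr_truth,
        "qpcr": qpcr_truth,
    }
    return inputs, truths


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineInputs:
    """Optional inputs per stage; a stage with no input is skipped."""

    proteins: list[SequenceRecord] | None = None
    gene_pairs: list[tuple[SequenceRecord, SequenceRecord]] | None = None  # (cds, genomic)
    promoters: list[SequenceRecord] | None = None
    expression: pd.DataFrame | None = None
    qpcr: pd.DataFrame | None = None
    qpcr_reference_gene: str = "DoActin"

    def any_present(self) -> bool:
        return any(
            x is not None
            for x in (self.proteins, self.gene_pairs, self.promoters, self.expression, self.qpcr)
        )


def _config_hash(config: RunConfig) -> str:
    # analytic parameters only: where the output lands must not change
    # the recorded fingerprint
    payload = json.dumps(
        {k: str(v) for k, v in vars(config).items() if k != "out_dir"},
        sort_keys=True,
    ).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def run_pipeline(config: RunConfig, inputs: PipelineInputs) -> dict:
    """Run all enabled stages; returns in-memory results per stage.

    Every output TSV carries a ``# seed=... config=...`` header line.
    """
    if not inputs.any_present():
        raise ValueError("no inputs supplied; nothing to run")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = f"seed={config.seed} config={_config_hash(config)}"
    results: dict = {}

    def save(df: pd.DataFrame, name: str, index: bool = False) -> None:
        with open(out / name, "w") as fh:
            fh.write(f"# {stamp}\n")
            df.to_csv(fh, sep="\t", index=index)

    if inputs.proteins is not None:
        logger.info("stage identify: scanning %d proteins", len(inputs.proteins))
        profile = dm.load_packaged_profile()
        threshold = (
            config.domain_threshold
            if config.domain_threshold is not None
            else dm.calibrate_threshold(profile, seed=config.seed)
        )
        hits, missed = [], []
        for recd in inputs.proteins:
            hit = dm.scan_domain(recd, profile, threshold)
            (hits.append(hit) if hit else missed.append(recd.id))
        calls = {
            h.protein_id: dm.classify_binding(h, config.basic_set, config.basic_cutoff)
            for h in hits
        }
        props = {p.id: dm.protein_properties(p) for p in inputs.proteins}
        refs = ph.load_packaged_references()
        clades = ph.assign_clades([(h.protein_id, h.aligned55) for h in hits], refs)
        members = pd.DataFrame(
            [
                {
                    "protein_id": h.protein_id,
                    "clade": clades[h.protein_id][0],
                    "length": props[h.protein_id].length,
                    "mw": round(props[h.protein_id].mw, 2),
                    "pi": round(props[h.protein_id].pi, 2),
                    "domain_start": h.start,
                    "score": round(h.score, 3),
                    "category": calls[h.protein_id].category,
                    "basic_count": calls[h.protein_id].basic_count,
                }
                for h in hits
            ]
        )
        save(members, "members.tsv")
        save(summarize_binding(list(calls.values())), "binding_summary.tsv")
        cons = dm.conservation([h.aligned55 for h in hits])
        save(
            pd.DataFrame([vars(c) for c in cons]),
            "conservation.tsv",
        )
        tree = ph.bootstrap_support(
            [h.protein_id for h in hits],
            [h.aligned55 for h in hits],
            n_replicates=config.n_bootstrap,
            seed=config.seed,
        )
        write_newick(tree.newick(), out / "tree.nwk")
        save(
            pd.DataFrame(
                [
                    {"protein_id": q, "clade": c, "nearest_reference": r,
                     "distance": round(dist, 4)}
                    for q, (c, r, dist) in clades.items()
                ]
            ),
            "clades.tsv",
        )
        homologs = nw.best_hits(
            [(h.protein_id, h.aligned55) for h in hits],
            [(rid, seq) for rid, seq, _ in refs],
        )
        net = nw.project_network(homologs, nw.load_packaged_edges())
        save(net.to_frame(), "network_edges.tsv")
        results.update(
            hits=hits, missed=missed, calls=calls, clades=clades, tree=tree,
            members=members, network=net,
        )

    if inputs.promoters is not None:
        library = pr.load_motif_library(config.motif_library)
        all_hits = [
            h for p in inputs.promoters for h in pr.scan_motifs(p, library)
        ]
        summary = pr.summarize_motifs(
            all_hits, [p.id for p in inputs.promoters], [m.name for m in library]
        )
        save(
            pd.DataFrame([vars(h) for h in all_hits]),
            "motif_hits.tsv",
        )
        save(summary, "motif_summary.tsv")
        results.update(motif_hits=all_hits, motif_summary=summary)

    if inputs.gene_pairs is not None:
        models = [gs.infer_structure(cds, genomic) for cds, genomic in inputs.gene_pairs]
        write_gff3(models, out / "gene_models.gff3")
        save(gs.structure_table(models), "gene_structure.tsv")
        results.update(gene_models=models, intron_stats=gs.intron_stats(models))

    if inputs.expression is not None:
        thresholds = ex.ExpressionThresholds(config.t_expr, config.t_low, config.t_mod)
        calls_df = ex.call_expression(inputs.expression, thresholds)
        expressed = inputs.expression.loc[calls_df["expressed"]]
        groups = ex.heatmap_groups(expressed, k=min(config.heatmap_k, len(expressed)))
        save(calls_df, "expression_calls.tsv", index=True)
        save(groups, "expression_groups.tsv", index=True)
        results.update(expression_calls=calls_df, expression_groups=groups)

    if inputs.qpcr is not None:
        folds = ex.ddct(inputs.qpcr, inputs.qpcr_reference_gene)
        save(folds, "qpcr_folds.tsv")
        results.update(qpcr_folds=folds)

    return results
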