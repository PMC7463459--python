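"""Expression tiers, heatmap grouping and 2^-ddCT qPCR analysis.

Tier bins on FPKM are half-open: [0, 2) not expressed, [2, 10) low,
[10, 50) moderate, [50, inf) abundant; a gene is "expressed" when any
tissue reaches 2.  Heatmap grouping clusters log2(FPKM + 0.01) rows by
average-linkage Euclidean agglomeration cut to k groups.

Relative expression follows the ddCT model: technical replicates are
averaged to one CT per (gene, condition, timepoint, biological
replicate); dCT = CT_gene - CT_reference per replicate; ddCT is the
condition-vs-baseline difference of mean dCT; fold = 2^-ddCT.
Significance is a two-sided pooled-variance Student's t-test on the
replicate dCT values (Welch optional), starred at p < 0.05 and p < 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import ttest_ind

TIERS = ("not_expressed", "low", "moderate", "abundant")


@dataclass(frozen=True)
class ExpressionThresholds:
    t_expr: float = 2.0
    t_low: float = 10.0
    t_mod: float = 50.0


def call_expression(
    matrix: pd.DataFrame, thresholds: ExpressionThresholds = ExpressionThresholds()
) -> pd.DataFrame:
    """Tier call per gene/tissue plus an ``expressed`` flag per gene.

    Returns a DataFrame of tier strings shaped like ``matrix`` with an
    extra boolean ``expressed`` column (>= t_expr in at least one tissue).
    """
    if (matrix.values < 0).any():
        raise ValueError("FPKM values must be non-negative")
    t = thresholds
    vals = matrix.values
    tiers = np.select(
        [vals < t.t_expr, vals < t.t_low, vals < t.t_mod],
        ["not_expressed", "low", "moderate"],
        default="abundant",
    )
    out = pd.DataFrame(tiers, index=matrix.index, columns=matrix.columns)
    out["expressed"] = (vals >= t.t_expr).any(axis=1)
    return out


def heatmap_groups(
    matrix: pd.DataFrame,
    k: int = 5,
    method: str = "average",
    metric: str = "euclidean",
) -> pd.DataFrame:
    """Cut an agglomerative clustering of log2(FPKM + 0.01) rows into k groups.

    Returns a DataFrame (gene, group) where groups are numbered 1..k in
    order of first appearance along the input gene order, making the
    labelling deterministic and order-stable up to relabelling.
    """
    if not 1 <= k <= len(matrix):
        raise ValueError(f"k must be in [1, {len(matrix)}]")
    transformed = np.log2(matrix.values + 0.01)
    if len(matrix) == 1:
        labels = np.array([1])
    else:
        Z = linkage(transformed, method=method, metric=metric)
        labels = fcluster(Z, t=k, criterion="maxclust")
    # renumber by first appearance for determinism
    remap: dict[int, int] = {}
    out = []
    for lab in labels:
        if lab not in remap:
            remap[lab] = len(remap) + 1
        out.append(remap[lab])
    return pd.DataFrame({"gene": matrix.index, "group": out}).set_index("gene")


def log2_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """The heatmap transform, log2(FPKM + 0.01)."""
    return np.log2(matrix + 0.01)


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

REQUIRED_QPCR_COLUMNS = ["condition", "timepoint", "gene", "bio_rep", "tech_rep", "ct"]


def ddct(
    table: pd.DataFrame,
    reference_gene: str,
    baseline: tuple[str, str] = ("control", "0h"),
    welch: bool = False,
) -> pd.DataFrame:
    """2^-ddCT fold changes with Student's t-test per gene/condition/timepoint.

    ``table`` is long-format with columns condition, timepoint, gene,
    bio_rep, tech_rep, ct.  The baseline (condition, timepoint) must be
    present, as must the reference gene for every (condition, timepoint,
    bio_rep).  Rows for the baseline itself carry ddCT 0 / fold 1 and no
    test.  A Benjamini–Hochberg column is emitted alongside the raw p for
    transparency; the stars follow the raw p.
    """
    missing = [c for c in REQUIRED_QPCR_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"qPCR table missing columns: {missing}")
    if (table["ct"] <= 0).any():
        raise ValueError("CT values must be positive")
    # average technical replicates
    ct = (
        table.groupby(["condition", "timepoint", "gene", "bio_rep"], sort=False)["ct"]
        .mean()
        .reset_index()
    )
    ref = ct[ct["gene"] == reference_gene].set_index(["condition", "timepoint", "bio_rep"])["ct"]
    targets = ct[ct["gene"] != reference_gene].copy()
    key = list(zip(targets["condition"], targets["timepoint"], targets["bio_rep"]))
    try:
        targets["dct"] = targets["ct"].values - ref.loc[key].values
    except KeyError as err:
        raise ValueError(f"reference gene missing for replicate group: {err}") from err

    base_cond, base_tp = baseline
    base = targets[(targets["condition"] == base_cond) & (targets["timepoint"] == base_tp)]
    if base.empty:
        raise ValueError(f"baseline {baseline!r} absent from table")
    base_by_gene = {g: grp["dct"].values for g, grp in base.groupby("gene")}

    rows = []
    for (cond, tp, gene), grp in targets.groupby(
        ["condition", "timepoint", "gene"], sort=False
    ):
        dcts = grp["dct"].values
        bvals = base_by_gene.get(gene)
        if bvals is None:
            raise ValueError(f"gene {gene!r} missing from baseline")
        ddct_val = float(dcts.mean() - bvals.mean())
        is_baseline = (cond, tp) == baseline
        if is_baseline:
            tstat, p = np.nan, np.nan
        else:
            if len(dcts) < 2 or len(bvals) < 2:
                raise ValueError("need >= 2 biological replicates in both groups")
            tstat, p = ttest_ind(dcts, bvals, equal_var=not welch)
        stars = "" if is_baseline or np.isnan(p) else ("**" if p < 0.01 else "*" if p < 0.05 else "")
        rows.append(
            {
                "gene": gene,
                "condition": cond,
                "timepoint": tp,
                "delta_ct": float(dcts.mean()),
                "delta_delta_ct": ddct_val,
                "fold": 2.0 ** (-ddct_val),
                "log2fc": -ddct_val,
                "t_statistic": float(tstat) if not np.isnan(tstat) else np.nan,
                "p_value": float(p) if not np.isnan(p) else np.nan,
                "stars": stars,
            }
        )
    out = pd.DataFrame(rows)
    # BH-adjusted p over the tested rows
    tested = out["p_value"].notna()
    p = out.loc[tested, "p_value"].values
    m = len(p)
    if m:
        order = np.argsort(p)
        adj = np.empty(m)
        running = 1.0
        for rank_idx in range(m - 1, -1, -1):
            idx = order[rank_idx]
            running = min(running, p[idx] * m / (rank_idx + 1))
            adj[idx] = running
        out.loc[tested, "p_bh"] = adj
    else:
        out["p_bh"] = np.nan
    return out
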