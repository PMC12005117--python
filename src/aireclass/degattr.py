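"""Differential expression and the gene-to-cluster attribution rule that
splits Aire target genes (Aire-DEGs) into Aire-driven and Aire-enhanced
classes.

Pipeline: a Wilcoxon rank-sum DEG scan of the WT Aire-expressing cluster
against its knockout counterpart defines the Aire-DEG set (Bonferroni
p < 0.05, positive log fold change).  Each gene is then attributed to one
or more clusters from its one-vs-rest significance profile and the z-scores
of its per-cluster mean expression, via a four-branch rule:

1. ``exclusive``  — significant (adjusted p < 1e-5) only in the cluster
   with the highest mean: assign that cluster.
2. ``zgap``       — z(top) - z(second) > 1: assign the top cluster.
3. ``multi_soft`` — no significant cluster: assign every cluster with z > 0.
4. ``multi_sig``  — otherwise: assign every cluster whose mean is not lower
   than the lowest mean among significantly-high clusters.

An Aire-DEG attributed solely to the Aire cluster is *Aire-driven*; one
attributed to any other mature cluster is *Aire-enhanced*.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .normx import group_zscore
from .rankstats import adjust_pvalues

__all__ = [
    "two_group_deg",
    "extract_aire_degs",
    "one_vs_rest_padj",
    "attribute_gene",
    "attribute_genes",
    "classify_aire_degs",
    "classify_dynamics",
    "call_aire_neutral",
]

BRANCHES = ("exclusive", "zgap", "multi_soft", "multi_sig")


def _vectorized_ranksum(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sided Mann-Whitney p per column of cells x genes blocks."""
    res = stats.mannwhitneyu(
        a, b, axis=0, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return np.asarray(res.pvalue, dtype=float)


def two_group_deg(
    layer,
    cells_a,
    cells_b,
    min_frac: float = 0.05,
    gene_names=None,
) -> pd.DataFrame:
    """Rank-sum DEG table between two disjoint cell sets on a lognorm layer.

    Genes expressed (value > 0) in fewer than ``min_frac`` of cells in BOTH
    groups are excluded from testing (flagged, no p value).  log_fc is the
    natural log of (mean expm1 + 1) ratios; p values are Bonferroni-adjusted
    over the tested genes.
    """
    x = np.asarray(layer, dtype=float)
    cells_a = np.asarray(cells_a)
    cells_b = np.asarray(cells_b)
    if cells_a.dtype == bool:
        cells_a = np.flatnonzero(cells_a)
    if cells_b.dtype == bool:
        cells_b = np.flatnonzero(cells_b)
    if len(cells_a) == 0 or len(cells_b) == 0:
        raise ValueError("both cell sets must be nonempty")
    if np.intersect1d(cells_a, cells_b).size:
        raise ValueError("cell sets overlap")

    a = x[cells_a]
    b = x[cells_b]
    frac_a = (a > 0).mean(axis=0)
    frac_b = (b > 0).mean(axis=0)
    excluded = (frac_a < min_frac) & (frac_b < min_frac)

    mean_a = np.expm1(a).mean(axis=0)
    mean_b = np.expm1(b).mean(axis=0)
    log_fc = np.log((mean_a + 1.0) / (mean_b + 1.0))

    n_genes = x.shape[1]
    p = np.full(n_genes, np.nan)
    tested = ~excluded
    if tested.any():
        p[tested] = _vectorized_ranksum(a[:, tested], b[:, tested])
    p_adj = np.full(n_genes, np.nan)
    p_adj[tested] = adjust_pvalues(p[tested], method="bonferroni")

    idx = gene_names if gene_names is not None else np.arange(n_genes)
    return pd.DataFrame(
        {
            "log_fc": log_fc,
            "p": p,
            "p_adj": p_adj,
            "frac_expressing_a": frac_a,
            "frac_expressing_b": frac_b,
            "excluded": excluded,
        },
        index=pd.Index(idx, name="gene"),
    )


def extract_aire_degs(
    deg_table: pd.DataFrame, p_max: float = 0.05, min_log_fc: float = 0.0
) -> pd.Index:
    """Genes significantly up in the WT Aire cluster vs the KO counterpart."""
    keep = (~deg_table["excluded"]) & (deg_table["p_adj"] < p_max) & (
        deg_table["log_fc"] > min_log_fc
    )
    return deg_table.index[keep.fillna(False)]


def one_vs_rest_padj(layer, clusters, cluster_ids=None) -> pd.DataFrame:
    """One-vs-rest rank-sum adjusted p per gene and cluster (Bonferroni over
    genes within each cluster's scan), restricted to the positive side:
    a cluster is significant only when its mean exceeds the rest mean."""
    x = np.asarray(layer, dtype=float)
    clusters = np.asarray(clusters)
    if cluster_ids is None:
        cluster_ids = list(pd.unique(clusters))
    out = {}
    for c in cluster_ids:
        mask = clusters == c
        p = _vectorized_ranksum(x[mask], x[~mask])
        p = adjust_pvalues(p, method="bonferroni")
        higher = x[mask].mean(axis=0) > x[~mask].mean(axis=0)
        p = np.where(higher, p, 1.0)
        out[c] = p
    return pd.DataFrame(out)


def attribute_gene(
    cluster_means: np.ndarray,
    p_adj: np.ndarray,
    sig_p: float = 1e-5,
    z_gap: float = 1.0,
) -> tuple[list[int], str]:
    """Attribute one gene to cluster(s) from its means and one-vs-rest p_adj.

    Returns (assigned cluster indices, branch).  See the module docstring
    for the four branches.
    """
    means = np.asarray(cluster_means, dtype=float)
    p = np.asarray(p_adj, dtype=float)
    if means.size < 2:
        raise ValueError("need at least two clusters")
    # z-scores of the cluster means (sample SD, matching group_zscore)
    sd = means.std(ddof=1)
    z = (means - means.mean()) / sd if sd > 0 else np.zeros_like(means)

    top = int(np.argmax(means))
    sig = np.flatnonzero(p < sig_p)
    order = np.argsort(z)[::-1]
    gap = z[order[0]] - z[order[1]]

    if sig.size and set(sig) == {top}:
        return [top], "exclusive"
    if gap > z_gap:
        return [int(order[0])], "zgap"
    if sig.size == 0:
        assigned = list(np.flatnonzero(z > 0))
        return assigned, "multi_soft"
    floor = means[sig].min()
    assigned = list(np.flatnonzero(means >= floor))
    return assigned, "multi_sig"


def attribute_genes(
    layer,
    clusters,
    cluster_ids=None,
    gene_names=None,
    sig_p: float = 1e-5,
    z_gap: float = 1.0,
) -> pd.DataFrame:
    """Run the attribution rule for every gene over the given clusters."""
    x = np.asarray(layer, dtype=float)
    clusters = np.asarray(clusters)
    if cluster_ids is None:
        cluster_ids = list(pd.unique(clusters))
    keep = np.isin(clusters, cluster_ids)
    x = x[keep]
    clusters = clusters[keep]

    padj = one_vs_rest_padj(x, clusters, cluster_ids)
    means = np.vstack([x[clusters == c].mean(axis=0) for c in cluster_ids]).T

    assigned, branch = [], []
    for g in range(x.shape[1]):
        idx, br = attribute_gene(means[g], padj.iloc[g].to_numpy(), sig_p, z_gap)
        assigned.append(frozenset(cluster_ids[i] for i in idx))
        branch.append(br)
    index = pd.Index(
        gene_names if gene_names is not None else np.arange(x.shape[1]), name="gene"
    )
    return pd.DataFrame({"assigned_clusters": assigned, "branch": branch}, index=index)


def classify_aire_degs(
    aire_degs: pd.Index, attribution: pd.DataFrame, aire_cluster: str
) -> pd.Series:
    """Label each gene aire_driven / aire_enhanced / none.

    An Aire-DEG attributed solely to the Aire cluster is aire_driven; one
    attributed to any other cluster is aire_enhanced; everything else none.
    """
    labels = pd.Series("none", index=attribution.index, name="aire_deg_class")
    missing = [g for g in aire_degs if g not in attribution.index]
    if missing:
        warnings.warn(f"{len(missing)} Aire-DEGs missing from attribution; labeled none")
    for g in aire_degs:
        if g not in attribution.index:
            continue
        assigned = attribution.loc[g, "assigned_clusters"]
        if len(assigned) == 0:
            warnings.warn(f"Aire-DEG {g} unattributed; labeled none")
            continue
        if assigned == frozenset({aire_cluster}):
            labels.loc[g] = "aire_driven"
        else:
            labels.loc[g] = "aire_enhanced"
    return labels


def classify_dynamics(layer, clusters, path=("low", "mid", "aire"), gene_names=None) -> pd.Series:
    """Up/down label across the maturation path, comparing endpoint means.

    mean(final) > mean(first) on the lognorm layer means up; exact equality
    counts as down (flagged by the tie in the means, not separately stored).
    """
    x = np.asarray(layer, dtype=float)
    clusters = np.asarray(clusters)
    for c in (path[0], path[-1]):
        if not np.any(clusters == c):
            raise ValueError(f"empty cluster {c!r} on the maturation path")
    first = x[clusters == path[0]].mean(axis=0)
    last = x[clusters == path[-1]].mean(axis=0)
    lab = np.where(last > first, "mtec_high_up", "mtec_high_down")
    index = pd.Index(gene_names if gene_names is not None else np.arange(x.shape[1]), name="gene")
    return pd.Series(lab, index=index, name="dynamics")


def call_aire_neutral(
    sc_table: pd.DataFrame,
    bulk_table: pd.DataFrame,
    bulk_log2fc_max: float = 0.2,
    bulk_fdr_min: float = 0.05,
    sc_p_min: float = 1e-5,
) -> pd.Index:
    """Aire-neutral genes: comparable in bulk KO vs WT and non-significant in
    the single-cell Aire contrast.

    bulk: |log2 FC| < 0.2 and FDR > 0.05; single cell: adjusted p >= 1e-5.
    """
    for col in ("log2_fc", "fdr"):
        if col not in bulk_table.columns:
            raise ValueError(f"bulk table missing column {col!r}")
    common = sc_table.index.intersection(bulk_table.index)
    bulk = bulk_table.loc[common]
    sc = sc_table.loc[common]
    sc_ok = sc["p_adj"].isna() | (sc["p_adj"] >= sc_p_min)
    keep = (
        (bulk["log2_fc"].abs() < bulk_log2fc_max)
        & (bulk["fdr"] > bulk_fdr_min)
        & sc_ok
    )
    return common[keep.to_numpy()]
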