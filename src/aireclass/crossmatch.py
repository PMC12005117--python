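"""Cross-dataset cell-to-cluster matching via auROC-selected signatures.

Per reference cluster, one-vs-rest marker genes are scored by auROC and
rank-sum p (BH-adjusted); the top genes by |AUC - 0.5| among those with
adjusted p < 0.05 form the signature.  Each query cell is assigned to the
reference cluster whose mean profile it correlates with best over the
pooled signature genes, or left unassigned when the best r is 0.2 or lower.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .degattr import _vectorized_ranksum
from .rankstats import adjust_pvalues

__all__ = ["select_signatures", "assign_cells", "matching_matrix"]


def _vectorized_auroc(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise AUC of a (positives) vs b via the rank-sum identity."""
    from scipy.stats import rankdata

    pooled = np.vstack([a, b])
    ranks = rankdata(pooled, axis=0)
    r1 = ranks[: a.shape[0]].sum(axis=0)
    u = r1 - a.shape[0] * (a.shape[0] + 1) / 2.0
    return u / (a.shape[0] * b.shape[0])


def select_signatures(
    layer,
    clusters,
    gene_names=None,
    top_k: int = 2000,
    p_max: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Per-cluster signature gene tables sorted by |AUC - 0.5| descending.

    Clusters with fewer than 3 cells are skipped with a warning.  Each table
    has columns auc and p_adj, truncated at ``top_k`` qualifying genes.
    """
    x = np.asarray(layer, dtype=float)
    clusters = np.asarray(clusters)
    ids = list(pd.unique(clusters))
    if len(ids) < 2:
        raise ValueError("need at least two reference clusters")
    names = pd.Index(gene_names if gene_names is not None else np.arange(x.shape[1]))
    out: dict[str, pd.DataFrame] = {}
    for c in ids:
        mask = clusters == c
        if mask.sum() < 3:
            warnings.warn(f"cluster {c!r} has fewer than 3 cells; skipped")
            continue
        auc = _vectorized_auroc(x[mask], x[~mask])
        p = _vectorized_ranksum(x[mask], x[~mask])
        p_adj = adjust_pvalues(p, method="bh")
        tab = pd.DataFrame({"auc": auc, "p_adj": p_adj}, index=names)
        tab = tab[tab["p_adj"] < p_max]
        tab = tab.reindex((tab["auc"] - 0.5).abs().sort_values(ascending=False).index)
        out[c] = tab.head(top_k)
    return out


def assign_cells(
    query_layer,
    reference_profiles: pd.DataFrame,
    signatures: dict[str, pd.DataFrame],
    query_gene_names,
    min_r: float = 0.2,
) -> pd.DataFrame:
    """Assign each query cell to the best-correlated reference cluster.

    ``reference_profiles`` is a genes x clusters frame of mean reference
    expression.  Correlation uses the union of signature genes present in
    the query; a cell with best r <= ``min_r`` is unassigned.
    """
    union = pd.Index(sorted(set().union(*(s.index for s in signatures.values()))))
    query_names = pd.Index(query_gene_names)
    present = union.intersection(query_names).intersection(reference_profiles.index)
    if len(present) == 0:
        raise ValueError("no signature genes present in the query")
    if len(present) < len(union):
        warnings.warn(f"{len(union) - len(present)} signature genes missing from query; dropped")

    x = np.asarray(query_layer, dtype=float)[:, query_names.get_indexer(present)]
    ref = reference_profiles.loc[present].to_numpy(dtype=float)
    ref_ids = list(reference_profiles.columns)

    xc = x - x.mean(axis=1, keepdims=True)
    rc = ref - ref.mean(axis=0, keepdims=True)
    xn = np.linalg.norm(xc, axis=1)
    rn = np.linalg.norm(rc, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ rc) / np.outer(xn, rn)
    r = np.nan_to_num(r, nan=-np.inf)

    best_idx = np.argmax(r, axis=1)  # ties: argmax takes the lowest index
    best_r = r[np.arange(len(x)), best_idx]
    assigned = np.where(best_r > min_r, np.array(ref_ids, dtype=object)[best_idx], "unassigned")
    return pd.DataFrame({"best_cluster": assigned, "r": np.where(np.isfinite(best_r), best_r, np.nan)})


def matching_matrix(assignments: pd.DataFrame, query_clusters) -> pd.DataFrame:
    """Query-cluster x reference-cluster proportion table (rows sum to 1)."""
    qc = np.asarray(query_clusters)
    ref_ids = sorted(set(assignments["best_cluster"]) - {"unassigned"})
    cols = ref_ids + ["unassigned"]
    rows = {}
    for q in pd.unique(qc):
        sub = assignments.loc[qc == q, "best_cluster"]
        if len(sub) == 0:
            rows[q] = [np.nan] * len(cols)
        else:
            counts = sub.value_counts()
            rows[q] = [counts.get(c, 0) / len(sub) for c in cols]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)
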