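"""Bulk Aire-induced gene calling, the cluster-contribution decomposition,
and tissue-restricted antigen (TRA) calling.

The contribution of a cluster to a gene's bulk signal is the product of
the gene's mean expression in the cluster and the cluster's relative size;
the top contributor explains where a bulk Aire-induced gene's expression
actually comes from.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["call_bulk_aire_induced", "cluster_contribution", "call_tra"]


def call_bulk_aire_induced(
    bulk_table: pd.DataFrame, fc_max: float = 0.5, fdr_max: float = 0.05
) -> pd.Index:
    """Genes down in bulk KO vs WT: FC(KO/WT) < 0.5 and FDR < 0.05."""
    for col in ("fc_ko_over_wt", "fdr"):
        if col not in bulk_table.columns:
            raise ValueError(f"bulk table missing column {col!r}")
    keep = (bulk_table["fc_ko_over_wt"] < fc_max) & (bulk_table["fdr"] < fdr_max)
    return bulk_table.index[keep]


def cluster_contribution(
    layer, clusters, cluster_ids, relative_sizes, gene_names=None
) -> pd.DataFrame:
    """Genes x clusters contribution matrix plus the top contributor.

    contribution(g, c) = mean expression of g in c x relative size of c.
    ``relative_sizes`` must be nonnegative and sum to 1 over ``cluster_ids``.
    """
    sizes = np.asarray(relative_sizes, dtype=float)
    if np.any(sizes < 0) or not np.isclose(sizes.sum(), 1.0):
        raise ValueError("relative sizes must be nonnegative and sum to 1")
    x = np.asarray(layer, dtype=float)
    clusters = np.asarray(clusters)
    means = np.vstack([x[clusters == c].mean(axis=0) for c in cluster_ids]).T
    contrib = means * sizes[None, :]
    idx = pd.Index(gene_names if gene_names is not None else np.arange(x.shape[1]), name="gene")
    out = pd.DataFrame(contrib, index=idx, columns=list(cluster_ids))
    out["top_contributor"] = out[list(cluster_ids)].idxmax(axis=1)
    return out


def call_tra(
    organ_table: pd.DataFrame,
    max_organs: int = 3,
    expressed_threshold=None,
) -> pd.Index:
    """TRA genes: expressed (value > threshold) in 1 to ``max_organs`` organs.

    ``expressed_threshold`` may be a scalar or a per-gene vector; the
    default is each gene's median over its positive values (genes expressed
    nowhere are never TRA).
    """
    x = organ_table.to_numpy(dtype=float)
    if np.any(x < 0):
        raise ValueError("organ expression must be nonnegative")
    if expressed_threshold is None:
        thr = np.array(
            [np.median(row[row > 0]) if np.any(row > 0) else 0.0 for row in x]
        )
    else:
        thr = np.broadcast_to(np.asarray(expressed_threshold, dtype=float), (x.shape[0],))
    n_expressed = (x > thr[:, None]).sum(axis=1)
    keep = (n_expressed >= 1) & (n_expressed <= max_organs)
    return organ_table.index[keep]
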