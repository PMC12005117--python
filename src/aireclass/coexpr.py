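"""Gene-gene co-expression structure: correlation matrices, affinity-
propagation micro-clusters, high-correlation connections and their genomic
geometry.

Aire-driven genes co-express almost only as close intra-chromosomal pairs,
whereas Aire-enhanced genes form modules scattered across chromosomes; the
intra/inter-chromosomal contingency of r > 0.6 connections quantifies this
asymmetry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rankstats import TestResult, chi_square_2x2, rank_sum_test

__all__ = [
    "filter_correlation_genes",
    "correlation_matrix",
    "MicroClustering",
    "affinity_propagation",
    "net_similarity",
    "extract_connections",
    "connection_stats",
]


def filter_correlation_genes(
    counts, cells=None, min_reads: int = 5, min_cells: int = 5, gene_names=None
) -> np.ndarray:
    """Genes with raw count >= min_reads in >= min_cells of the selected cells."""
    x = np.asarray(counts)
    if cells is not None:
        x = x[np.asarray(cells)]
    keep = (x >= min_reads).sum(axis=0) >= min_cells
    if gene_names is not None:
        return np.asarray(gene_names)[keep]
    return np.flatnonzero(keep)


def correlation_matrix(layer, genes=None, cells=None) -> pd.DataFrame:
    """Pearson gene-gene correlation on a normalized layer.

    Constant genes are excluded (their correlation is undefined).  Index and
    columns carry the gene identifiers.
    """
    x = np.asarray(layer, dtype=float)
    if cells is not None:
        x = x[np.asarray(cells)]
    if x.shape[0] < 3:
        raise ValueError("need at least 3 cells")
    names = np.asarray(genes) if genes is not None else np.arange(x.shape[1])
    if genes is not None and len(names) != x.shape[1]:
        raise ValueError("gene name per column required")
    keep = x.std(axis=0) > 0
    x = x[:, keep]
    names = names[keep]
    r = np.corrcoef(x, rowvar=False)
    return pd.DataFrame(r, index=names, columns=names)


# ---------------------------------------------------------------------------
# affinity propagation
# ---------------------------------------------------------------------------

@dataclass
class MicroClustering:
    """AP result: exemplar per point, exemplar set, convergence flag."""

    exemplars: np.ndarray  # exemplar index per point
    exemplar_set: np.ndarray
    converged: bool
    n_iter: int

    @property
    def sizes(self) -> np.ndarray:
        _, counts = np.unique(self.exemplars, return_counts=True)
        return np.sort(counts)[::-1]

    @property
    def n_clusters(self) -> int:
        return len(self.exemplar_set)


def net_similarity(similarity: np.ndarray, exemplars: np.ndarray) -> float:
    """Sum of similarities to assigned exemplars plus exemplar preferences."""
    s = np.asarray(similarity, dtype=float)
    total = 0.0
    for i, e in enumerate(exemplars):
        total += s[i, e]
    return float(total)


def affinity_propagation(
    similarity,
    damping: float = 0.9,
    max_iter: int = 1000,
    conv_window: int = 100,
    preference: float | None = None,
) -> MicroClustering:
    """Exemplar-based clustering by responsibility/availability passing.

    ``preference`` (the self-similarity) defaults to the median off-diagonal
    similarity.  A point is an exemplar when its responsibility +
    availability diagonal is positive at convergence; every other point is
    assigned to the most similar exemplar.  If the exemplar set does not
    stabilize within ``max_iter`` iterations the best iterate is returned
    with ``converged=False``.
    """
    s = np.array(similarity, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError("similarity must be square")
    n = s.shape[0]
    if n == 1:
        return MicroClustering(np.zeros(1, dtype=int), np.zeros(1, dtype=int), True, 0)

    if preference is None:
        off = s[~np.eye(n, dtype=bool)]
        preference = float(np.median(off)) if off.size else 0.0
    np.fill_diagonal(s, preference)
    # tiny deterministic jitter breaks exact ties without visible effect
    rng = np.random.default_rng(0)
    s = s + 1e-12 * (s.max() - s.min() + 1.0) * rng.standard_normal((n, n))

    r = np.zeros((n, n))
    a = np.zeros((n, n))
    idx = np.arange(n)
    stable = 0
    last = None
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # responsibilities
        as_ = a + s
        m1 = as_.max(axis=1)
        am1 = as_.argmax(axis=1)
        as2 = as_.copy()
        as2[idx, am1] = -np.inf
        m2 = as2.max(axis=1)
        rnew = s - m1[:, None]
        rnew[idx, am1] = s[idx, am1] - m2
        r = damping * r + (1 - damping) * rnew

        # availabilities
        rp = np.maximum(r, 0.0)
        np.fill_diagonal(rp, r.diagonal())
        col = rp.sum(axis=0)
        anew = np.minimum(0.0, col[None, :] - rp)
        np.fill_diagonal(anew, col - rp.diagonal())
        a = damping * a + (1 - damping) * anew

        exemplar_mask = (r.diagonal() + a.diagonal()) > 0
        current = tuple(np.flatnonzero(exemplar_mask))
        if current == last and len(current) > 0:
            stable += 1
            if stable >= conv_window:
                break
        else:
            stable = 0
            last = current

    exemplar_set = np.flatnonzero((r.diagonal() + a.diagonal()) > 0)
    if exemplar_set.size == 0:  # degenerate: fall back to the best single exemplar
        exemplar_set = np.array([int(np.argmax(r.diagonal() + a.diagonal()))])
    exemplar_set = _refine_exemplars(s, exemplar_set)
    exemplars = exemplar_set[np.argmax(s[:, exemplar_set], axis=1)]
    exemplars[exemplar_set] = exemplar_set  # exemplars are their own exemplars
    converged = stable >= conv_window
    return MicroClustering(exemplars, exemplar_set, converged, n_iter)


def _refine_exemplars(s: np.ndarray, exemplar_set: np.ndarray, max_rounds: int = 50) -> np.ndarray:
    """Final refinement of the exemplar set, as in the canonical procedure:
    within each cluster, re-pick the member maximizing the summed similarity
    to the cluster, until the set is stable."""
    ex = np.array(sorted(exemplar_set))
    for _ in range(max_rounds):
        labels = np.argmax(s[:, ex], axis=1)
        for k, e in enumerate(ex):
            labels[e] = k
        new_ex = []
        for k in range(len(ex)):
            members = np.flatnonzero(labels == k)
            sums = s[np.ix_(members, members)].sum(axis=0)
            new_ex.append(int(members[np.argmax(sums)]))
        new_ex = np.array(sorted(set(new_ex)))
        if len(new_ex) == len(ex) and np.all(new_ex == ex):
            break
        ex = new_ex
    return ex


# ---------------------------------------------------------------------------
# connections
# ---------------------------------------------------------------------------

def extract_connections(
    corr: pd.DataFrame, gene_meta: pd.DataFrame, threshold: float = 0.6
) -> pd.DataFrame:
    """Unordered gene pairs with Pearson r strictly above the threshold.

    Each pair is annotated with chromosome identity and TSS-to-TSS distance
    (defined only for same-chromosome pairs).
    """
    genes = corr.index.to_numpy()
    missing = [g for g in genes if g not in gene_meta.index]
    if missing:
        raise ValueError(f"genes missing genomic annotation: {missing[:5]}")
    r = corr.to_numpy()
    iu = np.triu_indices(len(genes), k=1)
    sel = r[iu] > threshold
    ga = genes[iu[0][sel]]
    gb = genes[iu[1][sel]]
    rv = r[iu][sel]
    chrom_a = gene_meta.loc[ga, "chrom"].to_numpy()
    chrom_b = gene_meta.loc[gb, "chrom"].to_numpy()
    same = chrom_a == chrom_b
    dist = np.where(
        same,
        np.abs(gene_meta.loc[ga, "tss"].to_numpy() - gene_meta.loc[gb, "tss"].to_numpy()),
        np.nan,
    )
    return pd.DataFrame(
        {"gene_a": ga, "gene_b": gb, "r": rv, "same_chromosome": same, "distance_bp": dist}
    )


def connection_stats(
    connections_a: pd.DataFrame, connections_b: pd.DataFrame
) -> dict:
    """Intra/inter contingency and distance comparison between two classes.

    Returns per-class intra/inter counts and inter percentages, the Yates
    chi-square across classes, and per-class median intra-chromosomal
    distances with a rank-sum comparison of the distance samples.
    """
    def _counts(conn: pd.DataFrame) -> tuple[int, int]:
        if len(conn) == 0:
            return 0, 0
        intra = int(conn["same_chromosome"].sum())
        return intra, int(len(conn) - intra)

    ia, ea = _counts(connections_a)
    ib, eb = _counts(connections_b)
    out: dict = {
        "intra_a": ia,
        "inter_a": ea,
        "intra_b": ib,
        "inter_b": eb,
        "inter_pct_a": 100.0 * ea / (ia + ea) if ia + ea else float("nan"),
        "inter_pct_b": 100.0 * eb / (ib + eb) if ib + eb else float("nan"),
        "intra_pct_a": 100.0 * ia / (ia + ea) if ia + ea else float("nan"),
        "intra_pct_b": 100.0 * ib / (ib + eb) if ib + eb else float("nan"),
    }
    if min(ia + ea, ib + eb) == 0:
        out["chi_square"] = None
    else:
        try:
            out["chi_square"] = chi_square_2x2([[ia, ea], [ib, eb]])
        except ValueError:  # a zero margin (e.g. identical degenerate classes)
            out["chi_square"] = TestResult(statistic=0.0, p=1.0, method="chi_square_yates")
    da = connections_a.loc[connections_a["same_chromosome"], "distance_bp"].to_numpy()
    db = connections_b.loc[connections_b["same_chromosome"], "distance_bp"].to_numpy()
    out["median_distance_a"] = float(np.median(da)) if da.size else float("nan")
    out["median_distance_b"] = float(np.median(db)) if db.size else float("nan")
    out["distance_test"] = rank_sum_test(da, db) if da.size and db.size else None
    return out
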