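"""Normalization layers: per-cell log-normalization, gene-length-corrected
TMM (GeTMM), and group-level z-score standardization.

Matrices are cells x genes throughout, matching the AnnData convention.
GeTMM operates on a genes x samples table (bulk / full-length single-cell
protocols where gene length matters): counts are converted to reads per
kilobase, scaled by trimmed-mean-of-M-values factors, and expressed as
counts per million.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["lognormalize", "getmm", "group_zscore"]


def lognormalize(counts, scale: float = 10_000.0) -> np.ndarray:
    """Per-cell depth normalization: ln(1 + scale * count / cell_total).

    ``counts`` is cells x genes.  Cells with zero total map to all-zero rows.
    """
    x = np.asarray(counts, dtype=float)
    if np.any(x < 0):
        raise ValueError("counts must be nonnegative")
    totals = x.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = np.where(totals > 0, x * (scale / np.where(totals > 0, totals, 1.0)), 0.0)
    return np.log1p(norm)


# ---------------------------------------------------------------------------
# GeTMM
# ---------------------------------------------------------------------------

def _tmm_factor(
    obs: np.ndarray, ref: np.ndarray, m_trim: float, a_trim: float, weighted: bool = True
) -> float:
    """TMM scaling factor of ``obs`` against ``ref`` (both raw RPK vectors).

    Doubly trimmed (M by ``m_trim`` each tail, A by ``a_trim`` each tail)
    mean of log2 ratios; by default precision-weighted with inverse
    approximate (delta-method) variances, as in the canonical method.
    """
    n_obs = obs.sum()
    n_ref = ref.sum()
    keep = (obs > 0) & (ref > 0)
    if not np.any(keep):
        return 1.0
    o = obs[keep]
    r = ref[keep]
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    # delta-method weights, as in the canonical TMM description
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)

    n = m.size
    lo_m, hi_m = np.floor(n * m_trim) + 1, n - np.floor(n * m_trim)
    lo_a, hi_a = np.floor(n * a_trim) + 1, n - np.floor(n * a_trim)
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not np.any(keep2):
        return 1.0
    if weighted:
        f = np.sum(m[keep2] / w[keep2]) / np.sum(1.0 / w[keep2])
    else:
        f = np.mean(m[keep2])
    return float(2.0**f)


def getmm(
    counts,
    gene_lengths,
    log2: bool = False,
    m_trim: float = 0.30,
    a_trim: float = 0.05,
    weighted: bool = True,
) -> np.ndarray:
    """Gene-length-corrected TMM normalization of a genes x samples table.

    Counts are divided by gene length in kb (RPK), TMM scaling factors are
    computed on the RPK table (reference sample = the one whose upper
    quartile of positive RPK is closest to the mean upper quartile), and
    per-million scaling yields GeTMM values; ``log2=True`` returns
    log2(GeTMM + 1).
    """
    x = np.asarray(counts, dtype=float)
    lengths = np.asarray(gene_lengths, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("gene lengths must be positive")
    if x.ndim != 2 or x.shape[0] != lengths.size:
        raise ValueError("counts must be genes x samples with one length per gene")
    lib = x.sum(axis=0)
    if np.any(lib == 0):
        raise ValueError("zero-library sample")

    rpk = x / (lengths[:, None] / 1000.0)
    rpk_lib = rpk.sum(axis=0)
    # reference = sample whose depth-normalized upper quartile is closest to
    # the mean upper quartile (depth-invariant, as in the canonical method);
    # all-zero genes drop out of the factor via pairwise zero removal
    uq = np.quantile(rpk / rpk_lib[None, :], 0.75, axis=0)
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.array(
        [
            1.0
            if j == ref_idx
            else _tmm_factor(rpk[:, j], rpk[:, ref_idx], m_trim, a_trim, weighted)
            for j in range(x.shape[1])
        ]
    )
    # center factors so they multiply to 1, as the canonical method does
    factors = factors / np.exp(np.mean(np.log(factors)))

    eff_lib = rpk.sum(axis=0) * factors
    out = rpk / eff_lib[None, :] * 1e6
    if log2:
        out = np.log2(out + 1.0)
    return out


def group_zscore(layer, groups) -> pd.DataFrame:
    """Z-score standardization of per-group mean expression across groups.

    ``layer`` is cells x genes; ``groups`` assigns one group per cell.
    Returns a groups x genes frame: per gene, (group mean - mean of group
    means) / SD of group means (sample SD, the R ``scale()`` convention);
    genes whose group means are all equal get zeros.
    """
    x = np.asarray(layer, dtype=float)
    groups = np.asarray(groups)
    if x.shape[0] != groups.size:
        raise ValueError("one group label per cell required")
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    means = np.vstack([x[groups == g].mean(axis=0) for g in labels])
    center = means.mean(axis=0)
    sd = means.std(axis=0, ddof=1)  # sample SD across groups (R scale())
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (means - center) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.DataFrame(z, index=pd.Index(labels, name="group"))
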