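"""Transcription-factor expression vs motif-activity correlation with a
dual permutation null.

The correlation between a TF's cluster-mean transcript abundance and its
cluster-mean motif-activity score is tested against two nulls: shuffled
cluster labels of the activity vector, and substituted activity vectors of
other TFs.  The reported p value is the larger (least significant) of the
two permutation Z-test p values — a deliberately conservative rule.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .rankstats import auroc, perm_z_test

__all__ = [
    "cluster_mean_profiles",
    "tf_activity_correlation",
    "tf_perm_significance",
    "select_characteristic_tfs",
]


def cluster_mean_profiles(matrix, clusters, cluster_ids=None) -> np.ndarray:
    """clusters x features mean matrix."""
    x = np.asarray(matrix, dtype=float)
    clusters = np.asarray(clusters)
    if cluster_ids is None:
        cluster_ids = list(pd.unique(clusters))
    return np.vstack([x[clusters == c].mean(axis=0) for c in cluster_ids])


def _pearson(u: np.ndarray, v: np.ndarray) -> float:
    su, sv = u.std(), v.std()
    if su == 0 or sv == 0:
        return float("nan")
    return float(np.corrcoef(u, v)[0, 1])


def tf_activity_correlation(expr_means: np.ndarray, act_means: np.ndarray) -> pd.Series:
    """Pearson r per TF between cluster-mean expression and activity.

    Both inputs are clusters x TFs with matching columns.  Constant vectors
    give NaN.
    """
    e = np.asarray(expr_means, dtype=float)
    a = np.asarray(act_means, dtype=float)
    if e.shape != a.shape:
        raise ValueError("expression and activity means must align")
    if e.shape[0] < 3:
        raise ValueError("need at least 3 clusters")
    return pd.Series([_pearson(e[:, j], a[:, j]) for j in range(e.shape[1])], name="r")


def tf_perm_significance(
    expression,
    activity,
    clusters,
    tf_names=None,
    n_perm: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation significance of the expression-activity correlation.

    Null 1 shuffles the cluster labels of the activity vector; null 2
    substitutes the activity vectors of ``n_perm`` other TFs sampled without
    replacement.  Each null yields a Z-test p; p_final is their maximum.
    """
    if n_perm < 2:
        raise ValueError("need n_perm >= 2")
    rng = np.random.default_rng(seed)
    e_means = cluster_mean_profiles(expression, clusters)
    a_means = cluster_mean_profiles(activity, clusters)
    n_clusters, n_tfs = e_means.shape
    names = pd.Index(tf_names if tf_names is not None else np.arange(n_tfs), name="tf")

    rows = []
    for j in range(n_tfs):
        r_obs = _pearson(e_means[:, j], a_means[:, j])
        if np.isnan(r_obs):
            rows.append((r_obs, 1.0, 1.0, 1.0, True))
            continue
        perm_label = np.array(
            [
                _pearson(e_means[:, j], a_means[rng.permutation(n_clusters), j])
                for _ in range(n_perm)
            ]
        )
        others = np.delete(np.arange(n_tfs), j)
        k = min(n_perm, others.size)
        sub = rng.choice(others, size=k, replace=False)
        perm_tf = np.array([_pearson(e_means[:, j], a_means[:, o]) for o in sub])

        res1 = perm_z_test(r_obs, perm_label[~np.isnan(perm_label)])
        res2 = perm_z_test(r_obs, perm_tf[~np.isnan(perm_tf)])
        degenerate = bool(res1.extra.get("degenerate") or res2.extra.get("degenerate"))
        rows.append((r_obs, res1.p, res2.p, max(res1.p, res2.p), degenerate))
    return pd.DataFrame(
        rows, columns=["r", "p_label_perm", "p_tf_perm", "p_final", "degenerate"], index=names
    )


def select_characteristic_tfs(
    corr_table: pd.DataFrame,
    expression,
    clusters,
    tf_names=None,
    r_min: float = 0.4,
    auc_min: float = 0.75,
) -> pd.DataFrame:
    """Top characteristic TF per cluster: |r| > r_min and one-vs-rest
    AUC > auc_min on TF expression, ranked by AUC.

    Returns one row per cluster (tf, auc, r); clusters with no qualifying
    TF appear with tf = None.
    """
    x = np.asarray(expression, dtype=float)
    clusters = np.asarray(clusters)
    names = pd.Index(tf_names if tf_names is not None else np.arange(x.shape[1]))
    ids = list(pd.unique(clusters))

    qualifying = corr_table.index[(corr_table["r"].abs() > r_min)]
    rows = []
    for c in ids:
        mask = clusters == c
        best = None
        for tf in qualifying:
            j = names.get_loc(tf)
            auc = auroc(x[mask, j], x[~mask, j])
            if auc > auc_min and (best is None or auc > best[1]):
                best = (tf, auc)
        if best is None:
            rows.append((c, None, np.nan, np.nan))
        else:
            rows.append((c, best[0], best[1], corr_table.loc[best[0], "r"]))
    return pd.DataFrame(rows, columns=["cluster", "tf", "auc", "r"]).set_index("cluster")
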