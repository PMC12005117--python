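import itertools

import numpy as np
import pytest

import aireclass as ac


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition synthetic dataset, shared across tests."""
    return ac.simulate_dataset(ac.SimParams(seed=1))


@pytest.fixture(scope="session")
def default_result(default_dataset):
    """DEG + attribution + class labels on the shared dataset."""
    return ac.classify_dataset(default_dataset)


@pytest.fixture(scope="session")
def truth(default_dataset):
    return default_dataset.var.set_index("gene_id")["truth_class"]


# ---------------------------------------------------------------------------
# independent oracles (deliberately written apart from the implementation)
# ---------------------------------------------------------------------------

def brute_force_ranksum_p(x, y):
    """Two-sided exact rank-sum p by enumerating every labeling of the
    pooled sample into groups of sizes (n1, n2)."""
    from scipy.stats import rankdata

    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = rankdata(pooled)
    w_obs = ranks[:n1].sum()
    lo = hi = total = 0
    for labels in itertools.combinations(range(len(pooled)), n1):
        w = sum(ranks[i] for i in labels)
        lo += w <= w_obs + 1e-9
        hi += w >= w_obs - 1e-9
        total += 1
    return min(1.0, 2.0 * min(lo, hi) / total)


def exhaustive_net_similarity(s):
    """Best achievable net similarity over every exemplar subset."""
    n = s.shape[0]
    best = -np.inf
    for k in range(1, n + 1):
        for subset in itertools.combinations(range(n), k):
            ex = np.array(subset)
            assign = ex[np.argmax(s[:, ex], axis=1)]
            assign[ex] = ex
            value = sum(s[i, assign[i]] for i in range(n))
            best = max(best, value)
    return best


def module_structured_similarity(rng):
    """Random gene-gene correlation instance with latent module structure,
    n <= 8, preference (median off-diagonal) on the diagonal."""
    n = int(rng.integers(2, 9))
    k = int(rng.integers(1, 4))
    labels = rng.integers(0, k, n)
    base = rng.standard_normal((k, 30))
    data = base[labels] + 0.6 * rng.standard_normal((n, 30))
    s = np.corrcoef(data)
    off = s[~np.eye(n, dtype=bool)]
    np.fill_diagonal(s, np.median(off) if off.size else 0.0)
    return s
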