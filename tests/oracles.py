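"""Independent reference implementations used to cross-check the package.

These deliberately avoid the package's own code paths: plain loops over
dense matrices and exhaustive enumeration at small n.
"""

import itertools

import numpy as np
from scipy import stats


def exact_ranksum_p(x, y):
    """Two-sided rank-sum p by full enumeration of group labelings."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n = len(x)
    obs = ranks[:n].sum()
    mu = n * (len(pooled) + 1) / 2.0
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n):
        s = ranks[list(combo)].sum()
        total += 1
        if abs(s - mu) >= abs(obs - mu) - 1e-9:
            count += 1
    return count / total


def r2_matrix(dose):
    """Dense pairwise dosage r^2 with mean imputation of missing values."""
    filled = np.where(np.isnan(dose),
                      np.nanmean(dose, axis=0, keepdims=True), dose)
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(filled.T)
    return np.nan_to_num(r, nan=0.0) ** 2


def brute_force_clump(vids, chrom, pos, p, in_set, r2, window, r2_max):
    """Reference greedy sweep: explicit priority sort over a precomputed
    dense r^2 matrix."""
    order = sorted(range(len(vids)),
                   key=lambda i: (not in_set[i], p[i], pos[i], vids[i]))
    removed = set()
    retained = []
    for i in order:
        if i in removed:
            continue
        retained.append(i)
        removed.add(i)
        for j in order:
            if j in removed or chrom[j] != chrom[i]:
                continue
            if abs(pos[j] - pos[i]) <= window and r2[i, j] > r2_max:
                removed.add(j)
    return [vids[i] for i in retained]
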