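"""Small-sample statistics shared by the spectrum and cohort modules.

Cohorts of the kind this package targets have a handful of samples per arm,
where the asymptotic Mann-Whitney approximation (scipy's fallback whenever
ties occur) is noticeably conservative. For small groups the two-sided
p-value is therefore computed by full enumeration of the permutation
distribution of the U statistic, with the standard half-credit for ties —
exact even in the presence of ties. Larger groups fall back to scipy.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations
from math import comb

import numpy as np
import scipy.stats as st

#: Enumerate exactly when the number of group-A assignments is at most this.
MAX_ENUMERATION = 200_000


@lru_cache(maxsize=32)
def _split_masks(n_total: int, n_a: int) -> np.ndarray:
    """Boolean matrix, one row per way of assigning n_a of n_total to group A."""
    masks = np.zeros((comb(n_total, n_a), n_total), dtype=bool)
    for row, idx in enumerate(combinations(range(n_total), n_a)):
        masks[row, list(idx)] = True
    return masks


def exact_rank_sum_p(a, b) -> float:
    """Two-sided rank-sum (Mann-Whitney) p-value, exact for small groups.

    The U statistic counts pairs where an A value exceeds a B value, ties
    counting one half. The p-value is the permutation probability of a U at
    least as far from its mean as observed.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_a, n_b = len(a), len(b)
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups must be non-empty")
    if comb(n_a + n_b, n_a) > MAX_ENUMERATION:
        return float(st.mannwhitneyu(a, b, alternative="two-sided").pvalue)

    pooled = np.concatenate([a, b])
    greater = (pooled[:, None] > pooled[None, :]).astype(float)
    greater += 0.5 * (pooled[:, None] == pooled[None, :])

    masks = _split_masks(n_a + n_b, n_a).astype(float)
    # U of every split: sum of greater[i, j] over i in A, j in B
    u_all = ((masks @ greater) * (1.0 - masks)).sum(axis=1)
    mid = n_a * n_b / 2.0
    u_obs = float(greater[:n_a, n_a:].sum())
    observed_dev = abs(u_obs - mid)
    return float(np.mean(np.abs(u_all - mid) >= observed_dev - 1e-12))


def rank_sum_statistic(a, b) -> float:
    """The Mann-Whitney U statistic of group A over group B (ties half-credit)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(
        ((a[:, None] > b[None, :]) + 0.5 * (a[:, None] == b[None, :])).sum()
    )
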