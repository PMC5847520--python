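"""Independent brute-force oracles shared by the test modules."""

from itertools import combinations

import numpy as np
from scipy import stats as sps


def exact_rank_sum_oracle(a, b):
    """Two-sided p of the rank-sum test by exhaustive assignment enumeration."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = sps.rankdata(pooled)
    obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for idx in combinations(range(len(pooled)), n1):
        r = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        us.append(r)
    us = np.array(us)
    p_low = (us <= obs + 1e-12).mean()
    p_high = (us >= obs - 1e-12).mean()
    return min(1.0, 2 * min(p_low, p_high))
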