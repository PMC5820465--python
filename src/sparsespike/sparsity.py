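"""Distribution of a neuron's target count on a randomly selected rank.

Under uniform random connectivity with K targets per neuron distributed
round-robin over M ranks, each target lands on a given rank with probability
1/M independently, so the per-rank target count is Binomial(K, 1/M).  The
three regimes of the resulting P(0), P(1), P(>=2) curves as M grows explain
why source-routed spike exchange stops scaling: beyond K ~ M most spikes
collected on a rank have no local target there.

The pmf conditions on the out-degree being exactly K; the benchmark
generator fixes the *in*-degree instead, so realised out-degrees are
themselves Binomial(N*K, 1/N) with mean K — the Monte-Carlo check samples
those realised out-degrees.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["target_count_pmf", "regime_curves"]


def target_count_pmf(K: int, M: int, n) -> float | np.ndarray:
    """Probability that a neuron with K targets has exactly ``n`` on one of M ranks.

    Evaluated in log space (`binom.logpmf`) for numerical safety at large K
    and M.  Vectorises over ``n``.
    """
    if K < 0 or M < 1:
        raise ValueError("require K >= 0 and M >= 1")
    n_arr = np.asarray(n)
    if np.any((n_arr < 0) | (n_arr > K)):
        raise ValueError("target count n must lie in [0, K]")
    out = np.exp(stats.binom.logpmf(n_arr, K, 1.0 / M))
    return float(out) if np.isscalar(n) else out


def regime_curves(K: int, M_list) -> dict[str, np.ndarray]:
    """P(0), P(1) and P(>=2) local targets for each rank count in ``M_list``.

    P(>=2) is computed as 1 - P(0) - P(1); each row sums to one by
    construction.  P(0) is non-decreasing and P(>=2) non-increasing in M.
    """
    M_arr = np.asarray(list(M_list), dtype=np.int64)
    p0 = np.array([target_count_pmf(K, int(m), 0) for m in M_arr])
    p1 = np.array([target_count_pmf(K, int(m), 1) for m in M_arr])
    p_multi = 1.0 - p0 - p1
    return {"M": M_arr, "P0": p0, "P1": p1, "P_multi": p_multi}
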