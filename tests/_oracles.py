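"""Independent brute-force oracles, written separately from the library code.

Plain-Python direct summation only; nothing here imports from lfpac, so these
stay an independent check of the pipeline's histogram + KL path.
"""

import math
from typing import Sequence


def mi_from_distribution(p: Sequence[float]) -> float:
    """Direct-summation KL-to-uniform divided by log(number of bins)."""
    n = len(p)
    kl = 0.0
    for pj in p:
        if pj > 0:
            kl += pj * math.log(pj * n)
    return max(kl, 0.0) / math.log(n)


def mi_from_series(phase: Sequence[float], amplitude: Sequence[float],
                   n_bins: int = 18) -> float:
    """Direct histogram of amplitudes by phase bin, then the KL sum."""
    sums = [0.0] * n_bins
    counts = [0] * n_bins
    two_pi = 2.0 * math.pi
    for ph, am in zip(phase, amplitude):
        j = int((ph % two_pi) / two_pi * n_bins)
        if j >= n_bins:
            j = n_bins - 1
        sums[j] += am
        counts[j] += 1
    means = [s / c if c else 0.0 for s, c in zip(sums, counts)]
    total = sum(means)
    if total <= 0:
        p = [1.0 / n_bins] * n_bins
    else:
        p = [m / total for m in means]
    return mi_from_distribution(p)


def ranksum_exact_p_less(a: Sequence[float], b: Sequence[float]) -> float:
    """P(rank sum of a group of size len(a) <= observed) by full enumeration."""
    from itertools import combinations

    pooled = sorted(list(a) + list(b))
    # ranks 1..n; assumes no ties
    rank_of = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(rank_of[v] for v in a)
    n, na = len(pooled), len(a)
    hits = total = 0
    for combo in combinations(range(1, n + 1), na):
        total += 1
        if sum(combo) <= w_obs:
            hits += 1
    return hits / total
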