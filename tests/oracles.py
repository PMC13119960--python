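"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the vectorized code paths of the package: plain
loops, two-pass formulas, and explicit enumeration.
"""

import math

import numpy as np


def brute_pearson(x, y) -> float:
    """Two-pass product-moment correlation with explicit loops."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def naive_greedy_cluster(matrix, r_threshold=0.9):
    """Literal re-implementation of the iterative reference-gene procedure.

    ``matrix`` is genes x samples (pandas). Returns a list of member-id lists
    in discovery order, singletons included.
    """
    remaining = list(matrix.index)
    clusters = []
    while remaining:
        ref = remaining[0]
        members = [ref]
        for g in remaining[1:]:
            x = matrix.loc[ref].to_numpy(dtype=float)
            y = matrix.loc[g].to_numpy(dtype=float)
            if np.std(y) == 0:
                continue
            if brute_pearson(x, y) > r_threshold:
                members.append(g)
        clusters.append(members)
        remaining = [g for g in remaining if g not in members]
    return clusters


def brute_hypergeom_upper_tail(k, universe, n_marker, n_cluster) -> float:
    """P(X >= k) by direct summation of the hypergeometric mass."""
    total = 0.0
    for i in range(k, min(n_marker, n_cluster) + 1):
        total += (
            math.comb(n_marker, i)
            * math.comb(universe - n_marker, n_cluster - i)
            / math.comb(universe, n_cluster)
        )
    return total
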