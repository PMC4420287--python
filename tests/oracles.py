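"""Independent reference implementations used as test oracles.

These deliberately avoid the code paths they check: the hypergeometric
oracle uses exact rational arithmetic, the connected-subset oracle uses
powerset enumeration, and the Welch oracle comes from statsmodels.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import networkx as nx


def exact_two_sided_hypergeom(x: int, N: int, K: int, n: int) -> Fraction:
    """Minimum-likelihood two-sided hypergeometric p as an exact rational."""
    denom = comb(N, n)
    lo, hi = max(0, n + K - N), min(K, n)
    w_x = comb(K, x) * comb(N - K, n - x)
    total = sum(
        comb(K, j) * comb(N - K, n - j)
        for j in range(lo, hi + 1)
        if comb(K, j) * comb(N - K, n - j) <= w_x
    )
    return Fraction(total, denom)


def all_connected_subsets(graph: nx.Graph, k_max: int | None = None):
    """Every connected induced vertex subset, by brute powerset enumeration."""
    nodes = sorted(graph.nodes)
    limit = len(nodes) if k_max is None else min(k_max, len(nodes))
    for k in range(1, limit + 1):
        for combo in itertools.combinations(nodes, k):
            sub = graph.subgraph(combo)
            if k == 1 or nx.is_connected(sub):
                yield frozenset(combo)


def welch_p(case, control) -> float:
    """Welch two-sided p from statsmodels (reference implementation)."""
    from statsmodels.stats.weightstats import ttest_ind

    _, p, _ = ttest_ind(case, control, usevar="unequal")
    return float(p)
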