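"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: cycle counting by
exhaustive simple-cycle enumeration, modularity by direct summation over an
explicitly enumerated partition, Fisher's p by exact hypergeometric tail
summation with rational arithmetic, and best-partition search by enumerating
all set partitions.
"""

from fractions import Fraction
from math import comb

import networkx as nx


def count_4cycles_through_edge(graph: nx.Graph, i, j) -> int:
    """Number of simple 4-cycles that use the edge (i, j), by enumeration."""
    count = 0
    for cycle in nx.simple_cycles(graph, length_bound=4):
        if len(cycle) != 4 or i not in cycle or j not in cycle:
            continue
        pos_i, pos_j = cycle.index(i), cycle.index(j)
        if (pos_i - pos_j) % 4 in (1, 3):  # adjacent in the cycle
            count += 1
    return count


def direct_modularity(graph: nx.Graph, modules) -> float:
    """Newman modularity by direct summation over the given node groups."""
    L = graph.number_of_edges()
    q = 0.0
    for group in modules:
        group = set(group)
        l_w = sum(1 for a, b in graph.edges() if a in group and b in group)
        d_s = sum(graph.degree(n) for n in group)
        q += l_w / L - (d_s / (2 * L)) ** 2
    return q


def set_partitions(items):
    """All set partitions of ``items`` (restricted-growth enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partial in set_partitions(rest):
        for k in range(len(partial)):
            yield partial[:k] + [[first] + partial[k]] + partial[k + 1 :]
        yield [[first]] + partial


def best_partition_exhaustive(graph: nx.Graph):
    """Globally modularity-optimal partition by exhaustive search."""
    best_q, best = float("-inf"), None
    for partition in set_partitions(sorted(graph.nodes())):
        q = direct_modularity(graph, partition)
        if q > best_q:
            best_q, best = q, partition
    return best_q, best


def fisher_exact_two_sided(n11: int, n12: int, n21: int, n22: int) -> Fraction:
    """Two-sided Fisher exact p by hypergeometric tail summation.

    With margins fixed, sums the probabilities of all tables whose point
    probability does not exceed the observed table's (exact rational
    arithmetic, so ties are handled without floating-point fuzz).
    """
    row1, row2 = n11 + n12, n21 + n22
    col1 = n11 + n21
    n = row1 + row2
    denom = comb(n, col1)
    lo, hi = max(0, col1 - row2), min(col1, row1)

    def pmf(k: int) -> Fraction:
        return Fraction(comb(row1, k) * comb(row2, col1 - k), denom)

    p_obs = pmf(n11)
    return sum((pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs),
               start=Fraction(0))
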