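"""Modularity measures and interface-weighted greedy module detection.

Two partition scores are provided.  ``m_ppi`` is Newman modularity,

    Q = sum_s [ l_W,s / L - (d_s / 2L)^2 ],

the excess of the observed within-module edge fraction over the
degree-preserving chance expectation.  ``m_dli_ddi`` is the interface-aware
revision in which strong domain-domain interactions (DDIs) are credited for
lying inside modules and weak domain-motif interactions (DLIs) are credited
for lying on module boundaries, each family against its own chance term:

    M = sum_s [ l_WD,s / l_D - (d_s^D / 2 l_D)^2
              + l_BL,s / l_L - 2 q_s (1 - q_s) ],   q_s = d_s^L / (2 l_L)

where l_WD,s counts within-module DDIs, l_BL,s counts DLIs with exactly one
endpoint in module s, l_D and l_L are the network-wide DDI and DLI counts and
d_s^D, d_s^L are the label-specific degree sums of module s.  The boundary
chance term 2 q (1 - q) is the configuration-model probability that an edge
has exactly one endpoint in the module.

Module detection is agglomerative greedy modularity optimisation (CNM):
starting from singletons, repeatedly apply the merge of two connected modules
with the greatest modularity gain, and read the partition off the trace step
with the highest modularity.  The interface-weighted variant runs the same
algorithm on weighted Newman modularity with DDIs up-weighted (default 100)
and DLIs down-weighted (default 0.1), so strong interactions drive early
merges and weak cross-module interactions are deferred.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from math import comb
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

from .network import DDI, DLI, AnnotatedNetwork, AnnotationTable

logger = logging.getLogger(__name__)


@dataclass
class Partition:
    """Disjoint, exhaustive assignment of proteins to integer module ids."""

    assignment: dict[str, int]
    excluded: set[int] = field(default_factory=set)

    def modules(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for node, mod in self.assignment.items():
            out.setdefault(mod, set()).add(node)
        return out

    def active_modules(self) -> dict[int, set[str]]:
        return {m: s for m, s in self.modules().items() if m not in self.excluded}

    @classmethod
    def from_groups(cls, groups: Iterable[Iterable[str]]) -> "Partition":
        assignment: dict[str, int] = {}
        for i, group in enumerate(groups):
            for node in group:
                assignment[node] = i
        return cls(assignment=assignment)


@dataclass(frozen=True)
class WeightScheme:
    """Interface weights for the detection algorithm (strong/weak/other)."""

    w_ddi: float = 100.0
    w_dli: float = 0.1
    w_other: float = 1.0

    def __post_init__(self) -> None:
        if min(self.w_ddi, self.w_dli, self.w_other) <= 0:
            raise ValueError("weights must be positive")

    def of(self, label: str | None) -> float:
        if label == DDI:
            return self.w_ddi
        if label == DLI:
            return self.w_dli
        return self.w_other


def _check_partition(net: AnnotatedNetwork, partition: Partition) -> None:
    nodes = set(net.graph.nodes())
    assigned = set(partition.assignment)
    if not nodes <= assigned:
        missing = sorted(nodes - assigned)[:5]
        raise ValueError(f"partition does not cover the network (e.g. {missing})")


def newman_modularity(
    net: AnnotatedNetwork,
    partition: Partition,
    weights: WeightScheme | None = None,
) -> float:
    """(Weighted) Newman modularity Q of a partition."""
    _check_partition(net, partition)
    wfun = weights.of if weights is not None else (lambda label: 1.0)
    total = 0.0
    within: dict[int, float] = {}
    strength: dict[int, float] = {}
    assign = partition.assignment
    for a, b, data in net.graph.edges(data=True):
        w = wfun(data.get("label"))
        total += w
        ma, mb = assign[a], assign[b]
        strength[ma] = strength.get(ma, 0.0) + w
        strength[mb] = strength.get(mb, 0.0) + w
        if ma == mb:
            within[ma] = within.get(ma, 0.0) + w
    if total == 0:
        raise ValueError("network has no edges")
    q = 0.0
    for mod in set(strength) | set(within):
        q += within.get(mod, 0.0) / total - (strength.get(mod, 0.0) / (2 * total)) ** 2
    return q


def m_ppi(net: AnnotatedNetwork, partition: Partition) -> float:
    """Topological modularity M_PPI (unweighted Newman modularity)."""
    return newman_modularity(net, partition)


@dataclass
class ModularityTerms:
    ddi_term: float
    dli_term: float
    l_d: int
    l_l: int
    per_module: dict[int, dict[str, float]]

    @property
    def value(self) -> float:
        return self.ddi_term + self.dli_term


def m_dli_ddi_terms(net: AnnotatedNetwork, partition: Partition) -> ModularityTerms:
    """Decomposed interface-aware modularity (see module docstring).

    If a label family is absent its term contributes 0, with a warning.
    """
    _check_partition(net, partition)
    assign = partition.assignment
    mods = sorted(set(assign[n] for n in net.graph.nodes()))
    l_d = l_l = 0
    within_ddi: dict[int, int] = {m: 0 for m in mods}
    boundary_dli: dict[int, int] = {m: 0 for m in mods}
    deg_ddi: dict[int, int] = {m: 0 for m in mods}
    deg_dli: dict[int, int] = {m: 0 for m in mods}
    for a, b, data in net.graph.edges(data=True):
        label = data.get("label")
        ma, mb = assign[a], assign[b]
        if label == DDI:
            l_d += 1
            deg_ddi[ma] += 1
            deg_ddi[mb] += 1
            if ma == mb:
                within_ddi[ma] += 1
        elif label == DLI:
            l_l += 1
            deg_dli[ma] += 1
            deg_dli[mb] += 1
            if ma != mb:
                boundary_dli[ma] += 1
                boundary_dli[mb] += 1
    if l_d == 0:
        warnings.warn("no DDI edges; DDI term contributes 0")
    if l_l == 0:
        warnings.warn("no DLI edges; DLI term contributes 0")
    ddi_term = dli_term = 0.0
    per_module: dict[int, dict[str, float]] = {}
    for m in mods:
        row: dict[str, float] = {
            "l_WD": within_ddi[m],
            "l_BL": boundary_dli[m],
            "d_D": deg_ddi[m],
            "d_L": deg_dli[m],
        }
        if l_d > 0:
            term = within_ddi[m] / l_d - (deg_ddi[m] / (2 * l_d)) ** 2
            row["ddi_term"] = term
            ddi_term += term
        if l_l > 0:
            q_s = deg_dli[m] / (2 * l_l)
            term = boundary_dli[m] / l_l - 2 * q_s * (1 - q_s)
            row["dli_term"] = term
            dli_term += term
        per_module[m] = row
    return ModularityTerms(ddi_term=ddi_term, dli_term=dli_term, l_d=l_d,
                           l_l=l_l, per_module=per_module)


def m_dli_ddi(net: AnnotatedNetwork, partition: Partition) -> float:
    """Interface-aware modularity M_DLI/DDI of a partition."""
    return m_dli_ddi_terms(net, partition).value


# ---------------------------------------------------------------------------
# Greedy agglomerative detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MergeEvent:
    step: int
    module_a: int
    module_b: int
    delta_q: float
    q_after: float


@dataclass
class GreedyResult:
    partition: Partition
    trace: list[MergeEvent]
    modularity: float
    best_step: int  # number of merges applied in the returned partition
    node_order: list[str]

    def merge_step_of(self, node_a: str, node_b: str) -> int | None:
        """Trace step at which the two nodes first share a module (1-based)."""
        parent = {i: i for i in range(len(self.node_order))}

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        index = {n: i for i, n in enumerate(self.node_order)}
        ia, ib = index[node_a], index[node_b]
        for ev in self.trace:
            ra, rb = find(ev.module_a), find(ev.module_b)
            parent[max(ra, rb)] = min(ra, rb)
            if find(ia) == find(ib):
                return ev.step
        return None


def greedy_modules(
    net: AnnotatedNetwork,
    weights: WeightScheme | None = None,
) -> GreedyResult:
    """Agglomerative greedy (weighted) modularity optimisation.

    Starting from singleton modules, repeatedly merge the pair of connected
    modules with the greatest modularity change (ties broken toward the
    smallest pair of module ids, making runs deterministic), until no merge
    remains; the returned partition is the trace prefix with the highest
    modularity.  Connected components never merge with each other.
    """
    graph = net.graph
    nodes = sorted(graph.nodes())
    if not nodes:
        raise ValueError("empty network")
    wfun = weights.of if weights is not None else (lambda label: 1.0)
    index = {n: i for i, n in enumerate(nodes)}

    total = 0.0
    strength = [0.0] * len(nodes)
    pair_w: dict[int, dict[int, float]] = {i: {} for i in range(len(nodes))}
    for u, v, data in graph.edges(data=True):
        w = wfun(data.get("label"))
        iu, iv = index[u], index[v]
        total += w
        strength[iu] += w
        strength[iv] += w
        lo, hi = min(iu, iv), max(iu, iv)
        pair_w[lo][hi] = pair_w[lo].get(hi, 0.0) + w
        pair_w[hi][lo] = pair_w[hi].get(lo, 0.0) + w
    if total == 0:
        raise ValueError("network has no edges")

    a = [s / (2 * total) for s in strength]  # strength fractions
    q = -sum(x * x for x in a)  # singleton-partition modularity
    trace: list[MergeEvent] = []
    merges: list[tuple[int, int]] = []
    q_history = [q]
    active = set(range(len(nodes)))

    step = 0
    while True:
        best_dq = None
        best_pair: tuple[int, int] | None = None
        for ci in sorted(active):
            nbrs = pair_w[ci]
            for cj in sorted(nbrs):
                if cj <= ci:
                    continue
                dq = nbrs[cj] / total - 2 * a[ci] * a[cj]
                if best_dq is None or dq > best_dq:
                    best_dq = dq
                    best_pair = (ci, cj)
        if best_pair is None:
            break
        ci, cj = best_pair
        step += 1
        q += best_dq
        trace.append(MergeEvent(step=step, module_a=ci, module_b=cj,
                                delta_q=best_dq, q_after=q))
        merges.append((ci, cj))
        q_history.append(q)
        # merge cj into ci
        a[ci] += a[cj]
        for ck, w in pair_w[cj].items():
            if ck == ci:
                continue
            pair_w[ci][ck] = pair_w[ci].get(ck, 0.0) + w
            pair_w[ck][ci] = pair_w[ck].get(ci, 0.0) + w
            del pair_w[ck][cj]
        pair_w[ci].pop(cj, None)
        pair_w[cj] = {}
        active.remove(cj)

    best_step = int(np.argmax(q_history))  # first maximiser on ties
    parent = {i: i for i in range(len(nodes))}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for ci, cj in merges[:best_step]:
        ra, rb = find(ci), find(cj)
        parent[max(ra, rb)] = min(ra, rb)
    assignment = {n: find(index[n]) for n in nodes}
    partition = Partition(assignment=assignment)
    return GreedyResult(
        partition=partition,
        trace=trace,
        modularity=float(q_history[best_step]),
        best_step=best_step,
        node_order=nodes,
    )


def filter_small_modules(partition: Partition, min_size: int = 3) -> Partition:
    """Flag modules smaller than ``min_size`` as excluded from statistics.

    Proteins keep their module assignment; pair-only (and singleton) modules
    carry too little internal structure to score.
    """
    sizes: dict[int, int] = {}
    for mod in partition.assignment.values():
        sizes[mod] = sizes.get(mod, 0) + 1
    excluded = {m for m, k in sizes.items() if k < min_size}
    return Partition(assignment=dict(partition.assignment), excluded=excluded)


# ---------------------------------------------------------------------------
# Module quality
# ---------------------------------------------------------------------------

def annotation_jaccard(x: set[str], y: set[str]) -> float:
    union = x | y
    return len(x & y) / len(union) if union else 0.0


@dataclass
class QualityReport:
    per_module: dict[int, float]
    mean_quality: float
    baseline: float
    fold_increase: float
    n_excluded: int

    @property
    def values(self) -> np.ndarray:
        return np.array([self.per_module[m] for m in sorted(self.per_module)])


def module_quality(
    partition: Partition,
    annotations: AnnotationTable,
    min_size: int = 3,
) -> QualityReport:
    """Annotation coherence of detected modules.

    Per module the quality is the mean pairwise Jaccard similarity of the
    annotation sets of its annotated proteins; pairs with an unannotated
    member are skipped, and modules below ``min_size`` are excluded.  The
    fold increase compares the mean module quality against the mean
    similarity over all annotated protein pairs in the partition.
    """
    flagged = filter_small_modules(partition, min_size=min_size)
    per_module: dict[int, float] = {}
    for mod, members in flagged.active_modules().items():
        annotated = sorted(m for m in members if annotations.get(m))
        sims = [
            annotation_jaccard(annotations.terms[x], annotations.terms[y])
            for k, x in enumerate(annotated)
            for y in annotated[k + 1 :]
        ]
        if sims:
            per_module[mod] = float(np.mean(sims))
    if not per_module:
        raise ValueError("no module with an annotated protein pair")
    annotated_all = sorted(p for p in partition.assignment if annotations.get(p))
    base_sims = [
        annotation_jaccard(annotations.terms[x], annotations.terms[y])
        for k, x in enumerate(annotated_all)
        for y in annotated_all[k + 1 :]
    ]
    baseline = float(np.mean(base_sims)) if base_sims else float("nan")
    mean_quality = float(np.mean(list(per_module.values())))
    fold = mean_quality / baseline if baseline > 0 else float("inf")
    return QualityReport(
        per_module=per_module,
        mean_quality=mean_quality,
        baseline=baseline,
        fold_increase=fold,
        n_excluded=len(flagged.excluded),
    )


@dataclass
class QualityComparison:
    ks_statistic: float
    ks_p: float
    cohen_d: float


def compare_quality(report_a: QualityReport, report_b: QualityReport) -> QualityComparison:
    """Two-sample KS test and Cohen's d between module-quality distributions."""
    xa, xb = report_a.values, report_b.values
    if len(xa) < 2 or len(xb) < 2:
        raise ValueError("need at least 2 scored modules on each side")
    ks_stat, ks_p = stats.ks_2samp(xa, xb)
    na, nb = len(xa), len(xb)
    va, vb = np.var(xa, ddof=1), np.var(xb, ddof=1)
    pooled = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    d = 0.0 if pooled == 0 else float((np.mean(xa) - np.mean(xb)) / pooled)
    return QualityComparison(ks_statistic=float(ks_stat), ks_p=float(ks_p), cohen_d=d)


def adjusted_rand_index(labels_a: Mapping[str, int], labels_b: Mapping[str, int]) -> float:
    """Adjusted Rand index between two partitions of the same node set."""
    keys = sorted(labels_a)
    if sorted(labels_b) != keys:
        raise ValueError("partitions cover different node sets")
    table: dict[tuple[int, int], int] = {}
    row: dict[int, int] = {}
    col: dict[int, int] = {}
    for k in keys:
        i, j = labels_a[k], labels_b[k]
        table[(i, j)] = table.get((i, j), 0) + 1
        row[i] = row.get(i, 0) + 1
        col[j] = col.get(j, 0) + 1
    n = len(keys)
    sum_ij = sum(comb(v, 2) for v in table.values())
    sum_i = sum(comb(v, 2) for v in row.values())
    sum_j = sum(comb(v, 2) for v in col.values())
    expected = sum_i * sum_j / comb(n, 2)
    max_index = (sum_i + sum_j) / 2
    if max_index == expected:
        return 1.0
    return (sum_ij - expected) / (max_index - expected)
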