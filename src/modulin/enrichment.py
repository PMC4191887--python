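"""Within/between-module enrichment of DLIs and DDIs.

Biological module sets (functional terms, complexes, localizations) are
annotation-derived protein groups, pruned so that no two retained groups
overlap heavily.  Each labelled edge whose endpoints are both annotated is
within-module (identical membership sets), between-module (disjoint) or
overlapping (partial sharing).  A 2x2 contingency table of
{between, within} x {DLI, DDI} counts, with margin-product expected counts,
quantifies the enrichment of each cell; significance comes from Fisher's
exact test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

from scipy import stats

from .network import DDI, DLI, AnnotatedNetwork, AnnotationTable

logger = logging.getLogger(__name__)

WITHIN = "within"
BETWEEN = "between"
OVERLAPPING = "overlapping"


@dataclass
class ModuleSet:
    """Non-overlapping protein groups used as biological modules."""

    namespace: str
    groups: dict[str, set[str]]
    size_range: tuple[int, int] | None = None

    def membership(self, protein: str) -> set[str]:
        return {t for t, members in self.groups.items() if protein in members}

    def membership_index(self) -> dict[str, set[str]]:
        idx: dict[str, set[str]] = {}
        for term, members in self.groups.items():
            for p in members:
                idx.setdefault(p, set()).add(term)
        return idx


def prune_overlapping_groups(
    groups: Mapping[str, set[str]],
    jaccard_threshold: float = 0.5,
    size_range: tuple[int, int] | None = None,
    namespace: str = "functional",
) -> ModuleSet:
    """Drop small near-duplicate groups until no heavy overlap remains.

    Groups outside ``size_range`` are removed first.  Then, greedily from the
    largest group down, any group whose Jaccard overlap with an already-kept
    group exceeds the threshold is dropped (the smaller of the two; on a size
    tie the lexicographically later id).  The result is a fixpoint: applying
    the pruning again changes nothing.
    """
    candidates = {
        t: set(m)
        for t, m in groups.items()
        if size_range is None or size_range[0] <= len(m) <= size_range[1]
    }
    # largest first; ties keep the lexicographically earlier id
    order = sorted(candidates, key=lambda t: (-len(candidates[t]), t))
    kept: list[str] = []
    for term in order:
        members = candidates[term]
        ok = True
        for other in kept:
            inter = len(members & candidates[other])
            union = len(members | candidates[other])
            if union and inter / union > jaccard_threshold:
                ok = False
                break
        if ok:
            kept.append(term)
    return ModuleSet(
        namespace=namespace,
        groups={t: candidates[t] for t in kept},
        size_range=size_range,
    )


def module_set_from_annotations(
    table: AnnotationTable,
    jaccard_threshold: float = 0.5,
    size_range: tuple[int, int] | None = None,
) -> ModuleSet:
    return prune_overlapping_groups(
        table.by_term(),
        jaccard_threshold=jaccard_threshold,
        size_range=size_range,
        namespace=table.namespace,
    )


def classify_edge_position(
    edge: tuple[str, str],
    module_set: ModuleSet,
    membership_index: Mapping[str, set[str]] | None = None,
) -> str | None:
    """Position of an edge relative to the module set.

    Returns ``within`` when the two membership sets are identical, ``between``
    when they are disjoint, ``overlapping`` otherwise, and ``None`` when an
    endpoint is unannotated (such edges are excluded from counting).
    """
    idx = membership_index if membership_index is not None else module_set.membership_index()
    a, b = edge
    ma, mb = idx.get(a), idx.get(b)
    if not ma or not mb:
        return None
    if ma == mb:
        return WITHIN
    if not (ma & mb):
        return BETWEEN
    return OVERLAPPING


@dataclass
class ContingencyTable:
    """Counts of {between, within} x {DLI, DDI} interactions.

    Cell layout follows the convention n11 = between-DLI, n12 = between-DDI,
    n21 = within-DLI, n22 = within-DDI.
    """

    n11: int
    n12: int
    n21: int
    n22: int
    overlap_mode: str = "as_between"
    namespace: str = ""
    n_excluded_unannotated: int = 0
    n_overlapping: int = 0

    @property
    def total(self) -> int:
        return self.n11 + self.n12 + self.n21 + self.n22

    def expected(self) -> dict[str, float]:
        """Margin-product expected counts (row total x column total / N)."""
        n = self.total
        if n == 0:
            raise ValueError("empty contingency table")
        rows = {"between": self.n11 + self.n12, "within": self.n21 + self.n22}
        cols = {"DLI": self.n11 + self.n21, "DDI": self.n12 + self.n22}
        return {
            "between-DLI": rows["between"] * cols["DLI"] / n,
            "between-DDI": rows["between"] * cols["DDI"] / n,
            "within-DLI": rows["within"] * cols["DLI"] / n,
            "within-DDI": rows["within"] * cols["DDI"] / n,
        }

    def observed(self) -> dict[str, int]:
        return {
            "between-DLI": self.n11,
            "between-DDI": self.n12,
            "within-DLI": self.n21,
            "within-DDI": self.n22,
        }


def build_contingency(
    net: AnnotatedNetwork,
    module_set: ModuleSet,
    overlap_mode: str = "as_between",
) -> ContingencyTable:
    """Count labelled edges by position and label.

    Unclassified edges and edges with an unannotated endpoint are excluded;
    overlapping edges are folded into the within or between row according to
    ``overlap_mode`` (the fold changes only the rows, never the DLI/DDI column
    margins).
    """
    if overlap_mode not in ("as_within", "as_between"):
        raise ValueError(f"unknown overlap_mode {overlap_mode!r}")
    idx = module_set.membership_index()
    counts = {(BETWEEN, DLI): 0, (BETWEEN, DDI): 0, (WITHIN, DLI): 0, (WITHIN, DDI): 0}
    n_unannotated = 0
    n_overlap = 0
    for rec in net.edges():
        if rec.label not in (DDI, DLI):
            continue
        pos = classify_edge_position(rec.key, module_set, membership_index=idx)
        if pos is None:
            n_unannotated += 1
            continue
        if pos == OVERLAPPING:
            n_overlap += 1
            pos = WITHIN if overlap_mode == "as_within" else BETWEEN
        counts[(pos, rec.label)] += 1
    if n_unannotated:
        logger.info("excluded %d labelled edge(s) with unannotated endpoints",
                    n_unannotated)
    table = ContingencyTable(
        n11=counts[(BETWEEN, DLI)],
        n12=counts[(BETWEEN, DDI)],
        n21=counts[(WITHIN, DLI)],
        n22=counts[(WITHIN, DDI)],
        overlap_mode=overlap_mode,
        namespace=module_set.namespace,
        n_excluded_unannotated=n_unannotated,
        n_overlapping=n_overlap,
    )
    if table.total == 0:
        raise ValueError("no labelled edges with annotated endpoints")
    return table


@dataclass
class EnrichmentResult:
    table: ContingencyTable
    enrichment: dict[str, float | None] = field(default_factory=dict)
    odds_ratio: float = float("nan")
    fisher_p: float = 1.0

    @property
    def namespace(self) -> str:
        return self.table.namespace


def enrichment(table: ContingencyTable) -> EnrichmentResult:
    """Observed/expected enrichment per cell plus a two-sided Fisher p.

    A cell with zero expected count has no defined ratio and is reported as
    ``None``.
    """
    expected = table.expected()
    observed = table.observed()
    ratios: dict[str, float | None] = {}
    for cell, exp in expected.items():
        ratios[cell] = None if exp == 0 else observed[cell] / exp
    odds, p = stats.fisher_exact(
        [[table.n11, table.n12], [table.n21, table.n22]], alternative="two-sided"
    )
    return EnrichmentResult(
        table=table,
        enrichment=ratios,
        odds_ratio=float(odds),
        fisher_p=float(p),
    )
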