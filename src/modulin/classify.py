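"""Assign interface labels (DDI / DLI / unclassified) to network edges.

A PPI is DDI-eligible when the two proteins carry a pair of domains listed in
the accepted interacting-domain-pair catalog, and DLI-eligible when one
protein carries a linear-motif instance whose motif class names a cognate
domain present on the other protein.  Edges eligible under exactly one
criterion receive that label; edges eligible under both, or neither, remain
unclassified.

The accepted domain-pair catalog is the union of a structurally derived gold
standard and predicted pairs that pass a confidence-score cutoff.  Each
prediction method is weighted by its precision against the gold standard, the
confidence score of a pair is the precision-weighted vote over methods, and
the acceptance cutoff is chosen by maximising F1 on a grid.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .network import (
    DDI,
    DLI,
    UNCLASSIFIED,
    AnnotatedNetwork,
    ProteinRecord,
    canonical_edge,
)

logger = logging.getLogger(__name__)

Pair = tuple[str, str]


def _canon(pairs: Iterable[Pair]) -> set[Pair]:
    return {canonical_edge(a, b) for a, b in pairs}


# ---------------------------------------------------------------------------
# Domain-pair confidence scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MethodWeight:
    """Precision of one domain-pair prediction method against the gold set."""

    method: str
    weight: float
    tp: int
    fp: int


def method_precision(predictions: Iterable[Pair], gold: Iterable[Pair],
                     method: str = "") -> MethodWeight:
    """Weight a prediction method by its precision TP/(TP+FP).

    A method with no predictions gets weight 0 (it then never contributes to
    any confidence score).
    """
    preds = _canon(predictions)
    gold_set = _canon(gold)
    tp = len(preds & gold_set)
    fp = len(preds - gold_set)
    if tp + fp == 0:
        warnings.warn(f"method {method!r} made no predictions; weight set to 0")
        return MethodWeight(method=method, weight=0.0, tp=0, fp=0)
    return MethodWeight(method=method, weight=tp / (tp + fp), tp=tp, fp=fp)


def confidence_scores(
    predictions_by_method: Mapping[str, Iterable[Pair]],
    weights: Mapping[str, MethodWeight] | Mapping[str, float],
) -> dict[Pair, float]:
    """CS(i,j) = sum over methods of W_k * I_k(i,j).

    ``I_k`` is 1 when method ``k`` predicts the pair.  Every method appearing
    in the predictions must have a weight.
    """
    scores: dict[Pair, float] = {}
    for method, pairs in predictions_by_method.items():
        if method not in weights:
            raise KeyError(f"no weight for prediction method {method!r}")
        w = weights[method]
        w = w.weight if isinstance(w, MethodWeight) else float(w)
        for pair in _canon(pairs):
            scores[pair] = scores.get(pair, 0.0) + w
    return scores


@dataclass
class CutoffScan:
    """F1 scan over candidate confidence-score cutoffs CS_0.

    Positives at a cutoff are pairs with CS strictly greater than CS_0; ties
    at the cutoff count as negatives.  The selected cutoff maximises F1, with
    ties broken toward the smallest cutoff.
    """

    grid: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    selected: float

    def as_rows(self) -> list[dict]:
        return [
            {
                "cs0": float(self.grid[i]),
                "tp": int(self.tp[i]),
                "fp": int(self.fp[i]),
                "fn": int(self.fn[i]),
                "precision": float(self.precision[i]),
                "recall": float(self.recall[i]),
                "f1": float(self.f1[i]),
            }
            for i in range(len(self.grid))
        ]


def default_grid() -> np.ndarray:
    """CS_0 grid 0.00 .. 1.20 in 0.01 increments."""
    return np.round(np.arange(0, 121) * 0.01, 2)


def select_cutoff(
    scores: Mapping[Pair, float],
    gold: Iterable[Pair],
    grid: Sequence[float] | None = None,
) -> CutoffScan:
    """Scan CS_0 over the grid and select the F1-maximising cutoff.

    Recall is computed against the full gold set: gold pairs that never
    received a score count as false negatives at every cutoff.
    """
    gold_set = _canon(gold)
    if not gold_set:
        raise ValueError("gold standard set is empty")
    grid_arr = default_grid() if grid is None else np.asarray(grid, dtype=float)
    if all(s == 0 for s in scores.values()):
        warnings.warn("all confidence scores are zero; degenerate cutoff scan")
    keys = list(scores)
    vals = np.array([scores[k] for k in keys], dtype=float)
    is_gold = np.array([k in gold_set for k in keys], dtype=bool)
    n_gold = len(gold_set)
    tp = np.empty(len(grid_arr), dtype=int)
    fp = np.empty(len(grid_arr), dtype=int)
    for i, cs0 in enumerate(grid_arr):
        positive = vals > cs0
        tp[i] = int(np.sum(positive & is_gold))
        fp[i] = int(np.sum(positive & ~is_gold))
    fn = n_gold - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        pr = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), 0.0)
        rc = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1), 0.0)
        f1 = np.where(pr + rc > 0, 2 * pr * rc / np.maximum(pr + rc, 1e-300), 0.0)
    best = int(np.argmax(f1))  # argmax returns the first (smallest) maximiser
    return CutoffScan(
        grid=grid_arr, tp=tp, fp=fp, fn=fn, precision=pr, recall=rc, f1=f1,
        selected=float(grid_arr[best]),
    )


def accepted_pairs(
    scores: Mapping[Pair, float], gold: Iterable[Pair], cs0: float
) -> set[Pair]:
    """Accepted catalog: gold pairs (always) plus predictions with CS > CS_0."""
    out = _canon(gold)
    out.update(p for p, s in scores.items() if s > cs0)
    return out


# ---------------------------------------------------------------------------
# Linear-motif scanning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifClass:
    """A linear-motif class: regex pattern plus its cognate binding domains.

    ``class_type`` distinguishes ligand-binding (LIG), docking (DOC) and
    degron (DEG) motifs -- the classes that mediate protein binding.
    """

    class_id: str
    class_type: str
    regex: str
    cognate_domains: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.cognate_domains:
            raise ValueError(f"{self.class_id}: cognate domains must be non-empty")
        re.compile(self.regex)


@dataclass(frozen=True)
class MotifHit:
    protein: str
    class_id: str
    start: int  # 1-based inclusive
    end: int
    matched: str


def scan_motifs(protein: ProteinRecord, classes: Iterable[MotifClass]) -> list[MotifHit]:
    """Scan a protein sequence for motif-class regex matches.

    Matches are found by a leftmost non-overlapping scan per class.  Hits that
    overlap any annotated domain span by at least one residue are discarded:
    a true linear motif lies outside globular domain regions, and this is the
    operational stand-in for structure-based context filtering.
    """
    if protein.sequence is None:
        raise ValueError(f"protein {protein.id} has no sequence")
    hits: list[MotifHit] = []
    for cls in classes:
        for m in re.finditer(cls.regex, protein.sequence):
            start, end = m.start() + 1, m.end()  # 1-based inclusive
            if end < start:  # zero-length match
                continue
            if any(start <= de and ds <= end for _, ds, de in protein.domain_spans):
                continue
            hits.append(
                MotifHit(protein=protein.id, class_id=cls.class_id,
                         start=start, end=end, matched=m.group(0))
            )
    return hits


# ---------------------------------------------------------------------------
# Motif regex match probability
# ---------------------------------------------------------------------------

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_TOKEN = re.compile(
    r"""
    (?P<anchor>[\^\$])
  | (?P<wild>\.)
  | (?P<class>\[(?P<neg>\^?)(?P<members>[A-Z]+)\])
  | (?P<literal>[A-Z])
  | (?P<repeat>\{(?P<lo>\d+)(?:,(?P<hi>\d+))?\})
    """,
    re.VERBOSE,
)


def motif_probability(
    cls: MotifClass | str,
    background: Mapping[str, float] | None = None,
) -> float:
    """Probability of a regex match at a fixed position under a background.

    The probability is the product over pattern positions of the summed
    background probability of the residues allowed there.  The supported
    dialect covers fixed residues, the wildcard ``.``, character classes with
    optional negation, anchors and bounded repeats (evaluated at their minimal
    length).  Anything else raises a ValueError naming the construct.  The
    default background is uniform (1/20 per residue).
    """
    pattern = cls.regex if isinstance(cls, MotifClass) else cls
    if background is None:
        background = {aa: 1.0 / 20.0 for aa in AMINO_ACIDS}
    pos = 0
    probs: list[float] = []
    while pos < len(pattern):
        m = _TOKEN.match(pattern, pos)
        if m is None:
            raise ValueError(
                f"unsupported regex construct at position {pos} in {pattern!r}: "
                f"{pattern[pos]!r}"
            )
        pos = m.end()
        if m.group("anchor"):
            continue
        if m.group("repeat"):
            if not probs:
                raise ValueError(f"repeat with no preceding token in {pattern!r}")
            lo = int(m.group("lo"))
            probs.extend([probs[-1]] * (lo - 1))
            if lo == 0:
                probs.pop()
            continue
        if m.group("wild"):
            probs.append(1.0)
        elif m.group("class"):
            members = set(m.group("members"))
            p = sum(background.get(a, 0.0) for a in members)
            if m.group("neg"):
                p = max(0.0, 1.0 - p)
            probs.append(p)
        else:
            probs.append(background.get(m.group("literal"), 0.0))
    return float(np.prod(probs)) if probs else 1.0


def filter_classes_by_probability(
    classes: Iterable[MotifClass],
    cutoff: float = 1e-5,
    background: Mapping[str, float] | None = None,
) -> list[MotifClass]:
    """Drop degenerate motif classes whose match probability exceeds cutoff."""
    return [
        c for c in classes if motif_probability(c, background) <= cutoff
    ]


# ---------------------------------------------------------------------------
# Per-protein feature inventories and edge classification
# ---------------------------------------------------------------------------

@dataclass
class Inventories:
    """Per-protein domain and motif-instance inventories.

    ``domains`` maps a protein to its domain instances (with multiplicity);
    ``motifs`` maps a protein to the motif-class ids of its motif instances.
    """

    domains: dict[str, list[str]] = field(default_factory=dict)
    motifs: dict[str, list[str]] = field(default_factory=dict)

    def domain_set(self, protein: str) -> set[str]:
        return set(self.domains.get(protein, ()))

    def motif_set(self, protein: str) -> set[str]:
        return set(self.motifs.get(protein, ()))

    @classmethod
    def from_records(
        cls,
        proteins: Mapping[str, ProteinRecord],
        hits: Iterable[MotifHit] = (),
    ) -> "Inventories":
        inv = cls()
        for pid, rec in proteins.items():
            inv.domains[pid] = list(rec.domains)
        for hit in hits:
            inv.motifs.setdefault(hit.protein, []).append(hit.class_id)
        return inv


def classify_edges(
    net: AnnotatedNetwork,
    inventories: Inventories,
    ddi_catalog: Iterable[Pair],
    classes: Iterable[MotifClass],
    in_place: bool = False,
) -> AnnotatedNetwork:
    """Label every edge DDI, DLI or unclassified from feature inventories.

    An edge is DDI-eligible when some domain on one endpoint pairs with a
    domain on the other endpoint in the accepted catalog (either orientation),
    and DLI-eligible when a motif instance on one endpoint belongs to a class
    whose cognate domain is present on the other endpoint.  Eligibility under
    both criteria (or neither) leaves the edge unclassified.  Mediating pairs
    are recorded; DLI evidence is recorded as ``("motif:<class>", domain)``.
    """
    catalog = _canon(ddi_catalog)
    cognates = {c.class_id: set(c.cognate_domains) for c in classes}
    out = net if in_place else net.copy()
    missing: set[str] = set()
    for a, b in out.graph.edges():
        a, b = canonical_edge(a, b)
        dom_a, dom_b = inventories.domain_set(a), inventories.domain_set(b)
        mot_a, mot_b = inventories.motif_set(a), inventories.motif_set(b)
        for pid, dom, mot in ((a, dom_a, mot_a), (b, dom_b, mot_b)):
            if not dom and not mot and pid not in inventories.domains:
                missing.add(pid)
        ddi_pairs = sorted(
            (da, db)
            for da in dom_a
            for db in dom_b
            if canonical_edge(da, db) in catalog
        )
        dli_pairs = sorted(
            [(f"motif:{cid}", db)
             for cid in mot_a
             for db in (cognates.get(cid, set()) & dom_b)]
            + [(da, f"motif:{cid}")
               for cid in mot_b
               for da in (cognates.get(cid, set()) & dom_a)]
        )
        if ddi_pairs and not dli_pairs:
            out.set_label(a, b, DDI, mediating_pairs=ddi_pairs)
        elif dli_pairs and not ddi_pairs:
            out.set_label(a, b, DLI, mediating_pairs=dli_pairs)
        else:
            out.set_label(a, b, UNCLASSIFIED,
                          mediating_pairs=ddi_pairs + dli_pairs)
    if missing:
        logger.warning(
            "%d protein(s) absent from inventories; treated as featureless",
            len(missing),
        )
    return out


def split_homo_hetero(net: AnnotatedNetwork) -> dict[Pair, str]:
    """Split DDI edges into homo-DDIs and hetero-DDIs.

    An edge is a homo-DDI when at least one mediating domain pair has the
    same domain id on both sides; otherwise it is a hetero-DDI.  Calling this
    on a non-DDI edge is an error, so the function runs over DDI edges only.
    """
    out: dict[Pair, str] = {}
    for rec in net.edges():
        if rec.label != DDI:
            continue
        if not rec.mediating_pairs:
            raise ValueError(f"DDI edge {rec.key} has no mediating pairs recorded")
        homo = any(x == y for x, y in rec.mediating_pairs)
        out[rec.key] = "homo-DDI" if homo else "hetero-DDI"
    return out


# ---------------------------------------------------------------------------
# Motif quality bookkeeping across pipeline stages
# ---------------------------------------------------------------------------

@dataclass
class StageQuality:
    stage: str
    n: int
    n_positive: int
    fraction: float | None
    baseline_fractions: np.ndarray

    @property
    def baseline_mean(self) -> float:
        return float(np.mean(self.baseline_fractions))


def stage_quality(
    stage_sets: Mapping[str, Iterable[str]],
    positive_set: Iterable[str],
    universe: Iterable[str],
    n_random: int = 10_000,
    random_size: int | None = None,
    seed: int = 0,
) -> dict[str, StageQuality]:
    """Fraction of validated motifs retained at each classification stage.

    For each stage set the positive fraction |stage & positive| / |stage| is
    compared with a baseline distribution of fractions over ``n_random``
    seeded random draws (without replacement) from the motif universe, each of
    size ``random_size`` (default: the positive-set size).
    """
    positives = set(positive_set)
    if not positives:
        raise ValueError("positive set is empty")
    pool = sorted(set(universe))
    size = len(positives) if random_size is None else random_size
    if size > len(pool):
        raise ValueError("random_size exceeds motif universe size")
    rng = np.random.default_rng(seed)
    pool_arr = np.array(pool, dtype=object)
    is_pos = np.array([m in positives for m in pool], dtype=bool)
    baseline = np.empty(n_random)
    for i in range(n_random):
        idx = rng.choice(len(pool_arr), size=size, replace=False)
        baseline[i] = is_pos[idx].mean()
    out: dict[str, StageQuality] = {}
    for stage, members in stage_sets.items():
        mset = set(members)
        if not mset:
            out[stage] = StageQuality(stage, 0, 0, None, baseline)
            continue
        n_pos = len(mset & positives)
        out[stage] = StageQuality(stage, len(mset), n_pos, n_pos / len(mset), baseline)
    return out
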