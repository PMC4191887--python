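"""Seeded synthetic universes for end-to-end testing of the analysis.

The generator plants a modular network (within-module edge probability
``p_in`` above the between-module ``p_out``), biases interface labels the way
the analysis assumes real interactomes behave -- within-module edges are
mostly strong domain-domain interactions (DDIs), between-module edges mostly
weak domain-motif interactions (DLIs) -- and then constructs per-protein
domain/motif inventories, domain-pair and motif-class catalogs, sequences and
annotations such that re-running the edge classifier on the inventories
recovers the planted labels exactly (a constructive guarantee, enforced by a
verify-and-repair pass).

Motif instances are concentrated on a reused pool of carrier proteins,
emulating motif-rich proteins with long disordered regions that carry several
short linear motifs; this keeps motif-bearing proteins a minority, which is
what makes the species-retention model below meaningful.

Species series: each synthetic species retains every protein independently,
motif-bearing proteins with ``retention_motif_bearing`` and all others with
``retention_core``.  Metazoan-like profiles retain motif-bearing proteins at
a higher rate, emulating the expansion of motif-mediated interactions in
complex organisms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .classify import AMINO_ACIDS, Inventories, MotifClass, classify_edges
from .modularity import Partition
from .network import (
    DDI,
    DLI,
    AnnotatedNetwork,
    AnnotationTable,
    InteractionRecord,
    ProteinRecord,
    canonical_edge,
)


@dataclass(frozen=True)
class PlantedModel:
    """Parameters of the planted-partition universe."""

    module_sizes: tuple[int, ...] = (40, 40, 40, 40, 40)
    p_in: float = 0.3
    p_out: float = 0.01
    beta_within_ddi: float = 0.9
    beta_between_dli: float = 0.9
    seed: int = 0
    overlap_fraction: float = 0.1  # proteins given a second annotation term

    def __post_init__(self) -> None:
        for p in (self.p_in, self.p_out, self.beta_within_ddi,
                  self.beta_between_dli, self.overlap_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if any(s < 3 for s in self.module_sizes):
            raise ValueError("module sizes must be >= 3")


@dataclass(frozen=True)
class SpeciesProfile:
    """Retention probabilities of one synthetic species."""

    species_id: str
    retention_core: float = 0.8
    retention_motif_bearing: float = 0.8
    group: str = "nonmetazoan-like"

    def __post_init__(self) -> None:
        for p in (self.retention_core, self.retention_motif_bearing):
            if not 0.0 <= p <= 1.0:
                raise ValueError("retention probabilities must lie in [0, 1]")


@dataclass
class Catalogs:
    ddi_pairs: set[tuple[str, str]] = field(default_factory=set)
    motif_classes: list[MotifClass] = field(default_factory=list)

    def classes_by_id(self) -> dict[str, MotifClass]:
        return {c.class_id: c for c in self.motif_classes}


@dataclass
class SyntheticUniverse:
    model: PlantedModel
    network: AnnotatedNetwork
    truth_partition: Partition
    truth_labels: dict[tuple[str, str], str]
    annotations: AnnotationTable
    inventories: Inventories | None = None
    catalogs: Catalogs | None = None
    #: per-edge evidence assignment, kept for the repair pass and diagnostics
    edge_assignment: dict[tuple[str, str], tuple] = field(default_factory=dict)

    def motif_bearing(self) -> set[str]:
        if self.inventories is None:
            raise ValueError("inventories not generated yet")
        return {p for p, motifs in self.inventories.motifs.items() if motifs}


def _protein_names(n: int) -> list[str]:
    return [f"P{i:04d}" for i in range(n)]


def generate_planted_network(model: PlantedModel) -> SyntheticUniverse:
    """Draw the planted network, labels and partition-mirroring annotations.

    Within-module pairs receive an edge with probability ``p_in`` and the edge
    is DDI with probability ``beta_within_ddi`` (else DLI); between-module
    pairs use ``p_out`` and DLI with probability ``beta_between_dli`` (else
    DDI).  The same seed reproduces the identical universe.
    """
    rng = np.random.default_rng(model.seed)
    sizes = list(model.module_sizes)
    names = _protein_names(sum(sizes))
    module_of: dict[str, int] = {}
    pos = 0
    for m, size in enumerate(sizes):
        for name in names[pos : pos + size]:
            module_of[name] = m
        pos += size
    n_total = len(names)
    for m, size in enumerate(sizes):
        if model.p_in * (size - 1) + model.p_out * (n_total - size) == 0:
            warnings.warn(f"module {m} has expected degree 0")

    net = AnnotatedNetwork(provenance=f"planted(seed={model.seed})")
    for name in names:
        net.add_protein(ProteinRecord(id=name))
    truth: dict[tuple[str, str], str] = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            same = module_of[a] == module_of[b]
            p = model.p_in if same else model.p_out
            if rng.random() >= p:
                continue
            if same:
                label = DDI if rng.random() < model.beta_within_ddi else DLI
            else:
                label = DLI if rng.random() < model.beta_between_dli else DDI
            net.add_edge(InteractionRecord(a=a, b=b, n_sources=1, label=label))
            truth[canonical_edge(a, b)] = label

    annotations = AnnotationTable(namespace="planted")
    k = len(sizes)
    for name in names:
        m = module_of[name]
        annotations.add(name, f"T{m}")
        if model.overlap_fraction > 0 and rng.random() < model.overlap_fraction:
            annotations.add(name, f"T{(m + 1) % k}")

    partition = Partition(assignment={n: module_of[n] for n in names})
    return SyntheticUniverse(
        model=model,
        network=net,
        truth_partition=partition,
        truth_labels=truth,
        annotations=annotations,
    )


# ---------------------------------------------------------------------------
# Inventories, catalogs and sequences
# ---------------------------------------------------------------------------

_CLASS_TYPES = ("LIG", "DOC", "DEG")


def _mint_motif_class(k: int, rng: np.random.Generator) -> MotifClass:
    """A 6-position motif pattern: four fixed residues, one 2-residue choice,
    one wildcard.  Match probability under a uniform background is
    2 / 20^4 = 6.25e-7, comfortably below the degeneracy cutoff."""
    aas = rng.choice(list(AMINO_ACIDS), size=6, replace=True)
    l1, l2, l3, l4, c1, c2 = (str(a) for a in aas)
    if c1 == c2:
        c2 = AMINO_ACIDS[(AMINO_ACIDS.index(c1) + 1) % 20]
    regex = f"{l1}{l2}[{c1}{c2}].{l3}{l4}"
    return MotifClass(
        class_id=f"{_CLASS_TYPES[k % 3]}_{k:04d}",
        class_type=_CLASS_TYPES[k % 3],
        regex=regex,
        cognate_domains=(f"MB{k:04d}",),
    )


def _exemplar(cls: MotifClass) -> str:
    """A literal peptide matching the class regex (first class member)."""
    r = cls.regex
    # pattern shape is L L [xy] . L L by construction
    return r[0] + r[1] + r[3] + "A" + r[-2] + r[-1]


def _mint_ddi_pair(k: int) -> tuple[str, str]:
    if k % 4 == 3:  # every fourth pair is a homodimeric domain pair
        return (f"PFH{k:04d}", f"PFH{k:04d}")
    return (f"PFA{k:04d}", f"PFB{k:04d}")


def generate_inventories(
    universe: SyntheticUniverse,
    edges_per_feature: int = 10,
    max_repair_rounds: int = 20,
) -> SyntheticUniverse:
    """Construct inventories, catalogs and sequences consistent with truth.

    Every DDI edge receives one interacting domain pair from the catalog
    (shared between up to ``edges_per_feature`` edges); every DLI edge places
    a motif instance on a carrier endpoint (preferring endpoints that already
    carry motifs) and the class's cognate domain on the other endpoint.
    Shared evidence can create accidental cross-evidence that would flip a
    label; a verify-and-repair pass re-mints dedicated features for the edges
    involved until re-classification reproduces the planted labels exactly.
    """
    model = universe.model
    rng = np.random.default_rng(np.random.SeedSequence([model.seed, 1]).generate_state(1)[0])
    net = universe.network
    catalogs = Catalogs()
    inv = Inventories(domains={p: [] for p in net.proteins},
                      motifs={p: [] for p in net.proteins})
    assignment: dict[tuple[str, str], tuple] = {}

    ddi_edges = sorted(e for e, lab in universe.truth_labels.items() if lab == DDI)
    dli_edges = sorted(e for e, lab in universe.truth_labels.items() if lab == DLI)

    n_pairs = max(1, -(-len(ddi_edges) // edges_per_feature)) if ddi_edges else 0
    pairs = [_mint_ddi_pair(k) for k in range(n_pairs)]
    catalogs.ddi_pairs.update(canonical_edge(*p) for p in pairs)
    for i, (a, b) in enumerate(ddi_edges):
        da, db = pairs[i // edges_per_feature]
        inv.domains[a].append(da)
        inv.domains[b].append(db)
        assignment[(a, b)] = ("ddi", da, db)

    n_classes = max(1, -(-len(dli_edges) // edges_per_feature)) if dli_edges else 0
    classes = [_mint_motif_class(k, rng) for k in range(n_classes)]
    catalogs.motif_classes.extend(classes)
    # Motifs concentrate on a small pool of carrier proteins (motif-rich hubs
    # with long disordered regions carry several short motifs).  A greedy
    # cover of the DLI subgraph picks the carriers: repeatedly take the
    # protein incident to the most unassigned DLI edges.
    carrier_of: dict[tuple[str, str], str] = {}
    remaining = set(dli_edges)
    incident: dict[str, set[tuple[str, str]]] = {}
    for e in dli_edges:
        incident.setdefault(e[0], set()).add(e)
        incident.setdefault(e[1], set()).add(e)
    while remaining:
        best = max(incident, key=lambda p: (len(incident[p] & remaining), p))
        for e in incident[best] & remaining:
            carrier_of[e] = best
            remaining.discard(e)
        del incident[best]
    for j, (a, b) in enumerate(dli_edges):
        cls = classes[j // edges_per_feature]
        carrier = carrier_of[(a, b)]
        other = b if carrier == a else a
        inv.motifs[carrier].append(cls.class_id)
        inv.domains[other].append(cls.cognate_domains[0])
        assignment[(a, b)] = ("dli", cls.class_id, carrier)

    universe.inventories = inv
    universe.catalogs = catalogs
    universe.edge_assignment = assignment

    _repair_labels(universe, rng, max_repair_rounds)
    _build_sequences(universe, rng)
    return universe


def _remove_instance(items: list[str], value: str) -> None:
    items.remove(value)  # removes one occurrence


def _dedicate_edge(universe: SyntheticUniverse, edge: tuple[str, str],
                   counter: list[int], rng: np.random.Generator) -> None:
    """Replace an edge's shared evidence with fresh single-use features."""
    inv = universe.inventories
    catalogs = universe.catalogs
    assert inv is not None and catalogs is not None
    kind = universe.edge_assignment[edge]
    a, b = edge
    k = counter[0]
    counter[0] += 1
    if kind[0] == "ddi":
        _, da, db = kind
        _remove_instance(inv.domains[a], da)
        _remove_instance(inv.domains[b], db)
        new = (f"PFX{k:04d}", f"PFY{k:04d}")
        catalogs.ddi_pairs.add(canonical_edge(*new))
        inv.domains[a].append(new[0])
        inv.domains[b].append(new[1])
        universe.edge_assignment[edge] = ("ddi", new[0], new[1])
    else:
        _, class_id, carrier = kind
        other = b if carrier == a else a
        by_id = catalogs.classes_by_id()
        old = by_id[class_id]
        _remove_instance(inv.motifs[carrier], class_id)
        _remove_instance(inv.domains[other], old.cognate_domains[0])
        new_cls = MotifClass(
            class_id=f"DED_{k:04d}",
            class_type=old.class_type,
            regex=_mint_motif_class(k, rng).regex,
            cognate_domains=(f"MBX{k:04d}",),
        )
        catalogs.motif_classes.append(new_cls)
        inv.motifs[carrier].append(new_cls.class_id)
        inv.domains[other].append(new_cls.cognate_domains[0])
        universe.edge_assignment[edge] = ("dli", new_cls.class_id, carrier)


def _repair_labels(universe: SyntheticUniverse, rng: np.random.Generator,
                   max_rounds: int) -> None:
    inv = universe.inventories
    catalogs = universe.catalogs
    assert inv is not None and catalogs is not None
    counter = [0]
    for _ in range(max_rounds):
        labelled = classify_edges(universe.network, inv, catalogs.ddi_pairs,
                                  catalogs.motif_classes)
        mismatched = [
            rec.key
            for rec in labelled.edges()
            if universe.truth_labels[rec.key] != rec.label
        ]
        if not mismatched:
            # adopt the verified labels (identical to truth) on the network
            universe.network = labelled
            return
        endpoints = {p for e in mismatched for p in e}
        for edge in sorted(universe.edge_assignment):
            if edge[0] in endpoints or edge[1] in endpoints:
                _dedicate_edge(universe, edge, counter, rng)
    raise RuntimeError(
        f"could not reconcile inventories with planted labels after "
        f"{max_rounds} repair rounds"
    )


_DOMAIN_LEN = 30
_DOMAIN_GAP = 5
_MOTIF_GAP = 3


def _build_sequences(universe: SyntheticUniverse, rng: np.random.Generator) -> None:
    """Random sequences with domain spans and literally implanted motifs.

    Domains occupy fixed-length blocks at the start of the sequence; motif
    exemplars are implanted after the domain region so they never overlap a
    domain span.
    """
    inv = universe.inventories
    catalogs = universe.catalogs
    assert inv is not None and catalogs is not None
    by_id = catalogs.classes_by_id()
    aa = np.array(list(AMINO_ACIDS))
    for pid in sorted(universe.network.proteins):
        domains = inv.domains.get(pid, [])
        motifs = inv.motifs.get(pid, [])
        dom_block = len(domains) * (_DOMAIN_LEN + _DOMAIN_GAP)
        motif_block = sum(
            len(_exemplar(by_id[m])) + _MOTIF_GAP for m in motifs
        )
        length = max(300, dom_block + motif_block + 20)
        seq = list(rng.choice(aa, size=length))
        spans: list[tuple[str, int, int]] = []
        pos = 0
        for dom in domains:
            start = pos + _DOMAIN_GAP
            spans.append((dom, start + 1, start + _DOMAIN_LEN))
            pos = start + _DOMAIN_LEN
        mpos = pos + _MOTIF_GAP
        for m in motifs:
            exemplar = _exemplar(by_id[m])
            seq[mpos : mpos + len(exemplar)] = list(exemplar)
            mpos += len(exemplar) + _MOTIF_GAP
        record = ProteinRecord(id=pid, sequence="".join(seq), domain_spans=spans)
        universe.network.proteins[pid] = record


def generate_universe(model: PlantedModel) -> SyntheticUniverse:
    """Planted network plus consistent inventories, catalogs and sequences."""
    return generate_inventories(generate_planted_network(model))


# ---------------------------------------------------------------------------
# Species series
# ---------------------------------------------------------------------------

def generate_species_series(
    universe: SyntheticUniverse,
    profiles: Sequence[SpeciesProfile],
    seed: int = 0,
) -> dict[str, set[str]]:
    """Per-species ortholog maps (sets of conserved protein ids).

    Each protein is kept independently: motif-bearing proteins with the
    profile's ``retention_motif_bearing``, all others with ``retention_core``.
    """
    bearing = universe.motif_bearing()
    proteins = sorted(universe.network.proteins)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]).generate_state(1)[0])
    maps: dict[str, set[str]] = {}
    for profile in profiles:
        draws = rng.random(len(proteins))
        kept = {
            p
            for p, u in zip(proteins, draws)
            if u < (profile.retention_motif_bearing if p in bearing
                    else profile.retention_core)
        }
        maps[profile.species_id] = kept
    return maps


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

def generate_alignment(
    motif_spans: Sequence[tuple[int, int]],
    n_seqs: int,
    conservation: float,
    seed: int = 0,
    length: int | None = None,
    flank_mutation: float = 1.0,
) -> list[str]:
    """Fixed-length alignment with conserved motif columns and noisy flanks.

    A random base sequence is mutated per row: columns inside ``motif_spans``
    (1-based inclusive) mutate with probability ``1 - conservation``, flanking
    columns with ``flank_mutation`` (default 1.0: fully randomised flanks).
    Substitutions are uniform over the 20 amino acids, so a "mutated" column
    can coincide with the base residue by chance.  No indels are introduced.
    """
    if n_seqs < 2:
        raise ValueError("need at least 2 sequences")
    if not 0.0 <= conservation <= 1.0:
        raise ValueError("conservation must lie in [0, 1]")
    if length is None:
        length = max(end for _, end in motif_spans) + 20 if motif_spans else 100
    in_motif = np.zeros(length, dtype=bool)
    for start, end in motif_spans:
        if not (1 <= start <= end <= length):
            raise ValueError(f"span ({start},{end}) outside alignment of length {length}")
        in_motif[start - 1 : end] = True
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    base = rng.choice(aa, size=length)
    mut_p = np.where(in_motif, 1.0 - conservation, flank_mutation)
    rows: list[str] = []
    for _ in range(n_seqs):
        mutate = rng.random(length) < mut_p
        row = np.where(mutate, rng.choice(aa, size=length), base)
        rows.append("".join(row))
    return rows
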