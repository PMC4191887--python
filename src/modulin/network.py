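"""Core data model: proteins, labelled interactions, annotated networks.

The network is an undirected simple graph.  Every edge carries an interface
label -- ``"DDI"`` (domain-domain interaction, a strong interface between two
globular domains), ``"DLI"`` (domain-linear-motif interaction, a weak
interface between a short peptide motif and a domain) or ``"unclassified"`` --
plus an evidence-source count and the mediating feature pairs that justified
the label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import networkx as nx

#: The three admissible interface labels.
LABELS = ("DDI", "DLI", "unclassified")

DDI = "DDI"
DLI = "DLI"
UNCLASSIFIED = "unclassified"


def canonical_edge(a: str, b: str) -> tuple[str, str]:
    """Return the endpoints of an undirected edge in lexicographic order."""
    return (a, b) if a <= b else (b, a)


@dataclass
class ProteinRecord:
    """A protein with optional sequence and 1-based inclusive domain spans."""

    id: str
    sequence: str | None = None
    domain_spans: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sequence is not None:
            n = len(self.sequence)
            for dom, start, end in self.domain_spans:
                if not (1 <= start <= end <= n):
                    raise ValueError(
                        f"domain {dom} span ({start},{end}) outside sequence "
                        f"of {self.id} (length {n})"
                    )

    @property
    def domains(self) -> list[str]:
        return [d for d, _, _ in self.domain_spans]


@dataclass
class InteractionRecord:
    """An undirected protein-protein interaction.

    ``mediating_pairs`` records the feature evidence that produced the label:
    ``(domain_a, domain_b)`` pairs for DDI evidence and
    ``("motif:<class>", domain)`` pairs for DLI evidence, oriented so the
    first element sits on the lexicographically smaller endpoint.
    """

    a: str
    b: str
    n_sources: int | None = 1
    label: str = UNCLASSIFIED
    mediating_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError(f"self-interaction {self.a} not allowed")
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.n_sources is not None and self.n_sources < 1:
            raise ValueError("n_sources must be >= 1")
        self.a, self.b = canonical_edge(self.a, self.b)

    @property
    def key(self) -> tuple[str, str]:
        return (self.a, self.b)


class AnnotatedNetwork:
    """Undirected simple graph of proteins with labelled edges.

    Backed by a :class:`networkx.Graph`; edge attributes are ``n_sources``,
    ``label`` and ``mediating_pairs``.  Protein records (sequences, domain
    spans) are kept alongside in :attr:`proteins`.
    """

    def __init__(self, provenance: str = "") -> None:
        self.graph = nx.Graph()
        self.proteins: dict[str, ProteinRecord] = {}
        self.provenance = provenance

    # -- construction -----------------------------------------------------

    def add_protein(self, record: ProteinRecord) -> None:
        self.proteins[record.id] = record
        self.graph.add_node(record.id)

    def ensure_protein(self, pid: str) -> None:
        if pid not in self.proteins:
            self.add_protein(ProteinRecord(id=pid))

    def add_edge(self, rec: InteractionRecord) -> None:
        """Add an interaction; duplicates keep the maximum ``n_sources``."""
        self.ensure_protein(rec.a)
        self.ensure_protein(rec.b)
        if self.graph.has_edge(rec.a, rec.b):
            old = self.graph.edges[rec.a, rec.b]
            counts = [c for c in (old["n_sources"], rec.n_sources) if c is not None]
            old["n_sources"] = max(counts) if counts else None
        else:
            self.graph.add_edge(
                rec.a,
                rec.b,
                n_sources=rec.n_sources,
                label=rec.label,
                mediating_pairs=list(rec.mediating_pairs),
            )

    # -- views -------------------------------------------------------------

    def edges(self) -> Iterator[InteractionRecord]:
        for a, b, data in self.graph.edges(data=True):
            a, b = canonical_edge(a, b)
            yield InteractionRecord(
                a=a,
                b=b,
                n_sources=data.get("n_sources", 1),
                label=data.get("label", UNCLASSIFIED),
                mediating_pairs=list(data.get("mediating_pairs", [])),
            )

    def edge_keys(self) -> list[tuple[str, str]]:
        return sorted(canonical_edge(a, b) for a, b in self.graph.edges())

    def label_of(self, a: str, b: str) -> str:
        return self.graph.edges[a, b].get("label", UNCLASSIFIED)

    def set_label(
        self, a: str, b: str, label: str, mediating_pairs: list | None = None
    ) -> None:
        if label not in LABELS:
            raise ValueError(f"unknown label {label!r}")
        self.graph.edges[a, b]["label"] = label
        if mediating_pairs is not None:
            self.graph.edges[a, b]["mediating_pairs"] = mediating_pairs

    def label_counts(self) -> dict[str, int]:
        counts = {lab: 0 for lab in LABELS}
        for _, _, data in self.graph.edges(data=True):
            counts[data.get("label", UNCLASSIFIED)] += 1
        return counts

    @property
    def n_proteins(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def copy(self) -> "AnnotatedNetwork":
        out = AnnotatedNetwork(provenance=self.provenance)
        out.graph = self.graph.copy()
        out.proteins = dict(self.proteins)
        return out

    def subgraph_on(self, proteins: Iterable[str]) -> "AnnotatedNetwork":
        """Induced subgraph on ``proteins``; labels and records carried over."""
        keep = set(proteins)
        out = AnnotatedNetwork(provenance=self.provenance)
        for pid in sorted(keep & set(self.proteins)):
            out.add_protein(self.proteins[pid])
        for rec in self.edges():
            if rec.a in keep and rec.b in keep:
                out.add_edge(rec)
        return out


@dataclass
class AnnotationTable:
    """Protein -> set of annotation terms for one namespace.

    Proteins absent from :attr:`terms` are treated as unannotated.
    """

    namespace: str = "functional"
    terms: dict[str, set[str]] = field(default_factory=dict)

    def add(self, protein: str, term: str) -> None:
        self.terms.setdefault(protein, set()).add(term)

    def get(self, protein: str) -> set[str] | None:
        return self.terms.get(protein)

    def by_term(self) -> dict[str, set[str]]:
        """Invert the table: term -> set of proteins."""
        groups: dict[str, set[str]] = {}
        for protein, ts in self.terms.items():
            for t in ts:
                groups.setdefault(t, set()).add(protein)
        return groups

    @classmethod
    def from_groups(
        cls, groups: Mapping[str, Iterable[str]], namespace: str = "functional"
    ) -> "AnnotationTable":
        table = cls(namespace=namespace)
        for term, members in groups.items():
            for p in members:
                table.add(p, term)
        return table
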