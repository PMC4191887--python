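"""Readers and writers for the tabular inputs and outputs.

All analysis inputs are plain TSV (edge lists, domain tables, motif-class
catalogs, annotation tables) or aligned FASTA.  Supplementary XLSX tables can
be converted to TSV with :func:`convert_xlsx`; the analysis core consumes TSV
only.  Writers round-trip with the corresponding readers.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from pathlib import Path
from typing import Iterable

from Bio import AlignIO

from .network import (
    LABELS,
    UNCLASSIFIED,
    AnnotatedNetwork,
    AnnotationTable,
    InteractionRecord,
    ProteinRecord,
    canonical_edge,
)

logger = logging.getLogger(__name__)

EDGE_COLUMNS = ("protein_a", "protein_b", "n_sources", "label")


class ParseError(ValueError):
    """Malformed input row; the message names the file and line number."""


def _rows(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            yield lineno, [c.strip() for c in row]


def read_network(
    path: str | Path, dialect: str = "labeled-tsv"
) -> AnnotatedNetwork:
    """Read an undirected edge list.

    ``simple-tsv`` expects columns ``protein_a  protein_b`` with optional
    ``n_sources``; ``labeled-tsv`` additionally accepts ``label``.  A header
    row is required.  Duplicate rows are collapsed keeping the maximum
    ``n_sources``; self-loops are dropped with a logged count; a blank or
    unrecognised label becomes ``unclassified`` with a warning.
    """
    if dialect not in ("simple-tsv", "labeled-tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    net = AnnotatedNetwork(provenance=f"read_network({path})")
    header: dict[str, int] | None = None
    n_loops = 0
    n_bad_labels = 0
    for lineno, row in _rows(path):
        if header is None:
            header = {name: i for i, name in enumerate(row)}
            if "protein_a" not in header or "protein_b" not in header:
                raise ParseError(
                    f"{path}:{lineno}: header must contain protein_a and "
                    f"protein_b, got {row}"
                )
            continue
        try:
            a = row[header["protein_a"]]
            b = row[header["protein_b"]]
        except IndexError:
            raise ParseError(f"{path}:{lineno}: expected endpoint columns") from None
        if not a or not b:
            raise ParseError(f"{path}:{lineno}: empty protein identifier")
        if a == b:
            n_loops += 1
            continue
        n_sources: int | None = None
        if "n_sources" in header and len(row) > header["n_sources"]:
            raw = row[header["n_sources"]]
            if raw:
                try:
                    n_sources = int(raw)
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: n_sources {raw!r} is not an integer"
                    ) from None
                if n_sources < 1:
                    raise ParseError(f"{path}:{lineno}: n_sources must be >= 1")
        label = UNCLASSIFIED
        if dialect == "labeled-tsv" and "label" in header and len(row) > header["label"]:
            raw = row[header["label"]]
            if raw in LABELS:
                label = raw
            elif raw:
                n_bad_labels += 1
            # blank stays unclassified
        net.add_edge(
            InteractionRecord(a=a, b=b, n_sources=n_sources, label=label)
        )
    if n_loops:
        logger.warning("dropped %d self-loop row(s) from %s", n_loops, path)
    if n_bad_labels:
        logger.warning(
            "%d row(s) in %s had unrecognised labels; set to unclassified",
            n_bad_labels,
            path,
        )
    return net


def write_network(net: AnnotatedNetwork, path: str | Path) -> None:
    """Write the edge list as labeled TSV (round-trips with read_network)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(EDGE_COLUMNS)
        for rec in sorted(net.edges(), key=lambda r: r.key):
            writer.writerow(
                [rec.a, rec.b, "" if rec.n_sources is None else rec.n_sources,
                 rec.label]
            )


def filter_by_evidence_count(
    net: AnnotatedNetwork, min_sources: int
) -> AnnotatedNetwork:
    """Stable-subnetwork filter: keep edges with ``n_sources >= min_sources``.

    Multiple independent publication sources indicate a reproducibly observed
    (stable) interaction.  Isolated proteins are removed; labels are kept.
    An edge without a recorded source count is an error.
    """
    out = AnnotatedNetwork(provenance=net.provenance + f" | >= {min_sources} sources")
    for rec in net.edges():
        if rec.n_sources is None:
            raise ValueError(f"edge {rec.key} has no n_sources recorded")
        if rec.n_sources >= min_sources:
            out.ensure_protein(rec.a)
            out.ensure_protein(rec.b)
            if rec.a in net.proteins:
                out.proteins[rec.a] = net.proteins[rec.a]
            if rec.b in net.proteins:
                out.proteins[rec.b] = net.proteins[rec.b]
            out.add_edge(rec)
    return out


def read_annotations(path: str | Path, namespace: str = "functional") -> AnnotationTable:
    """Read a ``protein  term`` TSV; repeated proteins merge their term sets."""
    table = AnnotationTable(namespace=namespace)
    header_seen = False
    for lineno, row in _rows(path):
        if not header_seen and row[0] == "protein":
            header_seen = True
            continue
        if len(row) < 2 or not row[0] or not row[1]:
            raise ParseError(f"{path}:{lineno}: expected 'protein<TAB>term'")
        table.add(row[0], row[1])
    return table


def write_annotations(table: AnnotationTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["protein", "term"])
        for protein in sorted(table.terms):
            for term in sorted(table.terms[protein]):
                writer.writerow([protein, term])


def read_domain_table(path: str | Path) -> dict[str, list[tuple[str, int, int]]]:
    """Read ``protein  domain_id  start  end`` (1-based inclusive spans)."""
    spans: dict[str, list[tuple[str, int, int]]] = {}
    header_seen = False
    for lineno, row in _rows(path):
        if not header_seen and row[0] == "protein":
            header_seen = True
            continue
        if len(row) < 4:
            raise ParseError(f"{path}:{lineno}: expected 4 columns")
        try:
            start, end = int(row[2]), int(row[3])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-integer span") from None
        if not (1 <= start <= end):
            raise ParseError(f"{path}:{lineno}: invalid span ({start},{end})")
        spans.setdefault(row[0], []).append((row[1], start, end))
    return spans


def read_motif_classes(path: str | Path):
    """Read ``class_id  class_type  regex  cognate_domains`` TSV.

    Cognate domains are semicolon-separated.  Duplicate class ids are an
    error; each regex is compiled up front so bad patterns fail loudly.
    """
    from .classify import MotifClass  # local import to avoid a cycle

    classes: list[MotifClass] = []
    seen: set[str] = set()
    header_seen = False
    for lineno, row in _rows(path):
        if not header_seen and row[0] == "class_id":
            header_seen = True
            continue
        if len(row) < 4:
            raise ParseError(f"{path}:{lineno}: expected 4 columns")
        class_id, class_type, regex, cognates = row[0], row[1], row[2], row[3]
        if class_id in seen:
            raise ParseError(f"{path}:{lineno}: duplicate class id {class_id!r}")
        seen.add(class_id)
        try:
            re.compile(regex)
        except re.error as exc:
            raise ParseError(f"{path}:{lineno}: bad regex {regex!r}: {exc}") from None
        classes.append(
            MotifClass(
                class_id=class_id,
                class_type=class_type,
                regex=regex,
                cognate_domains=tuple(d for d in cognates.split(";") if d),
            )
        )
    return classes


def write_motif_classes(classes, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["class_id", "class_type", "regex", "cognate_domains"])
        for c in classes:
            writer.writerow(
                [c.class_id, c.class_type, c.regex, ";".join(c.cognate_domains)]
            )


def read_domain_pairs(path: str | Path) -> set[tuple[str, str]]:
    """Read an interacting domain-pair catalog: ``domain_i  domain_j``."""
    pairs: set[tuple[str, str]] = set()
    header_seen = False
    for lineno, row in _rows(path):
        if not header_seen and row[0] == "domain_i":
            header_seen = True
            continue
        if len(row) < 2:
            raise ParseError(f"{path}:{lineno}: expected 2+ columns")
        pairs.add(canonical_edge(row[0], row[1]))
    return pairs


def read_domain_pair_predictions(
    path: str | Path,
) -> dict[str, set[tuple[str, str]]]:
    """Read per-method predictions: ``domain_i  domain_j  method_id``."""
    preds: dict[str, set[tuple[str, str]]] = {}
    header_seen = False
    for lineno, row in _rows(path):
        if not header_seen and row[0] == "domain_i":
            header_seen = True
            continue
        if len(row) < 3:
            raise ParseError(f"{path}:{lineno}: expected 3 columns")
        preds.setdefault(row[2], set()).add(canonical_edge(row[0], row[1]))
    return preds


def read_alignment(path: str | Path):
    """Read an aligned FASTA; ragged rows raise a ValueError."""
    return AlignIO.read(str(path), "fasta")


def write_alignment(alignment, path: str | Path) -> None:
    AlignIO.write(alignment, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n{sequences[name]}\n")


def write_report(results: dict, path: str | Path) -> None:
    """Write a machine-readable JSON summary of a run."""
    with open(path, "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset, tuple)):
        return sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def convert_xlsx(path: str | Path, out_path: str | Path, sheet: int | str = 0) -> int:
    """Convert one sheet of an XLSX workbook to TSV; returns the row count."""
    import pandas as pd

    frame = pd.read_excel(path, sheet_name=sheet)
    frame.to_csv(out_path, sep="\t", index=False)
    return len(frame)
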