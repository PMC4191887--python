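"""Motif conservation from ortholog alignments.

Column conservation is Shannon entropy (bits) of the residue frequencies in
one alignment column; the relative local conservation (RLC) of a position
standardises that entropy against the mean and standard deviation of the
entropies in a +/-10-column window, with the sign flipped so that conserved
(low-entropy) positions score high.  A motif's conservation is the mean RLC
over its residues.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

GAP_CHARS = {"-", "."}
VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")

#: Half-width of the standardisation window, in columns.
RLC_WINDOW = 10


@dataclass
class ColumnEntropy:
    index: int
    entropy: float | None  # None for a column with < 2 non-gap residues
    frequencies: dict[str, float]


def column_entropy(column: Sequence[str], index: int = 0) -> ColumnEntropy:
    """Shannon entropy H = -sum P(a) log2 P(a) over non-gap residues.

    Gaps are excluded from the frequencies; a column with fewer than two
    non-gap residues carries no conservation signal and is flagged with
    ``entropy=None``.  Non-amino-acid characters are an error.
    """
    if len(column) == 0:
        raise ValueError("empty column")
    residues = []
    for ch in column:
        c = ch.upper()
        if c in GAP_CHARS:
            continue
        if c not in VALID_RESIDUES:
            raise ValueError(f"non-amino-acid character {ch!r} in column {index}")
        residues.append(c)
    if len(residues) < 2:
        return ColumnEntropy(index=index, entropy=None, frequencies={})
    n = len(residues)
    freqs: dict[str, float] = {}
    for c in residues:
        freqs[c] = freqs.get(c, 0.0) + 1.0
    freqs = {c: k / n for c, k in freqs.items()}
    h = -sum(p * math.log2(p) for p in freqs.values())
    return ColumnEntropy(index=index, entropy=h, frequencies=freqs)


def alignment_entropies(alignment) -> list[float | None]:
    """Per-column entropies for a Bio.Align alignment or list of strings."""
    rows = [str(getattr(rec, "seq", rec)) for rec in alignment]
    if not rows:
        raise ValueError("empty alignment")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("ragged alignment rows")
    return [
        column_entropy([r[i] for r in rows], index=i).entropy
        for i in range(width)
    ]


@dataclass
class RLCScore:
    position: int  # 0-based column index
    window: tuple[int, int]
    mu: float
    sigma: float
    rlc: float


def rlc(entropies: Sequence[float | None], i: int, window: int = RLC_WINDOW) -> RLCScore:
    """Relative local conservation of column ``i``.

    rlc_i = (mu_i - CSV_i) / sigma_i where mu_i and sigma_i are the mean and
    (population) standard deviation of the column entropies in
    [i - window, i + window], clipped at the alignment ends.  A window with
    zero spread gives rlc = 0; flagged (None) columns are skipped in the
    window statistics.
    """
    n = len(entropies)
    if not 0 <= i < n:
        raise IndexError(f"column {i} outside alignment of width {n}")
    lo, hi = max(0, i - window), min(n - 1, i + window)
    vals = [e for e in entropies[lo : hi + 1] if e is not None]
    if len(vals) < 2:
        raise ValueError(f"window around column {i} has fewer than 2 scored columns")
    csv_i = entropies[i]
    if csv_i is None:
        raise ValueError(f"column {i} has no entropy (all-gap or near-empty)")
    mu = float(np.mean(vals))
    sigma = float(np.std(vals))
    value = 0.0 if sigma == 0.0 else (mu - csv_i) / sigma
    return RLCScore(position=i, window=(lo, hi), mu=mu, sigma=sigma, rlc=value)


@dataclass
class MotifConservation:
    span: tuple[int, int]  # 1-based inclusive alignment columns
    mean_rlc: float
    per_position: list[float]


def motif_conservation(
    alignment, span: tuple[int, int], window: int = RLC_WINDOW
) -> MotifConservation:
    """Mean per-position RLC over a motif span (1-based inclusive columns).

    Positions whose column is all-gap (or nearly) are skipped with a warning.
    """
    entropies = alignment_entropies(alignment)
    start, end = span
    if not (1 <= start <= end <= len(entropies)):
        raise ValueError(f"span {span} outside alignment of width {len(entropies)}")
    scores: list[float] = []
    skipped = 0
    for col in range(start - 1, end):
        if entropies[col] is None:
            skipped += 1
            continue
        scores.append(rlc(entropies, col, window=window).rlc)
    if skipped:
        warnings.warn(f"skipped {skipped} all-gap column(s) inside motif span {span}")
    if not scores:
        raise ValueError(f"no scorable columns in motif span {span}")
    return MotifConservation(span=span, mean_rlc=float(np.mean(scores)),
                             per_position=scores)


def bin_by_conservation(
    edge_scores: Mapping[tuple[str, str], Iterable[float]], n_bins: int
) -> list[list[tuple[str, str]]]:
    """Rank DLI edges by their best motif conservation and split into bins.

    Edges are ordered by the maximum conservation score of their motifs
    (descending; ties broken by edge identifier for stability) and divided
    into ``n_bins`` near-equal groups, the earlier groups taking the extra
    edges when the split is uneven.
    """
    items = []
    for edge, scores in edge_scores.items():
        scores = list(scores)
        if not scores:
            raise ValueError(f"edge {edge} has no scored motifs")
        items.append((edge, max(scores)))
    if len(items) < n_bins:
        raise ValueError(f"{len(items)} edges cannot fill {n_bins} bins")
    items.sort(key=lambda t: (-t[1], t[0]))
    n = len(items)
    base, extra = divmod(n, n_bins)
    bins: list[list[tuple[str, str]]] = []
    pos = 0
    for b in range(n_bins):
        size = base + (1 if b < extra else 0)
        bins.append([e for e, _ in items[pos : pos + size]])
        pos += size
    return bins
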