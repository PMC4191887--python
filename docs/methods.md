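# Methods

This note documents the models implemented in `modulin`, the parameter
choices that matter, the design decisions taken where the method left room,
and what the synthetic experiments do and do not establish.

## Interface classification

An interaction is *DDI-eligible* when some domain on one endpoint and some
domain on the other form a pair present in the accepted interacting-domain
catalog (orientation ignored), and *DLI-eligible* when a motif instance on
one endpoint belongs to a class whose cognate domain occurs on the other
endpoint. Labels are assigned conservatively: DDI or DLI only when exactly
one criterion holds, otherwise `unclassified`. Keeping dual-evidence edges
out of both classes avoids diluting either class with ambiguous interfaces;
the mediating feature pairs are still recorded for diagnostics, and DDI edges
can be split into homo-DDIs (some mediating pair has identical domain ids)
and hetero-DDIs.

The predicted part of the domain-pair catalog is integrated by a
precision-weighted vote. Each prediction method k is weighted by its
precision against a structurally derived gold standard, `W_k = TP/(TP+FP)`
(a method with no predictions gets weight 0 and a warning). The confidence
score of a pair is `CS = Σ_k W_k I_k`, and pairs are accepted when
`CS > CS₀` — strictly greater, so ties at the cutoff are negatives. `CS₀` is
chosen by scanning 0.00–1.20 in 0.01 steps and maximising F1 (ties broken
toward the smaller cutoff); recall is measured against the full gold set, so
gold pairs with no prediction count as false negatives. Gold pairs bypass
scoring entirely: they define the standard and are always accepted.

Motif scanning uses a leftmost non-overlapping regex scan per class, and
discards hits overlapping any annotated domain span by one residue or more —
a linear motif is by definition outside globular regions, and this domain
filter is the operational stand-in for structure-based context filtering.
Match probabilities are computed for a declared regex dialect (fixed
residues, wildcard, character classes with negation, anchors, bounded repeats
evaluated at minimal length) as the product over positions of the summed
background probability of the allowed residues; anything outside the dialect
is rejected loudly rather than mis-scored. The background defaults to uniform
(1/20) and is configurable; the degeneracy cutoff defaults to 10⁻⁵.

## Conservation scoring

Column conservation is Shannon entropy (bits) of the non-gap residue
frequencies; columns with fewer than two non-gap residues are flagged and
skipped. The base of the logarithm is irrelevant because scores are
standardised: the relative local conservation of position i is
`RLC_i = (μ_i − H_i)/σ_i` over the window [i−10, i+10] (clipped at alignment
ends, population σ), signed so that conserved positions score high; a window
with zero spread gives 0 rather than an undefined value. RLC is invariant
under positive affine rescaling of the entropies. A motif's score is the
mean RLC over its span; edges can then be ranked by their best motif score
and split into near-equal bins (ties broken by edge identifier so the
binning is reproducible).

## Edge clustering and the permutation null

The order-4 edge clustering coefficient of (i, j) counts ordered pairs
(u, v), u a neighbour of i (≠ j), v a neighbour of j (≠ i), u ≠ v, that are
themselves connected: `C = z_obs/s_max` with `s_max` the number of candidate
pairs. Under this convention each simple 4-cycle through the edge is counted
exactly once, which the tests verify against exhaustive cycle enumeration on
the complete atlas of small connected graphs. An edge with no candidate
cycles has C defined as 0. `s_max` is the plain candidate-pair count, with no
triangle correction.

The null model for label-stratified mean clustering permutes feature
inventories: all domain instances are pooled, shuffled and redealt preserving
each protein's count, motifs likewise and independently, the edges untouched;
edges are then re-classified. Because the topology never changes, per-edge
coefficients are computed once and reused across permutations. Empirical
p-values use the +1 correction, `p = (1 + #extreme)/(n_perm + 1)`, one-sided
in the observed directions (DDI mean high, DLI mean low). Permutations in
which a label vanishes are excluded with a logged count. The default
permutation count is 10,000; the demonstrations in this repository use 199
permutations, which already bounds p at 0.005 and keeps runs fast.

## Module sets and enrichment

Annotation-derived module sets are pruned greedily from the largest group
down: a group is dropped when its Jaccard overlap with an already-kept group
exceeds 0.5 (size ties keep the lexicographically earlier id), after an
optional size filter. The pruning is a fixpoint — re-applying it changes
nothing. Edges whose endpoints are both annotated are `within` (identical
membership sets), `between` (disjoint) or `overlapping` (partial sharing);
overlapping edges are folded into the within or between row under both
conventions, which changes row counts but never the DLI/DDI column margins.
Expected cell counts are margin products, enrichment is observed/expected
(undefined cells reported as missing), and significance is a two-sided
Fisher exact test (sidedness is a design choice; the tests pin the
implementation to an exact rational tail summation).

## Modularity and detection

`m_ppi` is Newman modularity `Σ_s [l_W,s/L − (d_s/2L)²]`. The interface-aware
measure is

    M_DLI/DDI = Σ_s [ l_WD,s/l_D − (d_s^D/2l_D)²  +  l_BL,s/l_L − 2q_s(1−q_s) ],

with `q_s = d_s^L/(2 l_L)`: within-module DDIs are credited against the
degree-based chance term of the DDI family, and boundary DLIs (exactly one
endpoint in the module; each between-module DLI therefore contributes to two
modules) against the configuration-model probability `2q(1−q)` of landing on
the boundary. This per-label-normalised configuration form is the package's
interpretation of the measure's verbal description; the boundary chance term
was validated against degree-preserving, label-respecting edge rewirings
(agreement within the rewiring spread — the closed form assumes stub matching
with replacement, so a small finite-size offset remains). An absent label
family contributes 0 with a warning.

Detection is agglomerative greedy modularity optimisation: from singletons,
repeatedly apply the connected-module merge with the greatest ΔQ, tie-broken
toward the smallest module-id pair so runs are deterministic; the partition
is read off the merge-trace step with maximal modularity. The weighted
variant substitutes weighted Newman modularity (edge weights in l and L,
strengths in d) with DDIs at 100, DLIs at 0.1 and other edges at 1: strong
interfaces merge early and weak bridges late, which is what separates
motif-bridged groups that plain topology fuses. Greedy agglomeration is a
heuristic — on cleanly separated fixtures it matches exhaustive best-partition
search (verified for two bridged 5-cliques and a ring of triangles), but no
global-optimality guarantee exists in general. Modules of fewer than three
proteins are flagged and excluded from quality statistics (their proteins
keep their assignment).

Module quality is the mean pairwise annotation Jaccard over annotated protein
pairs within non-excluded modules; the fold increase divides the mean module
quality by the mean similarity over all annotated pairs, so a random
partition scores ≈ 1. Detector comparisons use a two-sample KS test and
Cohen's d with pooled SD.

## Synthetic universes

The generator plants a partition (within-module edge probability `p_in`,
between `p_out`, `p_in > p_out` for recoverable plants), biases labels the
way the analysis assumes real interactomes behave (`beta_within_ddi`,
`beta_between_dli`, both defaulting to 0.9 — a strong but imperfect division
of labour), and mirrors the partition in annotations, one term per module
plus a configurable fraction (default 0.1) of proteins given a neighbouring
module's term to exercise the overlapping-membership path.

Inventories are constructed so that re-classification provably recovers the
planted labels: each DDI edge gets a catalog domain pair, each DLI edge a
motif instance on one endpoint and the cognate domain on the other. Features
are shared (one synthetic pair or class per 10 edges) so homo/hetero splits
and shared-evidence effects are exercisable; sharing can create accidental
cross-evidence, so a verify-and-repair pass re-classifies and re-mints
dedicated single-use features for the edges involved until labels match
exactly — the loop strictly reduces feature sharing, so it terminates.
Motif carriers are chosen by a greedy cover of the DLI subgraph, emulating
motif-rich hub proteins with long disordered regions; this keeps
motif-bearing proteins a minority, without which species-level differential
retention of motif-bearing proteins would be vacuous. Sequences are uniform
random amino acids (length ≥ 300), domains occupy fixed blocks at the
N-terminal end and motif exemplars are implanted literally downstream of all
domain spans, so regex scanning finds them and the domain-overlap filter
never removes them.

Species series retain each protein independently — motif-bearing proteins
with `retention_motif_bearing`, all others with `retention_core` (default
0.8, a typical ortholog-detection rate at moderate evolutionary distance) —
and an edge is conserved when both endpoints survive; labels are re-derived
on the restricted inventories. Metazoan-like profiles use higher
motif-bearing retention (0.9 vs 0.5 in the demonstrations), emulating the
expansion of motif-mediated interactions in complex organisms.

Alignments are fixed-length (no indels): a random base sequence is mutated
per row, motif columns with probability 1 − conservation and flank columns at
rate 1 (fully randomised), substitutions uniform over the 20 amino acids. At
conservation 1 motif columns are identical; at conservation 0 they are
statistically indistinguishable from flanks.

What the generator does **not** emulate: scale-free degree distributions,
realistic residue composition or substitution models, correlated loss of
interaction partners, annotation noise beyond the overlap decoys, or
motif-gain (as opposed to differential-loss) evolution. Passing tests
establish the internal consistency and statistical behaviour of the methods
under the planted assumptions, not their accuracy on real interactomes.

## Problem sizes

The bundled experiments use networks of 100–250 proteins (modules of 25–50),
50-seed replications for rate-style claims, 199 label permutations, and
40-species series (20 per group). These sizes give stable statistics (success
rates pinned at ≥ 95%, permutation p at its 0.005 floor, Welch p ≪ 0.01 for
the robust effects) while keeping any single run to a few minutes.

## Known limitations

- **Species-level M_DLI/DDI.** Under per-protein retention, every DLI —
  boundary or within-module — requires exactly one surviving motif carrier
  and one ordinary endpoint, so differential retention rescales both kinds
  identically and the boundary fraction of surviving DLIs is group-invariant
  in expectation. Because the per-label-normalised M_DLI/DDI depends on
  label composition only through that fraction, retention-only species
  series do **not** shift it between groups (simulations show a null effect),
  even though the DLI proportion rises and topological modularity falls
  exactly as expected. A group shift in M_DLI/DDI additionally requires the
  retained (or gained) DLIs to be differentially positioned on module
  boundaries, i.e. genuine structural rewiring rather than uniform loss. The
  measure's dissociation itself is real and is demonstrated directly:
  adding boundary DLIs to a fixed network strictly lowers `m_ppi` while
  raising `m_dli_ddi`.
- The exact algebraic form of M_DLI/DDI is a declared interpretation (see
  above); alternatives that normalise by total edge count instead of
  per-label counts behave worse (the boundary term is then dominated by its
  chance term and the measure penalises DLI-rich networks).
- The weighted detector optimises weighted Newman modularity; with extreme
  weights (100 vs 0.1) on very small fixtures, a single heavy edge can
  dominate total strength and keep weight-1 members out of its module — on
  realistic inputs many DDIs share the weight mass and this artefact
  disappears.
- The CS₀ selection reproduces the published operating point only with the
  original multi-method prediction compendium as input; the implementation
  is instead pinned to a brute-force grid-scan oracle on synthetic inputs.
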