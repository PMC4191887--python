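# modulin

Interface-aware analysis of protein–protein interaction (PPI) networks.

Protein interactions are not all alike. Strong **domain–domain interactions
(DDIs)** form large, stable interfaces between globular domains, while weak
**domain–linear-motif interactions (DLIs)** are transient contacts between a
short peptide motif (typically in a disordered region) and a binding domain.
`modulin` classifies the edges of a PPI network by interface type and asks
what each type does to the network's modular architecture: DDIs behave like
the strong ties of social networks, concentrating inside modules, while DLIs
behave like weak ties, bridging different modules. The package quantifies
this division of labour, exploits it to detect better biological modules, and
reproduces the expected evolutionary trend on synthetic species series.

## What it computes

- **Edge classification** — an edge is a DDI if its endpoints carry an
  interacting domain pair from an accepted catalog, a DLI if one endpoint
  carries a motif instance whose class binds a domain on the other endpoint,
  and unclassified when both or neither criterion holds. The predicted part
  of the domain-pair catalog is scored by a precision-weighted vote over
  prediction methods, `CS(i,j) = Σ_k W_k I_k(i,j)` with `W_k = TP/(TP+FP)`,
  thresholded at the F1-optimal cutoff `CS₀` found by a grid scan.
- **Motif hygiene** — regex scanning with a domain-overlap filter, match
  probabilities under a residue background (degenerate patterns with
  `p > 10⁻⁵` can be dropped), and conservation scoring: per-column Shannon
  entropy standardised in a ±10-column window (relative local conservation,
  RLC = (μ − H)/σ, averaged over the motif span).
- **Topology** — the order-4 edge clustering coefficient
  `C(i,j) = z_obs / s_max` (realised over possible 4-cycles through the
  edge), with an inventory-permutation null: domains and motifs are shuffled
  across proteins preserving per-protein counts, edges are re-classified, and
  one-sided empirical p-values are reported for the label-stratified means.
- **Module enrichment** — annotation-derived module sets (heavily overlapping
  terms pruned at Jaccard > 0.5), each labelled edge categorised as
  within/between/overlapping, and a 2×2 contingency table
  {between, within} × {DLI, DDI} with observed/expected enrichment ratios and
  a two-sided Fisher exact p.
- **Modularity** — Newman modularity
  `M_PPI = Σ_s [l_W,s/L − (d_s/2L)²]` and the interface-aware revision
  `M_DLI/DDI = Σ_s [l_WD,s/l_D − (d_s^D/2l_D)² + l_BL,s/l_L − 2q_s(1−q_s)]`,
  which credits DDIs for sitting inside modules and DLIs for sitting on
  module boundaries (`q_s` is the module's share of DLI degree).
- **Module detection** — agglomerative greedy modularity optimisation with a
  deterministic tie-break and a full merge trace; the interface-weighted
  variant runs the same algorithm with DDIs at weight 100 and DLIs at 0.1, so
  strong interfaces drive early merges and weak bridges are deferred. Module
  quality is the mean pairwise annotation Jaccard within modules (pair-only
  modules excluded), compared across detectors by KS test and Cohen's d.
- **Species series** — projection of a reference network onto species via
  ortholog maps, with per-species re-classification and group comparisons
  (Welch t-test) of DLI proportion and both modularity measures.
- **Synthetic data** — seeded planted-partition universes whose inventories
  are constructed so that re-classification recovers the planted labels
  exactly, plus alignments with conserved motif columns and species series
  with differential retention of motif-bearing proteins.

## Worked example

```python
from modulin import (PlantedModel, WeightScheme, classify_edges,
                     generate_universe, greedy_modules, m_ppi, m_dli_ddi,
                     mean_label_clustering, module_quality)

model = PlantedModel(module_sizes=(25, 25, 25, 25), p_in=0.3, p_out=0.03,
                     beta_within_ddi=0.9, beta_between_dli=0.9,
                     overlap_fraction=0.2, seed=0)
u = generate_universe(model)

labelled = classify_edges(u.network, u.inventories,
                          u.catalogs.ddi_pairs, u.catalogs.motif_classes)
print(labelled.label_counts())

clust = mean_label_clustering(labelled)
print(f"mean C: DDI={clust.mean['DDI']:.3f}  DLI={clust.mean['DLI']:.3f}  "
      f"KS p={clust.ks_p:.2g}")

weighted = greedy_modules(labelled, weights=WeightScheme())   # DDI=100, DLI=0.1
plain = greedy_modules(labelled)
print(f"quality weighted={module_quality(weighted.partition, u.annotations).mean_quality:.3f}  "
      f"unweighted={module_quality(plain.partition, u.annotations).mean_quality:.3f}")
print(f"M_PPI={m_ppi(labelled, u.truth_partition):.3f}  "
      f"M_DLI/DDI={m_dli_ddi(labelled, u.truth_partition):.3f}")
```

Output:

```
{'DDI': 325, 'DLI': 135, 'unclassified': 0}
mean C: DDI=0.166  DLI=0.088  KS p=1.2e-29
quality weighted=0.830  unweighted=0.777
M_PPI=0.499  M_DLI/DDI=0.783
```

The classifier recovers the planted labels (no unclassified edges remain);
DDI edges are roughly twice as clustered as DLI edges, because within-module
edges (mostly DDIs here) close many 4-cycles while between-module bridges
(mostly DLIs) close few; and down-weighting the weak bridges during detection
yields modules whose members share more annotations (0.830 vs 0.777 mean
within-module annotation Jaccard).

The same analyses are available from the shell:

```
modulin synth --config run.yaml --outdir data/
modulin classify --network data/network.tsv --domains D.tsv \
    --motif-classes M.tsv --ddi-gold G.tsv --ddi-pred P.tsv --cutoff auto --out labeled.tsv
modulin topology --network labeled.tsv --g 4 --out clustering.tsv
modulin enrich --network labeled.tsv --annotations A.tsv --overlap-mode both --out enrich.json
modulin detect --network labeled.tsv --weights 100,0.1,1 --out-partition part.tsv
modulin run --config run.yaml --outdir out/
```

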