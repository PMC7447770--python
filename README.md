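# episcape

Similarity-graph analysis of epidermal single-cell RNA-seq: soft
clustering by symmetric non-negative matrix factorization, cellular
entropy as a per-cell estimate of transition potency, graph shortest-path
pseudotime with minimum-spanning-tree lineage inference,
pseudotime-dependent gene dynamics, and probabilistic ligand–receptor
cell–cell communication.

## Who this is for

Human interfollicular epidermis is maintained by basal stem cells that
differentiate through spinous and granular layers. Droplet scRNA-seq of
such tissue yields a sparse gene-by-cell count matrix in which several
basal stem-cell states (BAS-I–IV), spinous (SPN), granular (GRN) and
melanocyte (MEL) populations coexist, connected by a bifurcating
differentiation trajectory. `episcape` implements the full analysis a
study of this kind needs, as a tested, reusable library:

- **QC and normalization** with the standard droplet filters (cells with
  >200 and <5000 detected genes, <10% mitochondrial counts; genes in ≥3
  cells; depth normalization to 10,000 counts and natural-log transform).
- **A cell–cell similarity graph** (PCA projection → positive-part
  Pearson correlation → symmetric k-nearest-neighbor graph) that is the
  single substrate for clustering, pseudotime, embedding and the
  landscape.
- **Soft clustering** by symmetric NMF, `min ‖S − HHᵀ‖²_F, H ≥ 0`, whose
  row-normalized factors give the probability `P[i,j]` that cell `i`
  belongs to community `j`; the community count comes from the Laplacian
  eigengap.
- **Cellular entropy** `ξᵢ = −Σⱼ P[i,j]·ln P[i,j]`: zero for a cell
  committed to one community, `ln K` for a maximally uncertain cell —
  an estimate of how likely the cell is to transition between states —
  rendered as a Waddington landscape over a 2-D embedding (valleys =
  stable states, mountains = transition-prone regions).
- **Trajectory inference**: pseudotime as normalized shortest-path
  distance from a chosen root cell (edge length `1 − S`), a lineage tree
  as the MST of mean inter-cluster graph distances with soft-assignment
  transition weights, rolling-wave ordering of pseudotime-dependent
  genes, temporal pattern discovery, and a differentiation score.
- **Cell–cell communication**: for each ligand–receptor pair with
  up-/down-regulated target genes, a sender→receiver probability matrix
  (thresholded at φ = 0.1), cluster-level networks, pattern-based
  grouping of pairs, and an inter-library consistency score
  `1 − Σ|ref − target| / #nonzero-ref`.
- **A synthetic epidermis generator** with full ground truth (community
  labels, latent differentiation time, marker programs, temporal
  archetypes, planted signaling routes, low-quality cells), so every
  stage is testable without external data.

## Worked example

```python
from episcape import (epidermis_preset, generate, filter_cells, filter_genes,
                      normalize_log, select_hvgs, build_similarity,
                      estimate_num_clusters, soft_cluster, cellular_entropy,
                      aggregate_entropy)

config = epidermis_preset()            # 3,000 cells, 2,000 genes, 7 communities
counts, truth = generate(config, seed=1)
qc = filter_genes(filter_cells(counts))
print(f"{qc.n_cells} of {counts.n_cells} cells pass QC")

norm = normalize_log(qc)
hvgs = select_hvgs(norm, 3000)
S = build_similarity(norm, hvgs)
K = estimate_num_clusters(S)
print(f"estimated number of communities: K = {K}")

assignment = soft_cluster(S, K, seed=1)
xi = cellular_entropy(assignment)
print(aggregate_entropy(xi, assignment.hard_labels).round(3).to_string(index=False))
```

prints

```
2736 of 3000 cells pass QC
estimated number of communities: K = 7
 cluster  mean_xi  median_xi    n  rank
       5    0.309      0.098  300     1
       1    0.131      0.001  537     2
       2    0.068      0.003 1284     3
       0    0.051      0.000  122     4
       4    0.033      0.000  228     5
       6    0.004      0.000   93     6
       3    0.001      0.000  172     7
```

The eigengap recovers the seven planted communities; 264 cells were
removed by QC (the generator plants ~8% deliberately corrupted cells
plus a small tail of genuinely borderline ones). Cluster 5 here is the
BAS-III-centered population sitting at the bifurcation toward BAS-IV and
SPN and absorbing transitional spinous cells — exactly the cells whose
membership distributions are mixed, hence the highest mean entropy.
Cluster 3 is the off-trajectory melanocyte community and cluster 6 the
compact BAS-IV state; both are committed, with entropy near zero.

The full pipeline (clustering → entropy/landscape → trajectory →
signaling, with all outputs and a reproducibility manifest) runs with

```bash
episcape run --out my_run --seed 1        # synthetic preset
episcape simulate --out fixture --seed 1  # write a 10x-style fixture
episcape qc --input fixture --out qc.tsv  # QC report for any 10x-style input
```

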