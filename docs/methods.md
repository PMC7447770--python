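# Methods

This note documents the models and procedures implemented in
`episcape`, the parameters that matter, the design choices made where
the design was genuinely open, and what the synthetic data generator
does and does not emulate.

## Quality control and normalization

Cells are kept when they satisfy, with strict inequalities, more than
200 and fewer than 5,000 detected genes (count > 0) and a mitochondrial
count fraction below 10%; genes expressed in fewer than 3 cells are
dropped. Thresholds are identical for every library, so filtering is
per-library by construction. Mitochondrial genes are identified by the
case-insensitive `MT-` symbol prefix. The mitochondrial fraction is
computed on raw counts *before* gene filtering (cell filters are applied
first; an `io_qc` flag order is fixed and recorded in provenance).
Normalization is depth scaling to 10,000 counts per cell followed by
`ln(1 + x)`; the transform maps zeros to zeros, so the sparsity pattern
of the counts is preserved exactly.

Highly variable genes are selected by principal-component loading: genes
are z-scored (clipped at ±10 to bound outlier influence), a PCA is
computed, the number of informative components *k* is the position of
the largest drop between consecutive PC variances (searched over the
first 20 gaps, ties toward smaller *k*), and each gene is scored by its
maximum absolute loading over those *k* components; the top *n* (3,000
by default, 10,000 for the trajectory re-analysis) are kept. Constant
genes score zero and are never selected.

## Similarity graph

All downstream inference runs on one symmetric, non-negative cell–cell
affinity matrix S with zero diagonal. The construction: project the
z-scored HVG submatrix onto its 20 leading principal components, take
the positive part of the Pearson correlation between the cells' PC
coordinate vectors, keep each cell's k = max(10, ⌈n/100⌉) largest
entries, and symmetrize by averaging with the transpose. A fixed
projection depth is used rather than the scree-gap rule applied in HVG
selection: the gap rule truncates to the dominant contrast alone on
scree-like spectra, discarding the weaker gradients that order cells
within a community, while 20 components retain both the
between-community contrasts and the within-community trajectory
structure. The construction is confined to `build_similarity` so
alternatives can be swapped in.

## Community count and soft clustering

The number of communities is estimated from the spectrum of the
symmetric normalized graph Laplacian, taken in ascending order, as the
position of the largest *relative* eigengap
(λ_{i+1} − λ_i)/max(λ_{i+1}, 0.01) among the first 20 eigenvalues (ties
toward smaller K). The relative form compensates for the upward drift
of the spectrum; the 0.01 floor keeps near-zero eigenvalues of weakly
connected blocks from dominating, while exact graph components still
give the textbook zero-multiplicity answer. Eigenvalues are computed
per connected component (a Lanczos run on the whole graph can silently
under-resolve a degenerate zero eigenvalue of multiplicity equal to the
component count). The user may override K.

Soft memberships come from symmetric NMF, `min ‖S − HHᵀ‖²_F` over
H ≥ 0 (n × K), using the damped multiplicative update
`H ← H ∘ (½ + (SH)/(2 HHᵀH))`, which is non-increasing in the
objective. Ten seeded restarts (seed + restart index) are run to
`max_iter = 500` or relative objective change below 1e−6, and the best
objective wins. P is H with rows rescaled to sum one; an all-zero row
(never observed in practice) becomes the uniform distribution and is
counted. Hard labels are the per-row argmax with ties to the lowest
index.

Markers are one-vs-rest per cluster: a gene qualifies when expressed in
≥25% of the cluster's cells with a mean natural-log expression
difference ≥0.25 over the rest ("0.25-fold" read as a 0.25 difference of
log-normalized means, the convention of the standard marker-finding
tools); significance is a two-sided Wilcoxon rank-sum test with
Benjamini–Hochberg adjustment per cluster, ranking by adjusted p then
log-fold difference. Clusters under 3 cells are skipped with a warning.
Two clusterings are compared by the matrix of top-500 marker-list
intersections.

The 2-D embedding is a nonlinear layout of the graph's geodesic
distances (edge length 1 − S, all-pairs shortest paths, disconnected
pairs set to 1.2 × the largest finite distance) by metric stress
majorization (SMACOF) from a classical-MDS initialization with a
deterministic sign convention; fixed seeds give identical coordinates.

## Cellular entropy and the Waddington landscape

A cell's entropy is ξᵢ = −Σⱼ P[i,j] ln P[i,j] with 0·ln 0 = 0. The
natural logarithm is used, so ξ ∈ [0, ln K]; a ln(K)-normalized variant
in [0, 1] is also emitted because reported entropy scales differ across
studies. Cluster-level aggregation reports the mean (and median) per
cluster, ranked by mean. The landscape is a Gaussian-kernel weighted
average of cell entropies over a grid spanning the embedding bounding
box plus 5% margin; the bandwidth is a fraction (default 0.05) of the
box diagonal. Grid points with total kernel weight below 1e−6 are set
to a background of 1.1 × max ξ so that unpopulated regions read as
mountains; the background rule is a rendering convention and is
configurable.

## Trajectory

Off-trajectory populations (melanocytes in the synthetic preset;
melanocytes and Langerhans cells in real epidermis) are excluded by
label, the remaining cells are re-normalized and re-analyzed with
10,000 HVGs, and a root cell is designated by the user (in simulated
runs, the cell with the smallest latent time).

Pseudotime is the single-source shortest-path distance from the root on
the similarity graph with edge length 1 − S (the alternative 1/S is
selectable), divided by the largest finite distance. Cells outside the
root's connected component are an error unless restriction is requested;
a root component under half the cells is always an error.

The lineage tree is the minimum spanning tree of the cluster-to-cluster
graph whose edge lengths are mean shortest-path distances between member
cells (exact below 200 members, else over 200 seeded uniformly sampled
members; on preset data subsampling reproduces exact distances within
10% relative error, dominated by small within-cluster entries). The tree
is rooted at the root cell's cluster; each cluster's order statistic is
the mean member distance to the root, and each parent→child edge weight
is the mean soft-membership mass of the parent's hard-assigned cells in
the child's column, normalized over the parent's tree children (so
outgoing weights form a distribution).

Pseudotime-dependent genes are the union of each cluster's top-100
markers. Profiles are per-bin mean expression along pseudotime,
moving-average smoothed and z-scored, with genes ordered by smoothed
peak position (the rolling wave). Bins are *equal-occupancy* (equal
cell counts per bin) rather than equal-width: every bin mean then has
the same sampling variance, and stretches of the trajectory where cells
are sparse — the early basal segment — keep their resolution. The
rolling wave uses 50 bins with a 5-bin window; pattern discovery uses a
finer 80-bin, 3-bin-window setting (recorded in the pipeline config)
because distinguishing the two earliest temporal programs needs the
extra early-trajectory resolution. Patterns are found by Ward-linkage
agglomerative clustering of the z-scored profiles, with the cluster
count chosen at the largest relative gap in merge heights over k = 2…10
unless fixed. The differentiation score of a gene set is the per-cell
mean of min-max-scaled expression over the set, averaged per cluster.

## Cell–cell communication

A pathway record is (pathway, ligand, receptor, up-targets,
down-targets). The cell-level scoring kernel is a documented package
choice satisfying the standard contract (ligand, receptor and target
expression combine into a sender→receiver probability): sender weight
aᵢ = ligand expression / cohort max; receiver weight bⱼ = receptor
expression / max; target activity tⱼ = ½[mean up-target scaled
expression + mean (1 − scaled expression) over down-targets], a missing
set dropping its term and both missing giving tⱼ = 1; raw score
sᵢⱼ = aᵢbⱼtⱼ; probabilities pᵢⱼ = sᵢⱼ/Σⱼ′ sᵢⱼ′ per sender (zero when
the denominator is zero). Entries below φ = 0.1 are zeroed when the
threshold is applied. Because the score is rank-one in (i, j), row
normalization cancels the sender magnitude: a sender either signals
(ligand detected) with the common receiver distribution, or not at all.
One consequence deserves emphasis: with receivers numbering in the
thousands, every pᵢⱼ is far below 0.1, so a cell-level φ empties the
network; φ is therefore meaningful on small cohorts (or at cluster
level), and the pipeline's default reports raw cluster averages, with
cell- and cluster-level thresholding selectable.

Cluster networks average pᵢⱼ over all (sender, receiver) cell pairs of
two clusters. Ligand–receptor pairs are grouped by flattening their
cluster matrices, projecting to 2-D with a seeded t-SNE (PCA below five
pairs, where no perplexity is valid) and cutting an average-linkage
dendrogram at the largest merge-height gap; each group's mean matrix is
emitted. The consistency of a target library against a reference is
1 − Σ|ref − target| / #nonzero-ref-entries, over entries nonzero in the
reference ("overlapped" read as reference-nonzero; differences read as
absolute values); a reference with no nonzero entries yields a missing
value.

## Synthetic epidermis generator

The generator emulates the statistical structure of droplet scRNA-seq
of neonatal human interfollicular epidermis: 3,000 cells, 2,000 genes,
5 libraries; seven communities at proportions BAS-I 4%, BAS-II 9%,
BAS-III 7%, BAS-IV 3%, SPN 54%, GRN 17%, MEL 6% (the printed shares of
the tissue sum to 99%; the granular community absorbs the remainder);
150 disjoint marker genes per community; a bifurcating lineage
BAS-I→BAS-II→BAS-III→{BAS-IV, SPN}, SPN→GRN with melanocytes off the
trajectory; six temporal archetypes (one early-declining, four
transient Gaussian peaks at latent times 0.2/0.4/0.6/0.8, one
late-rising) driving 50 genes each; four planted signaling routes (WNT
BAS-I→BAS-II, NOTCH BAS-III→SPN, TGFB BAS-IV→BAS-III, JAK/STAT
SPN→GRN); and 13 mitochondrial genes named `MT-*`.

Counts are negative binomial with shared dispersion 0.3 around a mean
that combines a lognormal gene baseline (σ = 0.8), the community marker
multiplier (6×), the temporal archetype evaluated at the cell's latent
time (multiplier 0.3 + 1.0 × shape), and signaling multipliers (ligand
4× in senders; receptor and up-targets 4×, down-targets 0.25× in
receivers), rescaled per cell so that the expected total equals a
lognormal depth (median 6,000, σ_log 0.35) split between a Beta(2, 70)
mitochondrial fraction and the rest. Temporal modulation is
deliberately weaker than the marker programs: in the tissue this
emulates, community identity dominates within-community temporal
drift — clustering resolves the communities even though a continuous
trajectory runs through them.

Latent time: each on-trajectory community occupies a unit window along
its lineage path; at a bifurcation the main continuation (larger
subtree) starts where the parent's window ends while side branches bud
from the parent's mid-window, and windows are rescaled so the latest
leaf ends at 1. The stagger makes the planted tree also the tree of
shortest generative distances (with synchronous branch points, the
side branch and the main branch are equidistant from each other's
cells, and the inferred MST becomes a coin flip). Near every lineage
boundary the two adjacent marker programs cross-fade over a latent-time
scale of 0.02, so transitional cells are genuinely intermediate and the
trajectory is a connected continuum rather than disconnected islands —
these boundary cells are also the ones that legitimately carry high
cellular entropy.

A configurable fraction (default 8%) of cells is corrupted to violate
QC: either all but 120 random non-mitochondrial genes are zeroed
(fails only the minimum-genes filter) or the mitochondrial fraction is
raised to 15–35% (fails only the mitochondrial filter); a
too-many-genes mode exists when the gene universe exceeds 5,000. Each
corrupted cell fails exactly the filter it was built to fail.

What the generator does **not** emulate: doublets, ambient RNA, batch
effects (none were observed in the tissue this emulates), zero
inflation beyond the negative binomial, spliced/unspliced layers, and
realistic gene–gene correlation beyond the planted programs. Passing
tests therefore demonstrate that the pipeline recovers planted
structure of realistic strength and shape at realistic sparsity — not
that it is robust to artifacts the generator does not produce.

## Determinism and numerics

Every stochastic step takes an explicit seed; restart seeds derive from
it by fixed offsets, and the pipeline fans one top-level seed into its
stages, so a configuration and seed reproduce every output byte for
byte. Degenerate inputs are handled explicitly: single-cell graphs,
empty QC results, constant genes (never HVGs), constant temporal
profiles (flagged, z-score left at zero), all-zero membership rows
(uniform), silent ligands (zero network), all-zero consistency
references (missing value). Ties break toward the smaller index or
smaller k throughout. The problem sizes used in the test and acceptance
runs (3,000-cell preset, 20-seed trajectory replicates, 10-seed
clustering and signaling replicates) were chosen as the smallest at
which the planted effects are comfortably above sampling noise.

## Known limitations

- The similarity construction and the signaling kernel are documented
  stand-ins for method families whose published objectives vary; both
  sit behind single functions precisely so they can be replaced.
- Per-sender normalization makes the cell-level signaling probability
  insensitive to ligand magnitude (only to ligand detection); a kernel
  without row normalization would behave differently at cluster level.
- The eigengap estimate assumes communities are expressed in the
  graph's spectrum; for continuously blending populations it
  under-counts, and K should then be fixed by the user.
- Pseudotime is a graph metric: it compresses regions of low cell
  density, so positions along it are ordinal, not proportional to
  biological time — the equal-occupancy binning partially compensates.
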