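"""Graph pseudotime, lineage-tree inference and pseudotime-dependent genes.

Pseudotime is the single-source shortest-path distance from a
user-chosen root cell on the similarity graph (edge length 1 - S),
normalized to [0, 1]. The lineage tree is the minimum spanning tree of
the cluster-to-cluster graph whose edge lengths are mean shortest-path
distances between member cells; each cluster's order statistic is the
mean distance of its members to the root, and each parent->child edge
carries a transition probability derived from the soft cluster
memberships of the parent's cells. Off-trajectory populations
(melanocytes, Langerhans cells) are excluded by label before these
analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, dijkstra, minimum_spanning_tree

from .clustering import SimilarityMatrix, SoftAssignment, find_markers, top_markers
from .io_qc import NormalizedMatrix

__all__ = [
    "PseudotimeVector",
    "LineageTree",
    "TemporalProfiles",
    "compute_pseudotime",
    "infer_lineage",
    "pseudotime_dependent_genes",
    "cluster_temporal_patterns",
    "differentiation_score",
]


@dataclass
class PseudotimeVector:
    """Normalized shortest-path pseudotime; NaN outside the root component."""

    t: np.ndarray
    distances: np.ndarray  # unnormalized shortest-path distances
    root: int
    n_unreachable: int


@dataclass
class LineageTree:
    """Rooted MST over clusters with order statistics and transition weights."""

    tree: nx.DiGraph  # edges parent -> child with 'weight' (transition prob.)
    root_cluster: object
    order: pd.Series  # mean member distance to root, per cluster
    distances: pd.DataFrame  # cluster-to-cluster mean shortest-path distances

    @property
    def edges(self) -> list[tuple]:
        return list(self.tree.edges)

    def undirected_edge_set(self) -> set[frozenset]:
        return {frozenset(e) for e in self.tree.edges}

    def to_json_dict(self) -> dict:
        return {
            "root": str(self.root_cluster),
            "nodes": [
                {"cluster": str(c), "order": float(self.order[c])}
                for c in self.tree.nodes
            ],
            "edges": [
                {
                    "parent": str(u),
                    "child": str(v),
                    "weight": float(self.tree.edges[u, v]["weight"]),
                }
                for u, v in self.tree.edges
            ],
        }


@dataclass
class TemporalProfiles:
    """Binned, smoothed, z-scored gene dynamics along pseudotime."""

    profiles: pd.DataFrame  # genes x bins (z-scored)
    peak_bin: pd.Series
    bin_centers: np.ndarray
    constant_genes: list[str] = field(default_factory=list)

    @property
    def rolling_wave_order(self) -> list[str]:
        """Genes ordered by the position of their smoothed peak."""
        order = self.peak_bin.sort_values(kind="stable")
        return order.index.tolist()

    def peak_time(self, gene: str) -> float:
        return float(self.bin_centers[int(self.peak_bin[gene])])


def _edge_graph(S: sp.csr_matrix) -> sp.csr_matrix:
    W = S.copy().tocsr()
    W.data = 1.0 - W.data
    W.data[W.data <= 0] = 1e-9
    return W


def compute_pseudotime(
    S: SimilarityMatrix,
    root_cell: int,
    restrict_to_root_component: bool = False,
) -> PseudotimeVector:
    """Shortest-path pseudotime from ``root_cell`` (edge length 1 - S).

    Distances are normalized by the maximum finite distance. Cells
    outside the root's connected component get NaN; unless
    ``restrict_to_root_component`` is set their presence is an error,
    and a root component smaller than half the cells is always an error.
    """
    n = S.n_cells
    if not 0 <= root_cell < n:
        raise ValueError(f"root cell {root_cell} not in graph of {n} cells")
    W = _edge_graph(S.S)
    n_comp, memb = connected_components(S.S, directed=False)
    comp_sizes = np.bincount(memb)
    root_comp = memb[root_cell]
    if comp_sizes[root_comp] < 0.5 * n:
        raise ValueError(
            f"root component holds {comp_sizes[root_comp]}/{n} cells "
            f"(<50%); component sizes: {sorted(comp_sizes, reverse=True)}"
        )
    d = dijkstra(W, directed=False, indices=root_cell)
    unreachable = ~np.isfinite(d)
    if unreachable.any() and not restrict_to_root_component:
        raise ValueError(
            f"{int(unreachable.sum())} cells are unreachable from the root; "
            "pass restrict_to_root_component=True to drop them"
        )
    dmax = d[~unreachable].max()
    t = d / dmax if dmax > 0 else np.zeros_like(d)
    t[unreachable] = np.nan
    return PseudotimeVector(
        t=t, distances=d, root=root_cell, n_unreachable=int(unreachable.sum())
    )


def _cluster_distances(
    S: sp.csr_matrix,
    labels: np.ndarray,
    max_cells: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean shortest-path distance between member cells of each cluster
    pair; clusters above ``max_cells`` members are uniformly subsampled
    (seeded)."""
    rng = np.random.default_rng(seed)
    W = _edge_graph(S)
    clusters = pd.unique(labels)
    samples = {}
    for cl in clusters:
        idx = np.flatnonzero(labels == cl)
        if len(idx) > max_cells:
            idx = np.sort(rng.choice(idx, size=max_cells, replace=False))
        samples[cl] = idx
    sources = np.concatenate([samples[cl] for cl in clusters])
    D = dijkstra(W, directed=False, indices=sources)
    out = pd.DataFrame(0.0, index=pd.Index(clusters), columns=pd.Index(clusters))
    offs = np.cumsum([0] + [len(samples[cl]) for cl in clusters])
    for i, a in enumerate(clusters):
        rows = D[offs[i] : offs[i + 1]]
        for b in clusters:
            block = rows[:, samples[b]]
            finite = np.isfinite(block)
            out.loc[a, b] = float(block[finite].mean()) if finite.any() else np.inf
    return out


def infer_lineage(
    S: SimilarityMatrix,
    labels: np.ndarray,
    P: SoftAssignment,
    pt: PseudotimeVector,
    max_cells_per_cluster: int = 200,
    seed: int = 0,
) -> LineageTree:
    """Minimum spanning tree over clusters, rooted at the root cell's
    cluster, with soft-assignment transition weights.

    The transition weight of a parent->child edge is the mean membership
    mass of the parent's hard-assigned cells in the child's cluster,
    normalized over the parent's tree children (so each parent's
    outgoing weights sum to one).
    """
    labels = np.asarray(labels)
    clusters = list(pd.unique(labels))
    cl_index = {c: i for i, c in enumerate(clusters)}
    dist = _cluster_distances(S.S, labels, max_cells=max_cells_per_cluster, seed=seed)
    root_cluster = labels[pt.root]
    if len(clusters) == 1:
        tree = nx.DiGraph()
        tree.add_node(clusters[0])
        order = pd.Series({clusters[0]: 0.0})
        return LineageTree(tree, root_cluster, order, dist)
    D = dist.to_numpy(copy=True)
    finite = np.isfinite(D)
    if not finite.all():
        D[~finite] = 10.0 * np.nanmax(np.where(finite, D, np.nan))
    mst = minimum_spanning_tree(sp.csr_matrix(np.triu(D, k=1)))
    G = nx.Graph()
    G.add_nodes_from(clusters)
    r_idx, c_idx = mst.nonzero()
    for i, j in zip(r_idx, c_idx):
        G.add_edge(clusters[i], clusters[j])
    # orient away from the root cluster
    tree = nx.bfs_tree(G, root_cluster)
    # order statistic: mean member distance to the root cell
    order = {}
    for cl in clusters:
        d = pt.distances[labels == cl]
        d = d[np.isfinite(d)]
        order[cl] = float(d.mean()) if len(d) else np.inf
    order = pd.Series(order)
    # transition weights from soft memberships of the parent's cells
    hard = P.hard_labels
    for parent in tree.nodes:
        children = list(tree.successors(parent))
        if not children:
            continue
        parent_cells = np.flatnonzero(
            labels == parent
        ) if P.P.shape[0] == len(labels) else None
        mass = []
        for ch in children:
            j = cl_index[ch]
            mass.append(float(P.P[parent_cells, j].mean()))
        mass = np.asarray(mass)
        total = mass.sum()
        w = mass / total if total > 0 else np.full(len(children), 1.0 / len(children))
        for ch, wi in zip(children, w):
            tree.edges[parent, ch]["weight"] = float(wi)
    return LineageTree(tree, root_cluster, order, dist)


def _bin_profiles(
    x: np.ndarray, t: np.ndarray, bins: int, window: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean expression per pseudotime bin, moving-average smoothed.

    Bins are equal-occupancy (each holds the same number of cells, in
    pseudotime order) so every bin mean has the same sampling variance
    and cell-sparse stretches of the trajectory keep their resolution.
    ``centers`` is the mean pseudotime of each bin's cells.
    """
    n = len(t)
    bins = min(bins, n)
    ranks = np.empty(n, dtype=int)
    ranks[np.argsort(t, kind="stable")] = np.arange(n)
    which = np.minimum((ranks / n * bins).astype(int), bins - 1)
    sums = np.zeros((bins, x.shape[1]))
    counts = np.zeros(bins)
    tsums = np.zeros(bins)
    np.add.at(sums, which, x)
    np.add.at(counts, which, 1.0)
    np.add.at(tsums, which, t)
    filled = counts > 0
    means = sums[filled] / counts[filled, None]
    centers = tsums[filled] / counts[filled]
    window = min(window, len(means))
    kernel = np.ones(window) / window
    pad = window // 2
    sm = np.apply_along_axis(
        lambda v: np.convolve(np.pad(v, (pad,), mode="edge"), kernel, "valid")[
            : len(means)
        ],
        0,
        means,
    )
    return sm, centers, filled


def pseudotime_dependent_genes(
    nm: NormalizedMatrix,
    labels: np.ndarray,
    pt: PseudotimeVector,
    top_n: int = 100,
    bins: int = 50,
    window: int = 5,
    markers: pd.DataFrame | None = None,
) -> TemporalProfiles:
    """Dynamics of the union of per-cluster top-``top_n`` marker genes.

    The candidate set is the union of each cluster's ``top_n`` markers
    (a precomputed marker table may be passed). Each gene's profile is
    its mean expression per pseudotime bin, moving-average smoothed over
    ``window`` bins and z-scored; genes are ordered by the bin of their
    smoothed peak (the rolling-wave order).
    """
    if markers is None:
        markers = find_markers(nm, labels)
    genes: list[str] = []
    seen = set()
    for cl in pd.unique(markers["cluster"]):
        for g in top_markers(markers, cl, top_n):
            if g not in seen:
                seen.add(g)
                genes.append(g)
    if not genes:
        raise ValueError("empty candidate gene set")
    genes = sorted(genes)  # profile set is order-invariant in the input
    cols = nm.symbols.get_indexer(genes)
    ok = np.isfinite(pt.t)
    x = np.asarray(nm.values[np.ix_(np.flatnonzero(ok), cols)].todense())
    sm, centers, _ = _bin_profiles(x, pt.t[ok], bins, window)
    mu = sm.mean(axis=0)
    sd = sm.std(axis=0)
    constant = sd <= 1e-12
    z = np.zeros_like(sm)
    z[:, ~constant] = (sm[:, ~constant] - mu[~constant]) / sd[~constant]
    profiles = pd.DataFrame(z.T, index=pd.Index(genes, name="gene"))
    peak = pd.Series(np.argmax(z, axis=0), index=profiles.index, name="peak_bin")
    return TemporalProfiles(
        profiles=profiles,
        peak_bin=peak,
        bin_centers=centers,
        constant_genes=[g for g, c in zip(genes, constant) if c],
    )


def cluster_temporal_patterns(
    profiles: TemporalProfiles | pd.DataFrame,
    k: int | str = "auto",
    k_range: tuple[int, int] = (2, 10),
) -> tuple[pd.Series, pd.DataFrame]:
    """Group temporal profiles into expression patterns.

    Agglomerative clustering (Ward linkage, Euclidean distance on the
    z-scored profiles); with ``k="auto"`` the number of patterns is the
    k in ``k_range`` with the largest relative gap between consecutive
    merge heights. Returns per-gene pattern labels and the per-pattern
    average dynamic.
    """
    prof = profiles.profiles if isinstance(profiles, TemporalProfiles) else profiles
    X = prof.to_numpy()
    n = len(X)
    if n < 2:
        labels = pd.Series(np.zeros(n, dtype=int) + 1, index=prof.index)
        return labels, prof.copy()
    from scipy.cluster.hierarchy import fcluster, linkage

    Z = linkage(X, method="ward", metric="euclidean")
    heights = Z[:, 2]
    if k == "auto":
        if heights[-1] <= 1e-12:
            warnings.warn("all profiles identical; one pattern cluster")
            best_k = 1
        else:
            lo, hi = k_range
            hi = min(hi, n)
            best_k, best_gap = lo, -np.inf
            for kk in range(lo, hi + 1):
                below = heights[n - kk - 1] if n - kk - 1 >= 0 else 0.0
                above = heights[n - kk]
                gap = above / max(below, 1e-12)
                if gap > best_gap + 1e-12:
                    best_gap, best_k = gap, kk
    else:
        best_k = int(k)
    lab = fcluster(Z, t=best_k, criterion="maxclust")
    labels = pd.Series(lab, index=prof.index, name="pattern")
    means = prof.groupby(labels).mean()
    means.index.name = "pattern"
    return labels, means


def differentiation_score(
    nm: NormalizedMatrix, gene_set: list[str], labels: np.ndarray | None = None
) -> tuple[np.ndarray, pd.Series | None]:
    """Mean min-max-scaled expression of ``gene_set`` per cell.

    Each gene is scaled to [0, 1] across cells; the per-cell score is the
    mean over the set, and the per-cluster score the mean over members.
    """
    cols = nm.symbols.get_indexer(pd.unique(pd.Series(gene_set)))
    cols = cols[cols >= 0]
    if len(cols) == 0:
        raise ValueError("gene_set has no genes present in the matrix")
    x = np.asarray(nm.values[:, cols].todense())
    lo = x.min(axis=0)
    rng_ = x.max(axis=0) - lo
    rng_[rng_ == 0] = 1.0
    scaled = (x - lo) / rng_
    score = scaled.mean(axis=1)
    per_cluster = None
    if labels is not None:
        per_cluster = (
            pd.DataFrame({"cluster": np.asarray(labels), "score": score})
            .groupby("cluster")["score"]
            .mean()
        )
    return score, per_cluster
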