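"""Cell-cell similarity graph, soft clustering and marker identification.

The similarity graph is the substrate for every downstream inference:
soft cluster memberships come from a symmetric non-negative matrix
factorization S ~ H H^T of the graph, the number of communities from the
Laplacian eigengap, pseudotime from shortest paths on it, and the 2-D
layout from its geodesic distances.

Construction: the HVG submatrix is z-scored and projected onto its 20
leading principal components; the affinity between two cells is
the positive part of the Pearson correlation of their PC coordinates;
each cell keeps its k nearest neighbors (k = max(10, ceil(n/100))) and
the kept graph is symmetrized by averaging with its transpose. This is a
concrete, documented construction satisfying the "local + global
structure" contract; it sits behind this function so alternatives can be
swapped in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy import stats

from .io_qc import NormalizedMatrix, _pc_variance_gap, standardized_dense

__all__ = [
    "SimilarityMatrix",
    "SoftAssignment",
    "Embedding2D",
    "build_similarity",
    "estimate_num_clusters",
    "soft_cluster",
    "find_markers",
    "embed_2d",
    "marker_overlap",
]


@dataclass
class SimilarityMatrix:
    """Symmetric non-negative cell-cell affinity graph.

    Entries lie in [0, 1], the diagonal is zero and S equals its
    transpose exactly.
    """

    S: sp.csr_matrix
    k: int
    isolated: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.S = sp.csr_matrix(self.S)
        if (abs(self.S - self.S.T) > 1e-12).nnz:
            raise ValueError("similarity matrix is not symmetric")
        if self.S.nnz and self.S.data.min() < 0:
            raise ValueError("similarity entries must be non-negative")
        deg = np.asarray(self.S.sum(axis=1)).ravel()
        object.__setattr__(self, "isolated", np.flatnonzero(deg == 0))

    @property
    def n_cells(self) -> int:
        return self.S.shape[0]


@dataclass
class SoftAssignment:
    """Cell-to-cluster probabilities from symmetric NMF.

    ``P[i, j]`` is the probability that cell i belongs to cluster j; rows
    sum to one. ``hard_labels`` is the per-row argmax with ties broken to
    the lowest cluster index.
    """

    P: np.ndarray
    K: int
    objective: float
    n_iter: int
    objective_trace: np.ndarray
    n_degenerate_rows: int = 0

    @property
    def hard_labels(self) -> np.ndarray:
        return np.argmax(self.P, axis=1)


@dataclass
class Embedding2D:
    coords: np.ndarray  # n x 2
    method: str
    seed: int


def build_similarity(
    nm: NormalizedMatrix,
    hvgs: list[str] | None = None,
    k: int | None = None,
    n_pcs: int = 20,
) -> SimilarityMatrix:
    """Build the symmetric kNN correlation similarity graph (see module
    docstring for the construction).

    The projection depth is a fixed ``n_pcs`` leading components (capped
    by the data): a fixed depth keeps both the dominant between-community
    contrasts and the weaker gradients that order cells within a
    community, which a scree-gap truncation tends to discard.
    """
    n = nm.n_cells
    if n == 1:
        return SimilarityMatrix(sp.csr_matrix((1, 1)), k=0)
    if hvgs is None:
        hvgs = list(nm.symbols)
    idx = nm.symbols.get_indexer(pd.unique(pd.Series(hvgs)))
    idx = idx[idx >= 0]
    if len(idx) < 2:
        raise ValueError("need at least 2 HVGs present in the matrix")
    sub = NormalizedMatrix(
        nm.values[:, idx], nm.obs, nm.var.iloc[idx], nm.scale_factor
    )
    z = standardized_dense(sub)
    from sklearn.decomposition import PCA

    n_comp = int(min(n_pcs, n - 1, z.shape[1]))
    pca = PCA(n_components=n_comp, svd_solver="randomized", random_state=0)
    pcs = pca.fit_transform(z)
    # positive-part Pearson correlation between cells in PC space
    c = pcs - pcs.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(c, axis=1)
    norm[norm == 0] = 1.0
    c /= norm[:, None]
    corr = np.clip(c @ c.T, 0.0, 1.0)
    np.fill_diagonal(corr, 0.0)
    if k is None:
        k = max(10, int(np.ceil(n / 100)))
    k_eff = min(k, n - 1)
    # keep each row's k largest entries
    part = np.argpartition(-corr, kth=k_eff - 1, axis=1)[:, :k_eff]
    rows = np.repeat(np.arange(n), k_eff)
    cols = part.ravel()
    vals = corr[rows, cols]
    A = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    S = (A + A.T) * 0.5
    S.setdiag(0.0)
    S.eliminate_zeros()
    return SimilarityMatrix(sp.csr_matrix(S), k=k_eff)


def _component_eigvals(S: sp.csr_matrix, n_ev: int) -> np.ndarray:
    """Smallest ``n_ev`` eigenvalues of the symmetric normalized Laplacian
    of one connected graph (single zero eigenvalue)."""
    n = S.shape[0]
    if n == 1:
        return np.zeros(1)
    deg = np.asarray(S.sum(axis=1)).ravel()
    d = np.where(deg > 0, deg, 1.0)
    dinv = sp.diags(1.0 / np.sqrt(d))
    A = dinv @ S @ dinv
    k = min(n_ev, n)
    if k >= n - 1 or n <= 300:
        vals = np.linalg.eigvalsh(A.toarray())
        return np.sort(1.0 - vals)[:k]
    v0 = np.ones(n) / np.sqrt(n)
    vals = spla.eigsh(A, k=k, which="LA", v0=v0, return_eigenvectors=False)
    return np.sort(1.0 - vals)


def _sym_laplacian_eigvals(S: sp.csr_matrix, n_ev: int) -> np.ndarray:
    """Smallest ``n_ev`` Laplacian eigenvalues, computed exactly per
    connected component (the zero eigenvalue has one copy per component,
    which iterative solvers on the whole graph often fail to resolve)."""
    from scipy.sparse.csgraph import connected_components

    n_comp, memb = connected_components(S, directed=False)
    pieces = []
    for c in range(n_comp):
        idx = np.flatnonzero(memb == c)
        block = S[np.ix_(idx, idx)]
        pieces.append(_component_eigvals(sp.csr_matrix(block), n_ev))
    lam = np.sort(np.concatenate(pieces))
    # snap numerically-tiny values onto the exact zeros they represent
    lam[:n_comp] = 0.0
    return lam[:n_ev]


def estimate_num_clusters(
    S: SimilarityMatrix, max_k: int = 20, floor: float = 0.01
) -> int:
    """Number of communities by the Laplacian eigengap heuristic.

    Eigenvalues of the symmetric normalized Laplacian are taken in
    ascending order and K is the position of the largest *relative* gap
    (lam[i+1] - lam[i]) / max(lam[i+1], floor) among the first ``max_k``
    eigenvalues (ties toward smaller K). The relative form compensates
    for the upward drift of the spectrum, and the ``floor`` keeps the
    near-zero eigenvalues of weakly connected blocks from dominating:
    exact graph components still produce the textbook zero-multiplicity
    answer because every gap above the last zero scores higher than any
    gap between zeros.
    """
    n = S.n_cells
    if n == 0:
        raise ValueError("empty graph")
    if n == 1:
        return 1
    n_ev = min(max_k + 1, n)
    lam = _sym_laplacian_eigvals(S.S, n_ev)
    gaps = np.diff(lam)
    if len(gaps) == 0:
        return 1
    rel = gaps / np.maximum(lam[1:], floor)
    return int(np.argmax(rel)) + 1


def _symnmf_once(
    S: sp.csr_matrix, K: int, rng: np.random.Generator, max_iter: int, tol: float
) -> tuple[np.ndarray, float, int, list[float]]:
    """Multiplicative-update symmetric NMF: min ||S - H H^T||_F^2, H >= 0.

    Uses the damped update H <- H * (1/2 + (S H) / (2 H H^T H)), which is
    non-increasing in the objective.
    """
    n = S.shape[0]
    s_norm2 = float((S.multiply(S)).sum())
    scale = np.sqrt(max(S.mean(), 1e-12))
    H = rng.uniform(0.1, 1.0, size=(n, K)) * scale
    eps = 1e-12

    def objective(H: np.ndarray) -> float:
        SH = S @ H
        G = H.T @ H
        return s_norm2 - 2.0 * float(np.sum(SH * H)) + float(np.sum(G * G))

    trace = [objective(H)]
    it = 0
    for it in range(1, max_iter + 1):
        SH = S @ H
        HHtH = H @ (H.T @ H)
        H = H * (0.5 + SH / (2.0 * HHtH + eps))
        obj = objective(H)
        trace.append(obj)
        prev = trace[-2]
        if abs(prev - obj) <= tol * max(abs(prev), 1.0):
            break
    return H, trace[-1], it, trace


def soft_cluster(
    S: SimilarityMatrix,
    K: int,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> SoftAssignment:
    """Soft-cluster the similarity graph by symmetric NMF.

    Runs ``n_init`` seeded restarts (seed + restart index) and keeps the
    factorization with the lowest objective. Membership probabilities are
    the rows of H rescaled to sum one; an all-zero row is replaced by the
    uniform distribution and counted in ``n_degenerate_rows``.
    """
    n = S.n_cells
    if K < 1 or K > n:
        raise ValueError(f"K={K} out of range for n={n}")
    best = None
    for r in range(n_init):
        rng = np.random.default_rng(seed + r)
        H, obj, it, trace = _symnmf_once(S.S, K, rng, max_iter, tol)
        if best is None or obj < best[1]:
            best = (H, obj, it, trace)
    H, obj, it, trace = best
    rowsum = H.sum(axis=1)
    degenerate = rowsum <= 0
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} cells had all-zero membership")
        H = H.copy()
        H[degenerate] = 1.0
        rowsum = H.sum(axis=1)
    P = H / rowsum[:, None]
    return SoftAssignment(
        P=P,
        K=K,
        objective=obj,
        n_iter=it,
        objective_trace=np.asarray(trace),
        n_degenerate_rows=int(degenerate.sum()),
    )


def find_markers(
    nm: NormalizedMatrix,
    labels: np.ndarray,
    min_frac: float = 0.25,
    min_logfc: float = 0.25,
    min_cluster_size: int = 3,
) -> pd.DataFrame:
    """One-vs-rest marker genes per cluster.

    A gene qualifies as a marker of a cluster when it is expressed
    (count > 0) in at least ``min_frac`` of the cluster's cells and its
    mean log-normalized expression exceeds the rest by at least
    ``min_logfc`` (natural-log difference). Significance is a two-sided
    Wilcoxon rank-sum test with Benjamini-Hochberg adjustment per
    cluster; markers are ranked by adjusted p then log-fold difference.
    """
    labels = np.asarray(labels)
    clusters = pd.unique(labels)
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters")
    x = nm.dense()
    expressed = x > 0
    out = []
    for cl in clusters:
        mask = labels == cl
        n_in = int(mask.sum())
        if n_in < min_cluster_size:
            warnings.warn(f"cluster {cl!r} has {n_in} cells (<{min_cluster_size}); skipped")
            continue
        xin, xout = x[mask], x[~mask]
        frac_in = expressed[mask].mean(axis=0)
        frac_out = expressed[~mask].mean(axis=0)
        logfc = xin.mean(axis=0) - xout.mean(axis=0)
        keep = (frac_in >= min_frac) & (logfc >= min_logfc)
        if not keep.any():
            continue
        cols = np.flatnonzero(keep)
        res = stats.mannwhitneyu(
            xin[:, cols], xout[:, cols], alternative="two-sided", axis=0
        )
        from statsmodels.stats.multitest import multipletests

        padj = multipletests(res.pvalue, method="fdr_bh")[1]
        df = pd.DataFrame(
            {
                "cluster": cl,
                "gene": nm.symbols.to_numpy()[cols],
                "logfc": logfc[cols],
                "frac_in": frac_in[cols],
                "frac_out": frac_out[cols],
                "stat": res.statistic,
                "pval": res.pvalue,
                "padj": padj,
            }
        )
        df = df.sort_values(
            ["padj", "logfc"], ascending=[True, False], kind="stable"
        ).reset_index(drop=True)
        df["rank"] = np.arange(1, len(df) + 1)
        out.append(df)
    if not out:
        return pd.DataFrame(
            columns=["cluster", "gene", "logfc", "frac_in", "frac_out",
                     "stat", "pval", "padj", "rank"]
        )
    return pd.concat(out, ignore_index=True)


def top_markers(markers: pd.DataFrame, cluster, n: int) -> list[str]:
    """Top-n marker gene symbols of one cluster, by rank."""
    sub = markers[markers["cluster"] == cluster]
    return sub.nsmallest(n, "rank")["gene"].tolist()


def marker_overlap(
    markers_a: pd.DataFrame, markers_b: pd.DataFrame, top_n: int = 500
) -> pd.DataFrame:
    """Pairwise |top_n(a) intersect top_n(b)| between two marker tables."""
    ca = pd.unique(markers_a["cluster"])
    cb = pd.unique(markers_b["cluster"])
    out = pd.DataFrame(0, index=pd.Index(ca, name="cluster_a"),
                       columns=pd.Index(cb, name="cluster_b"))
    sets_a = {c: set(top_markers(markers_a, c, top_n)) for c in ca}
    sets_b = {c: set(top_markers(markers_b, c, top_n)) for c in cb}
    for a in ca:
        for b in cb:
            out.loc[a, b] = len(sets_a[a] & sets_b[b])
    return out


def _graph_distances(S: sp.csr_matrix) -> np.ndarray:
    from scipy.sparse.csgraph import shortest_path

    W = S.copy().tocsr()
    W.data = 1.0 - W.data
    W.data[W.data <= 0] = 1e-9
    D = shortest_path(W, method="D", directed=False)
    finite = np.isfinite(D)
    if not finite.all():
        dmax = D[finite].max() if finite.any() else 1.0
        D[~finite] = 1.2 * dmax
    return D


def embed_2d(S: SimilarityMatrix, seed: int = 0, max_iter: int = 120) -> Embedding2D:
    """Nonlinear 2-D layout of the similarity graph.

    Geodesic (shortest-path) distances with edge length 1 - S are
    embedded by metric stress majorization (SMACOF) from a classical-MDS
    initialization; deterministic under a fixed seed.
    """
    n = S.n_cells
    if n == 0:
        raise ValueError("empty graph")
    if n == 1:
        return Embedding2D(np.zeros((1, 2)), "geodesic-smacof", seed)
    D = _graph_distances(S.S)
    # classical MDS initialization
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    top = np.argsort(vals)[::-1][:2]
    init = vecs[:, top] * np.sqrt(np.maximum(vals[top], 1e-12))
    # deterministic sign convention
    for d in range(2):
        if init[np.argmax(np.abs(init[:, d])), d] < 0:
            init[:, d] = -init[:, d]
    from sklearn.manifold import smacof

    coords, _ = smacof(
        D,
        n_components=2,
        init=init,
        n_init=1,
        max_iter=max_iter,
        random_state=seed,
        normalized_stress=False,
    )
    return Embedding2D(coords, "geodesic-smacof", seed)
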