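"""Count-matrix IO, quality control, normalization and HVG selection.

The QC rules implemented here are the standard droplet scRNA-seq filters
used for interfollicular epidermis libraries: cells must show more than
``min_genes`` and fewer than ``max_genes`` detected genes (strict
inequalities) and a mitochondrial count fraction strictly below
``max_mito``; genes expressed in fewer than ``min_cells`` cells are
dropped; counts are depth-normalized to a fixed scale factor and
natural-log transformed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "read_count_matrix",
    "write_count_matrix",
    "filter_cells",
    "filter_genes",
    "normalize_log",
    "select_hvgs",
    "qc_report",
]

MITO_PREFIX = "MT-"


@dataclass
class CountMatrix:
    """Sparse cells x genes integer count matrix with cell/gene metadata.

    Attributes
    ----------
    counts
        CSR matrix of shape (n_cells, n_genes), non-negative integers.
    obs
        Per-cell table indexed by barcode, with at least a ``library``
        column. Barcodes are unique within a library.
    var
        Per-gene table indexed by gene id, with ``symbol`` and boolean
        ``mito`` columns.
    """

    counts: sp.csr_matrix
    obs: pd.DataFrame
    var: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape[0] != len(self.obs):
            raise ValueError(
                f"count matrix has {self.counts.shape[0]} cells but obs has "
                f"{len(self.obs)} rows"
            )
        if self.counts.shape[1] != len(self.var):
            raise ValueError(
                f"count matrix has {self.counts.shape[1]} genes but var has "
                f"{len(self.var)} rows"
            )
        if "library" not in self.obs.columns:
            raise ValueError("obs must carry a 'library' column")
        for lib, grp in self.obs.groupby("library"):
            if grp.index.duplicated().any():
                raise ValueError(f"duplicate barcodes within library {lib!r}")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def barcodes(self) -> pd.Index:
        return self.obs.index

    @property
    def symbols(self) -> pd.Index:
        return pd.Index(self.var["symbol"])

    def genes_detected(self) -> np.ndarray:
        """Number of genes with count > 0 per cell."""
        return np.asarray((self.counts > 0).sum(axis=1)).ravel()

    def total_counts(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def mito_fraction(self) -> np.ndarray:
        """Mitochondrial count fraction per cell (0 for empty cells)."""
        tot = self.total_counts().astype(float)
        mito = np.asarray(
            self.counts[:, self.var["mito"].to_numpy(bool)].sum(axis=1)
        ).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(tot > 0, mito / np.maximum(tot, 1), 0.0)
        return frac

    def subset(self, cell_mask=None, gene_mask=None) -> "CountMatrix":
        m = self.counts
        obs, var = self.obs, self.var
        if cell_mask is not None:
            m = m[cell_mask]
            obs = obs.iloc[np.flatnonzero(cell_mask)] if np.asarray(
                cell_mask
            ).dtype == bool else obs.iloc[cell_mask]
        if gene_mask is not None:
            m = m[:, gene_mask]
            var = var.iloc[np.flatnonzero(gene_mask)] if np.asarray(
                gene_mask
            ).dtype == bool else var.iloc[gene_mask]
        return CountMatrix(sp.csr_matrix(m), obs.copy(), var.copy())

    def to_anndata(self):
        """Export as an :class:`anndata.AnnData` (lazy import)."""
        import anndata

        return anndata.AnnData(
            X=self.counts.copy(), obs=self.obs.copy(), var=self.var.copy()
        )


@dataclass
class NormalizedMatrix:
    """Depth-normalized, log-transformed expression (cells x genes).

    ``values[i, g] = ln(1 + counts[i, g] / total_i * scale_factor)``; the
    sparsity pattern of the source counts is preserved exactly.
    """

    values: sp.csr_matrix
    obs: pd.DataFrame
    var: pd.DataFrame
    scale_factor: float = 10_000.0
    provenance: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def symbols(self) -> pd.Index:
        return pd.Index(self.var["symbol"])

    def dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())

    def gene_vector(self, symbol: str) -> np.ndarray:
        idx = self.symbols.get_indexer([symbol])
        if idx[0] < 0:
            raise KeyError(f"gene symbol {symbol!r} not present")
        return np.asarray(self.values[:, idx[0]].todense()).ravel()


def _read_one_library(directory: Path, library: str) -> CountMatrix:
    mtx_path = directory / "matrix.mtx"
    bc_path = directory / "barcodes.tsv"
    ft_path = directory / "features.tsv"
    for p in (mtx_path, bc_path, ft_path):
        if not p.exists():
            raise FileNotFoundError(f"missing {p}")
        if p.stat().st_size == 0:
            raise ValueError(f"empty file {p}")
    try:
        mat = scipy.io.mmread(str(mtx_path))
    except Exception as exc:  # malformed header / body
        raise ValueError(f"malformed Matrix Market file {mtx_path}: {exc}") from exc
    mat = sp.csr_matrix(mat)
    barcodes = pd.read_csv(bc_path, sep="\t", header=None)[0].astype(str)
    feats = pd.read_csv(ft_path, sep="\t", header=None)
    if feats.shape[1] < 2:
        feats[1] = feats[0]
    n_bc, n_ft = len(barcodes), len(feats)
    # On-disk convention is genes x cells; accept the transpose as well.
    if mat.shape == (n_ft, n_bc):
        mat = sp.csr_matrix(mat.T)
    elif mat.shape == (n_bc, n_ft):
        pass
    else:
        raise ValueError(
            f"{mtx_path}: matrix shape {mat.shape} matches neither "
            f"(features={n_ft}, barcodes={n_bc}) orientation"
        )
    obs = pd.DataFrame({"library": library}, index=pd.Index(barcodes, name="barcode"))
    symbols = feats[1].astype(str)
    var = pd.DataFrame(
        {
            "symbol": symbols.to_numpy(),
            "mito": symbols.str.upper().str.startswith(MITO_PREFIX).to_numpy(),
        },
        index=pd.Index(feats[0].astype(str), name="gene_id"),
    )
    return CountMatrix(mat, obs, var)


def read_count_matrix(directory) -> CountMatrix:
    """Read a 10x-style directory (or a directory of per-library subdirs).

    Orientation on disk may be genes x cells or cells x genes; the result
    is always cells x genes. Gene symbols starting with ``MT-`` (case
    insensitive) are flagged mitochondrial.
    """
    directory = Path(directory)
    if not directory.exists():
        raise FileNotFoundError(f"no such directory: {directory}")
    if (directory / "matrix.mtx").exists():
        return _read_one_library(directory, directory.name)
    subdirs = sorted(
        d for d in directory.iterdir() if d.is_dir() and (d / "matrix.mtx").exists()
    )
    if not subdirs:
        raise FileNotFoundError(
            f"{directory} contains neither matrix.mtx nor library subdirectories"
        )
    parts = [_read_one_library(d, d.name) for d in subdirs]
    var = parts[0].var
    for p in parts[1:]:
        if not p.var.index.equals(var.index):
            raise ValueError("libraries disagree on the feature list")
    counts = sp.vstack([p.counts for p in parts], format="csr")
    obs = pd.concat([p.obs for p in parts])
    return CountMatrix(counts, obs, var.copy())


def write_count_matrix(m: CountMatrix, directory) -> None:
    """Write per-library 10x-style subdirectories (genes x cells on disk)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for lib in pd.unique(m.obs["library"]):
        sub = directory / str(lib)
        sub.mkdir(exist_ok=True)
        mask = (m.obs["library"] == lib).to_numpy()
        block = m.counts[mask].T.tocoo()
        scipy.io.mmwrite(str(sub / "matrix.mtx"), block, field="integer")
        m.obs.index[mask].to_series().to_csv(
            sub / "barcodes.tsv", sep="\t", header=False, index=False
        )
        pd.DataFrame(
            {"id": m.var.index, "symbol": m.var["symbol"].to_numpy()}
        ).to_csv(sub / "features.tsv", sep="\t", header=False, index=False)


def filter_cells(
    m: CountMatrix,
    min_genes: int = 200,
    max_genes: int = 5000,
    max_mito: float = 0.10,
) -> CountMatrix:
    """Keep cells with min_genes < detected genes < max_genes and
    mitochondrial fraction < max_mito (all strict).

    Thresholds are the same for every library, and each cell is judged on
    its own raw counts, so the filter is per-library by construction.
    """
    if m.n_cells == 0:
        return m
    detected = m.genes_detected()
    mito = m.mito_fraction()
    keep = (detected > min_genes) & (detected < max_genes) & (mito < max_mito)
    return m.subset(cell_mask=keep)


def filter_genes(m: CountMatrix, min_cells: int = 3) -> CountMatrix:
    """Drop genes expressed (count > 0) in fewer than ``min_cells`` cells."""
    support = np.asarray((m.counts > 0).sum(axis=0)).ravel()
    return m.subset(gene_mask=support >= min_cells)


def qc_report(m: CountMatrix, min_genes=200, max_genes=5000, max_mito=0.10) -> pd.DataFrame:
    """Per-cell QC table with pass/fail flags for each filter."""
    detected = m.genes_detected()
    mito = m.mito_fraction()
    return pd.DataFrame(
        {
            "library": m.obs["library"].to_numpy(),
            "genes_detected": detected,
            "total_counts": m.total_counts(),
            "mito_fraction": mito,
            "pass_min_genes": detected > min_genes,
            "pass_max_genes": detected < max_genes,
            "pass_mito": mito < max_mito,
        },
        index=m.obs.index,
    )


def normalize_log(m: CountMatrix, scale: float = 10_000.0) -> NormalizedMatrix:
    """Depth-normalize to ``scale`` counts per cell and ln(1 + x) transform."""
    totals = m.total_counts().astype(float)
    if np.any(totals == 0):
        bad = m.obs.index[totals == 0].tolist()
        raise ValueError(f"cells with zero total counts: {bad[:5]}")
    x = m.counts.tocsr().astype(float)
    row_scale = scale / totals
    x = sp.diags(row_scale) @ x
    x.data = np.log1p(x.data)
    return NormalizedMatrix(
        sp.csr_matrix(x),
        m.obs.copy(),
        m.var.copy(),
        scale_factor=float(scale),
        provenance={"order": "filter_cells,filter_genes,normalize_log"},
    )


def _pc_variance_gap(explained: np.ndarray, max_k: int = 20) -> int:
    """Index k of the largest drop between consecutive PC variances.

    Searches the first ``max_k`` gaps; ties break toward the smaller k.
    """
    n = min(max_k, len(explained) - 1)
    if n < 1:
        return 1
    gaps = explained[:n] - explained[1 : n + 1]
    return int(np.argmax(gaps)) + 1


def standardized_dense(nm: NormalizedMatrix, clip: float = 10.0) -> np.ndarray:
    """Per-gene z-scored dense matrix, clipped at +/- ``clip``."""
    x = nm.dense()
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    np.clip(z, -clip, clip, out=z)
    return z


def select_hvgs(nm: NormalizedMatrix, n: int = 3000, max_k: int = 20) -> list[str]:
    """Select highly variable genes by principal-component loading.

    Genes are z-scored (clipped at +/-10), a PCA is computed, the number
    of informative components k is the position of the largest gap in the
    PC variance spectrum (first ``max_k`` gaps), and each gene is scored
    by its maximum absolute loading over those k components. Returns the
    top ``n`` gene symbols by score. Constant genes have zero loading and
    are never selected ahead of varying ones.
    """
    if nm.n_cells < 2 or nm.n_genes < 2:
        raise ValueError("need at least 2 cells and 2 genes")
    if n >= nm.n_genes:
        warnings.warn(
            f"requested {n} HVGs but only {nm.n_genes} genes present; "
            "returning all genes"
        )
    z = standardized_dense(nm)
    varying = z.std(axis=0) > 0
    n_comp = int(min(max_k + 1, nm.n_cells - 1, varying.sum()))
    from sklearn.decomposition import PCA

    pca = PCA(n_components=n_comp, svd_solver="randomized", random_state=0)
    pca.fit(z)
    k = _pc_variance_gap(pca.explained_variance_, max_k=max_k)
    score = np.abs(pca.components_[:k]).max(axis=0)
    score[~varying] = -1.0  # constant genes never selected
    order = np.argsort(-score, kind="stable")
    top = order[: min(n, nm.n_genes)]
    top = top[score[top] >= 0]
    return [nm.var["symbol"].iloc[i] for i in top]
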