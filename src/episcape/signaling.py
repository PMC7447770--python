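"""Probabilistic ligand-receptor cell-cell communication networks.

For each ligand-receptor pair with its downstream target genes, a
sender -> receiver probability matrix is computed from log-normalized
expression: the sender weight is the cell's ligand expression scaled by
the cohort maximum, the receiver weight combines receptor expression
with target-gene activity (up-targets count positively, down-targets
through 1 - scaled expression), the raw score is their product, and each
sender's row is normalized into a probability distribution over
receivers. Probabilities below a threshold phi (default 0.1) are set to
zero. Cluster-level networks average the cell-level probabilities over
all cell pairs of two clusters, and a consistency score compares
cluster-level networks between sequencing libraries.

The cell-level scoring kernel is a documented package choice (the
multiplicative max-normalized form below); it is confined to
:func:`signaling_probability` so alternatives can be swapped in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_qc import NormalizedMatrix

__all__ = [
    "PathwaySpec",
    "CellSignaling",
    "load_pathways",
    "write_pathways",
    "signaling_probability",
    "aggregate_cluster_signaling",
    "group_lr_pairs",
    "consistency_score",
]


@dataclass(frozen=True)
class PathwayRecord:
    pathway: str
    ligand: str
    receptor: str
    targets_up: tuple[str, ...]
    targets_down: tuple[str, ...]

    @property
    def pair_id(self) -> str:
        return f"{self.pathway}:{self.ligand}-{self.receptor}"


@dataclass
class PathwaySpec:
    """Ligand-receptor-target definitions for a set of pathways."""

    records: list[PathwayRecord]

    def __post_init__(self) -> None:
        seen = set()
        for r in self.records:
            if r.ligand == r.receptor:
                raise ValueError(
                    f"record {r.pathway}: ligand equals receptor ({r.ligand})"
                )
            key = (r.pathway, r.ligand, r.receptor)
            if key in seen:
                raise ValueError(f"duplicate record {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def missing_genes(self, nm: NormalizedMatrix) -> dict[str, list[str]]:
        """Genes of each record absent from the expression matrix."""
        have = set(nm.symbols)
        out = {}
        for r in self.records:
            miss = [
                g
                for g in (r.ligand, r.receptor, *r.targets_up, *r.targets_down)
                if g not in have
            ]
            if miss:
                out[r.pair_id] = miss
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pathway": [r.pathway for r in self.records],
                "ligand": [r.ligand for r in self.records],
                "receptor": [r.receptor for r in self.records],
                "targets_up": [";".join(r.targets_up) for r in self.records],
                "targets_down": [";".join(r.targets_down) for r in self.records],
            }
        )


@dataclass
class CellSignaling:
    """Cell-level signaling probabilities for one ligand-receptor pair.

    ``p`` holds the post-threshold probabilities (sparse, senders x
    receivers). The pre-threshold distribution of any sender with a
    nonzero ligand is ``receiver_probability`` (identical across such
    senders, a consequence of per-sender normalization of the rank-one
    score); ``sender_active`` marks senders with nonzero ligand.
    """

    record: PathwayRecord
    p: sp.csr_matrix
    phi: float
    sender_weight: np.ndarray
    receiver_score: np.ndarray
    receiver_probability: np.ndarray
    thresholded: bool = True

    @property
    def sender_active(self) -> np.ndarray:
        return self.sender_weight > 0


def _parse_targets(cell: object) -> tuple[str, ...]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return ()
    s = str(cell).strip()
    if not s:
        return ()
    return tuple(x.strip() for x in s.split(";") if x.strip())


def load_pathways(path) -> PathwaySpec:
    """Read a pathway TSV with columns pathway, ligand, receptor,
    targets_up, targets_down (semicolon-separated gene sets)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"pathway", "ligand", "receptor", "targets_up", "targets_down"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        if not isinstance(row["ligand"], str) or not isinstance(row["receptor"], str):
            raise ValueError(f"{path}: malformed row {i}")
        records.append(
            PathwayRecord(
                pathway=str(row["pathway"]),
                ligand=row["ligand"].strip(),
                receptor=row["receptor"].strip(),
                targets_up=_parse_targets(row["targets_up"]),
                targets_down=_parse_targets(row["targets_down"]),
            )
        )
    return PathwaySpec(records)


def write_pathways(spec: PathwaySpec, path) -> None:
    spec.to_frame().to_csv(path, sep="\t", index=False)


def _scaled(nm: NormalizedMatrix, gene: str) -> np.ndarray:
    """Expression scaled by its maximum over cells (zeros if silent)."""
    v = nm.gene_vector(gene)
    m = v.max()
    return v / m if m > 0 else np.zeros_like(v)


def signaling_probability(
    nm: NormalizedMatrix,
    rec: PathwayRecord,
    phi: float = 0.1,
    apply_threshold: bool = True,
) -> CellSignaling | None:
    """Sender -> receiver probability matrix for one ligand-receptor pair.

    Sender weight ``a_i`` = ligand expression / max; receiver weight
    ``b_j`` = receptor expression / max; target activity ``t_j`` is the
    mean of up-target scaled expression and of (1 - scaled expression)
    over down-targets (each term dropped if its set is missing; both
    missing gives t_j = 1). Raw score s_ij = a_i b_j t_j is normalized
    per sender into p_ij, then entries below ``phi`` are zeroed when
    ``apply_threshold`` is set. Returns None (with a warning) if ligand
    or receptor is absent from the matrix.
    """
    have = set(nm.symbols)
    if rec.ligand not in have or rec.receptor not in have:
        warnings.warn(
            f"pair {rec.pair_id}: ligand or receptor absent; record skipped"
        )
        return None
    a = _scaled(nm, rec.ligand)
    b = _scaled(nm, rec.receptor)
    up = [g for g in rec.targets_up if g in have]
    dn = [g for g in rec.targets_down if g in have]
    terms = []
    if up:
        terms.append(np.mean([_scaled(nm, g) for g in up], axis=0))
    if dn:
        terms.append(1.0 - np.mean([_scaled(nm, g) for g in dn], axis=0))
    t = np.mean(terms, axis=0) if terms else np.ones(nm.n_cells)
    bt = b * t
    total = bt.sum()
    q = bt / total if total > 0 else np.zeros_like(bt)
    if apply_threshold:
        q_thr = np.where(q >= phi, q, 0.0)
    else:
        q_thr = q
    # p is rank-one: row i equals q_thr when a_i > 0, else zero
    active = np.flatnonzero(a > 0)
    nz = np.flatnonzero(q_thr)
    if len(active) and len(nz):
        rows = np.repeat(active, len(nz))
        cols = np.tile(nz, len(active))
        vals = np.tile(q_thr[nz], len(active))
        p = sp.csr_matrix((vals, (rows, cols)), shape=(nm.n_cells, nm.n_cells))
    else:
        p = sp.csr_matrix((nm.n_cells, nm.n_cells))
    return CellSignaling(
        record=rec,
        p=p,
        phi=phi,
        sender_weight=a,
        receiver_score=bt,
        receiver_probability=q,
        thresholded=apply_threshold,
    )


def aggregate_cluster_signaling(
    cs: CellSignaling, labels: np.ndarray
) -> pd.DataFrame:
    """Cluster-level network: entry (a, b) is the mean cell-level
    probability over sender cells of cluster a and receiver cells of b."""
    labels = np.asarray(labels)
    n = cs.p.shape[0]
    if len(labels) != n:
        raise ValueError("labels must cover all cells")
    clusters = list(pd.unique(labels))
    masks = {cl: labels == cl for cl in clusters}
    out = pd.DataFrame(0.0, index=pd.Index(clusters, name="sender"),
                       columns=pd.Index(clusters, name="receiver"))
    # mean over the block = (row-sum over receivers in b, averaged over senders in a)
    csr = cs.p.tocsr()
    for a_cl in clusters:
        rows = csr[masks[a_cl]]
        for b_cl in clusters:
            block = rows[:, masks[b_cl]]
            out.loc[a_cl, b_cl] = block.sum() / (rows.shape[0] * int(masks[b_cl].sum()))
    return out


def group_lr_pairs(
    matrices: dict[str, pd.DataFrame] | list[pd.DataFrame],
    seed: int = 0,
    k_range: tuple[int, int] = (1, 10),
) -> tuple[pd.Series, dict[int, pd.DataFrame]]:
    """Group ligand-receptor pairs by their cluster-interaction pattern.

    Flattened cluster-level matrices are projected to 2-D with a seeded
    t-SNE (plain PCA for fewer than 5 pairs, where a perplexity cannot
    be chosen) and grouped by average-linkage agglomerative clustering;
    the group count is set at the largest merge-height gap. Returns the
    group label per pair and the element-wise mean matrix per group.
    """
    if isinstance(matrices, list):
        matrices = {str(i): m for i, m in enumerate(matrices)}
    names = list(matrices)
    if not names:
        raise ValueError("no matrices given")
    shapes = {matrices[n].shape for n in names}
    if len(shapes) != 1:
        raise ValueError("cluster matrices have differing shapes")
    X = np.vstack([matrices[n].to_numpy().ravel() for n in names])
    n = len(names)
    if n == 1:
        return (
            pd.Series([1], index=names, name="group"),
            {1: matrices[names[0]].copy()},
        )
    if np.allclose(X, X[0], atol=1e-12):
        labels = pd.Series(np.ones(n, dtype=int), index=names, name="group")
        return labels, {1: matrices[names[0]].copy()}
    if n >= 5:
        from sklearn.manifold import TSNE

        perplexity = min(30.0, max(2.0, (n - 1) / 3))
        emb = TSNE(
            n_components=2,
            perplexity=perplexity,
            init="pca",
            random_state=seed,
        ).fit_transform(X)
    else:
        from sklearn.decomposition import PCA

        emb = PCA(n_components=2, random_state=seed).fit_transform(X)
    from scipy.cluster.hierarchy import fcluster, linkage

    Z = linkage(emb, method="average", metric="euclidean")
    heights = Z[:, 2]
    lo, hi = k_range
    hi = min(hi, n)
    best_k, best_gap = 1, 0.0
    for kk in range(max(lo, 2), hi + 1):
        # cutting into kk clusters crosses the gap below merge n-kk
        below = heights[n - kk - 1] if n - kk - 1 >= 0 else 0.0
        gap = heights[n - kk] - below
        if gap > best_gap + 1e-12:
            best_gap, best_k = gap, kk
    lab = fcluster(Z, t=best_k, criterion="maxclust")
    labels = pd.Series(lab, index=names, name="group")
    groups = {}
    for gid in sorted(set(lab)):
        members = [names[i] for i in np.flatnonzero(lab == gid)]
        groups[gid] = sum(matrices[m] for m in members) / len(members)
    return labels, groups


def consistency_score(
    ref: pd.DataFrame | np.ndarray, target: pd.DataFrame | np.ndarray
) -> float:
    """Consistency of a target library's cluster network with a reference.

    Over entries nonzero in the reference, one minus the mean absolute
    difference: 1 - sum(|ref - target|) / #nonzero-ref-entries. NaN when
    the reference has no nonzero entries.
    """
    R = np.asarray(ref, dtype=float)
    T = np.asarray(target, dtype=float)
    if R.shape != T.shape:
        raise ValueError("reference and target shapes differ")
    mask = R != 0
    if not mask.any():
        return float("nan")
    return float(1.0 - np.abs(R[mask] - T[mask]).sum() / mask.sum())


def consistency_report(
    per_library: dict[str, dict[str, pd.DataFrame]], reference: str
) -> pd.DataFrame:
    """Consistency of every library against ``reference``, per L-R pair.

    ``per_library`` maps library -> {pair_id -> cluster matrix}.
    """
    if reference not in per_library:
        raise ValueError(f"reference library {reference!r} not present")
    ref = per_library[reference]
    rows = []
    for lib, mats in per_library.items():
        if lib == reference:
            continue
        for pair, R in ref.items():
            if pair not in mats:
                continue
            rows.append(
                {
                    "library": lib,
                    "pair": pair,
                    "consistency": consistency_score(R, mats[pair]),
                }
            )
    df = pd.DataFrame(rows, columns=["library", "pair", "consistency"])
    return df
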