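"""Shared fixtures: one preset dataset analyzed once per session."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from episcape import clustering, io_qc, simulate, trajectory

CANONICAL_SEED = 1


@dataclass
class PresetRun:
    """Seed-1 epidermis preset taken through QC, similarity and clustering."""

    counts: io_qc.CountMatrix
    truth: simulate.GroundTruth
    filtered: io_qc.CountMatrix
    nm: io_qc.NormalizedMatrix
    true_labels: np.ndarray  # aligned to filtered cells
    true_latent: np.ndarray
    hvgs: list
    S: clustering.SimilarityMatrix
    assignment: clustering.SoftAssignment


@dataclass
class EpithelialRun:
    """Melanocyte-excluded re-analysis used by the trajectory stages."""

    nm: io_qc.NormalizedMatrix
    true_labels: np.ndarray
    true_latent: np.ndarray
    S: clustering.SimilarityMatrix
    pt: trajectory.PseudotimeVector
    assignment: clustering.SoftAssignment
    markers: pd.DataFrame


def analyze_preset(seed: int) -> PresetRun:
    cfg = simulate.epidermis_preset()
    counts, truth = simulate.generate(cfg, seed=seed)
    filtered = io_qc.filter_genes(io_qc.filter_cells(counts))
    keep = counts.obs.index.get_indexer(filtered.obs.index)
    nm = io_qc.normalize_log(filtered)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        hvgs = io_qc.select_hvgs(nm, 3000)
    S = clustering.build_similarity(nm, hvgs)
    assignment = clustering.soft_cluster(S, 7, seed=seed)
    return PresetRun(
        counts=counts,
        truth=truth,
        filtered=filtered,
        nm=nm,
        true_labels=truth.labels[keep],
        true_latent=truth.latent_time[keep],
        hvgs=hvgs,
        S=S,
        assignment=assignment,
    )


def analyze_epithelial(run: PresetRun, seed: int) -> EpithelialRun:
    epi = run.true_labels != "MEL"
    fe = io_qc.filter_genes(run.filtered.subset(cell_mask=epi))
    nme = io_qc.normalize_log(fe)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        hvgs = io_qc.select_hvgs(nme, 10000)
    Se = clustering.build_similarity(nme, hvgs)
    lat = run.true_latent[epi]
    root = int(np.nanargmin(lat))
    pt = trajectory.compute_pseudotime(Se, root)
    sa = clustering.soft_cluster(Se, 6, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        markers = clustering.find_markers(nme, run.true_labels[epi])
    return EpithelialRun(
        nm=nme,
        true_labels=run.true_labels[epi],
        true_latent=lat,
        S=Se,
        pt=pt,
        assignment=sa,
        markers=markers,
    )


@pytest.fixture(scope="session")
def preset_run() -> PresetRun:
    return analyze_preset(CANONICAL_SEED)


@pytest.fixture(scope="session")
def epi_run(preset_run) -> EpithelialRun:
    return analyze_epithelial(preset_run, CANONICAL_SEED)


def block_similarity(sizes, within=0.9, between=0.0) -> clustering.SimilarityMatrix:
    """Exact block-structured similarity with zero diagonal."""
    n = sum(sizes)
    S = np.full((n, n), between)
    start = 0
    for m in sizes:
        S[start : start + m, start : start + m] = within
        start += m
    np.fill_diagonal(S, 0.0)
    return clustering.SimilarityMatrix(sp.csr_matrix(S), k=n - 1)


def toy_normalized(values: np.ndarray, symbols=None) -> io_qc.NormalizedMatrix:
    """Wrap a dense cells x genes array as a NormalizedMatrix."""
    n, g = values.shape
    symbols = list(symbols) if symbols is not None else [f"G{j}" for j in range(g)]
    obs = pd.DataFrame(
        {"library": "library_1"},
        index=pd.Index([f"C{i}" for i in range(n)], name="barcode"),
    )
    var = pd.DataFrame(
        {"symbol": symbols, "mito": [s.upper().startswith("MT-") for s in symbols]},
        index=pd.Index([f"ID{j}" for j in range(g)], name="gene_id"),
    )
    return io_qc.NormalizedMatrix(sp.csr_matrix(values), obs, var)


def toy_counts(counts: np.ndarray, symbols=None, library=None) -> io_qc.CountMatrix:
    n, g = counts.shape
    symbols = list(symbols) if symbols is not None else [f"G{j}" for j in range(g)]
    obs = pd.DataFrame(
        {"library": library if library is not None else "library_1"},
        index=pd.Index([f"C{i}" for i in range(n)], name="barcode"),
    )
    var = pd.DataFrame(
        {"symbol": symbols, "mito": [s.upper().startswith("MT-") for s in symbols]},
        index=pd.Index([f"ID{j}" for j in range(g)], name="gene_id"),
    )
    return io_qc.CountMatrix(sp.csr_matrix(counts), obs, var)
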