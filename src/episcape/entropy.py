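"""Cellular entropy (differentiation potency) and the Waddington landscape.

A cell's entropy is the Shannon entropy of its soft cluster-assignment
distribution,

    xi_i = - sum_j P[i, j] * ln(P[i, j]),

with 0 * ln 0 = 0. A one-hot assignment gives xi = 0 (a stable state); a
uniform assignment over K clusters gives the maximum ln K (a cell poised
between many states). The Waddington landscape renders entropy as a
height field over the 2-D embedding: valleys are stable attractor
states, mountains are transition-prone regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import Embedding2D, SoftAssignment

__all__ = ["EntropyVector", "Landscape", "cellular_entropy", "aggregate_entropy", "build_landscape"]


@dataclass
class EntropyVector:
    """Per-cell entropy, raw (xi) and normalized by ln K."""

    xi: np.ndarray
    normalized: np.ndarray
    K: int


@dataclass
class Landscape:
    """Height field over the embedding bounding box (+5% margin)."""

    grid_x: np.ndarray  # G
    grid_y: np.ndarray  # G
    heights: np.ndarray  # G x G, indexed [iy, ix]
    cell_heights: np.ndarray  # surface height at each cell position
    bandwidth: float
    background: float


def cellular_entropy(P: SoftAssignment | np.ndarray, tol: float = 1e-6) -> EntropyVector:
    """Shannon entropy of each cell's cluster-membership distribution.

    Natural logarithm; rows must sum to 1 within ``tol``. Returns both
    the raw value in [0, ln K] and the ln(K)-normalized value in [0, 1].
    """
    M = P.P if isinstance(P, SoftAssignment) else np.asarray(P, dtype=float)
    if M.ndim != 2:
        raise ValueError("P must be 2-D (cells x clusters)")
    rowsum = M.sum(axis=1)
    if np.any(np.abs(rowsum - 1.0) > tol):
        bad = int(np.argmax(np.abs(rowsum - 1.0)))
        raise ValueError(
            f"membership row {bad} sums to {rowsum[bad]:.6f}, not 1"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(M > 0, np.log(np.where(M > 0, M, 1.0)), 0.0)
    xi = -(M * logs).sum(axis=1)
    xi = np.maximum(xi, 0.0)
    K = M.shape[1]
    norm = xi / np.log(K) if K > 1 else np.zeros_like(xi)
    return EntropyVector(xi=xi, normalized=norm, K=K)


def aggregate_entropy(xi: EntropyVector | np.ndarray, labels) -> pd.DataFrame:
    """Mean (and median) entropy per cluster, ranked by mean descending."""
    values = xi.xi if isinstance(xi, EntropyVector) else np.asarray(xi, float)
    labels = np.asarray(labels)
    if len(labels) != len(values):
        raise ValueError("labels must cover all cells")
    df = (
        pd.DataFrame({"cluster": labels, "xi": values})
        .groupby("cluster")["xi"]
        .agg(mean_xi="mean", median_xi="median", n="size")
        .sort_values("mean_xi", ascending=False)
    )
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index()


def build_landscape(
    emb: Embedding2D,
    xi: EntropyVector | np.ndarray,
    grid_size: int = 100,
    bandwidth: float = 0.05,
    min_weight: float = 1e-6,
    background_factor: float = 1.1,
) -> Landscape:
    """Gaussian-kernel entropy surface over the 2-D embedding.

    The height at a grid point is the kernel-weighted average of cell
    entropies (bandwidth expressed as a fraction of the bounding-box
    diagonal, +5% margin on each side). Grid points with total kernel
    weight below ``min_weight`` are set to a background of
    ``background_factor * max(xi)``: unpopulated regions are mountains.
    """
    values = xi.xi if isinstance(xi, EntropyVector) else np.asarray(xi, float)
    pts = np.asarray(emb.coords if isinstance(emb, Embedding2D) else emb, float)
    if len(pts) == 0:
        raise ValueError("cannot build a landscape from zero cells")
    if len(pts) != len(values):
        raise ValueError("embedding and entropy cover different cells")
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    lo = lo - 0.05 * span
    hi = hi + 0.05 * span
    gx = np.linspace(lo[0], hi[0], grid_size)
    gy = np.linspace(lo[1], hi[1], grid_size)
    diag = float(np.hypot(hi[0] - lo[0], hi[1] - lo[1]))
    h = bandwidth * diag
    background = background_factor * float(values.max())

    def surface_at(qx: np.ndarray, qy: np.ndarray, chunk: int = 2048) -> np.ndarray:
        out = np.empty(len(qx))
        for s in range(0, len(qx), chunk):
            e = s + chunk
            d2 = (qx[s:e, None] - pts[None, :, 0]) ** 2 + (
                qy[s:e, None] - pts[None, :, 1]
            ) ** 2
            w = np.exp(-d2 / (2.0 * h * h))
            tot = w.sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                avg = (w @ values) / np.where(tot > 0, tot, 1.0)
            out[s:e] = np.where(tot < min_weight, background, avg)
        return out

    xx, yy = np.meshgrid(gx, gy)
    heights = surface_at(xx.ravel(), yy.ravel()).reshape(grid_size, grid_size)
    cell_h = surface_at(pts[:, 0], pts[:, 1])
    return Landscape(
        grid_x=gx,
        grid_y=gy,
        heights=heights,
        cell_heights=cell_h,
        bandwidth=bandwidth,
        background=background,
    )
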