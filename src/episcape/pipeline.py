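"""End-to-end pipeline: simulate/read -> QC -> cluster -> entropy ->
trajectory -> signaling, with a reproducible run manifest.

Every stage's parameters and the per-stage cell/gene counts are recorded
in ``manifest.json``; re-running with the same configuration and seed
reproduces every output byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import yaml

from . import clustering, entropy, io_qc, signaling, simulate, trajectory

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    With ``simulate_preset`` set, input data are generated from the
    epidermis preset and ground truth drives root-cell selection and
    off-trajectory exclusion; otherwise ``input_dir`` must point to a
    10x-style directory and ``root_cell``/``off_trajectory_clusters``
    must be given explicitly.
    """

    out_dir: str = "episcape_run"
    seed: int = 0
    simulate_preset: bool = True
    n_cells: int | None = None  # preset override
    input_dir: str | None = None
    pathway_file: str | None = None
    min_genes: int = 200
    max_genes: int = 5000
    max_mito: float = 0.10
    min_cells_per_gene: int = 3
    n_hvgs: int = 3000
    n_hvgs_trajectory: int = 10000
    n_clusters: int | str = "auto"
    root_cell: str = "auto"
    off_trajectory_clusters: list = field(default_factory=list)
    phi: float = 0.1
    # where to apply the phi threshold: "cell", "cluster" or "none".
    # At cohort sizes in the thousands, per-sender normalization spreads
    # probability so thin that phi=0.1 zeroes every cell-level entry, so
    # the pipeline default reports raw cluster averages.
    threshold_level: str = "none"
    deg_top_n: int = 100
    wave_bins: int = 50
    wave_window: int = 5
    pattern_bins: int = 80
    pattern_window: int = 3
    landscape_grid: int = 100
    landscape_bandwidth: float = 0.05
    reference_library: str | None = None

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _fmt(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage and write outputs + manifest to ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}}
    rng_seed = int(config.seed)

    # --- input ----------------------------------------------------------
    truth = None
    if config.simulate_preset:
        cfg = simulate.epidermis_preset()
        if config.n_cells:
            cfg.n_cells = int(config.n_cells)
        cm, truth = simulate.generate(cfg, seed=rng_seed)
        simulate.write_fixture(cm, truth, out / "input")
    else:
        if not config.input_dir or not Path(config.input_dir).exists():
            raise FileNotFoundError(
                f"input directory not found: {config.input_dir!r}"
            )
        cm = io_qc.read_count_matrix(config.input_dir)
    manifest["stages"]["input"] = {"cells": cm.n_cells, "genes": cm.n_genes}

    # --- QC -------------------------------------------------------------
    report = io_qc.qc_report(cm, config.min_genes, config.max_genes, config.max_mito)
    _fmt(report, out / "qc_report.tsv")
    filtered = io_qc.filter_cells(
        cm, config.min_genes, config.max_genes, config.max_mito
    )
    filtered = io_qc.filter_genes(filtered, config.min_cells_per_gene)
    nm = io_qc.normalize_log(filtered)
    manifest["stages"]["qc"] = {
        "cells": filtered.n_cells,
        "genes": filtered.n_genes,
    }
    if truth is not None:
        keep = cm.obs.index.get_indexer(filtered.obs.index)
        truth_labels = truth.labels[keep]
        truth_latent = truth.latent_time[keep]

    # --- similarity + clustering ---------------------------------------
    hvgs = io_qc.select_hvgs(nm, config.n_hvgs)
    pd.Series(hvgs, name="gene").to_csv(out / "hvgs.tsv", sep="\t", index=False)
    S = clustering.build_similarity(nm, hvgs)
    scipy.io.mmwrite(str(out / "similarity.mtx"), S.S)
    if config.n_clusters == "auto":
        K = clustering.estimate_num_clusters(S)
    else:
        K = int(config.n_clusters)
    sa = clustering.soft_cluster(S, K, seed=rng_seed)
    labels = sa.hard_labels
    P_df = pd.DataFrame(
        sa.P, index=nm.obs.index, columns=[f"cluster_{j}" for j in range(K)]
    )
    P_df.insert(0, "hard_label", labels)
    _fmt(P_df, out / "soft_assignment.tsv")
    markers = clustering.find_markers(nm, labels)
    _fmt(markers, out / "markers.tsv", index=False)
    emb = clustering.embed_2d(S, seed=rng_seed)
    _fmt(
        pd.DataFrame(emb.coords, index=nm.obs.index, columns=["x", "y"]),
        out / "embedding.tsv",
    )
    manifest["stages"]["clustering"] = {
        "K": int(K),
        "nmf_objective": float(sa.objective),
        "cluster_sizes": np.bincount(labels, minlength=K).tolist(),
    }

    # --- entropy + landscape -------------------------------------------
    xi = entropy.cellular_entropy(sa)
    ent_df = pd.DataFrame(
        {"xi": xi.xi, "xi_normalized": xi.normalized, "cluster": labels},
        index=nm.obs.index,
    )
    _fmt(ent_df, out / "entropy.tsv")
    _fmt(entropy.aggregate_entropy(xi, labels), out / "entropy_clusters.tsv", index=False)
    land = entropy.build_landscape(
        emb, xi, grid_size=config.landscape_grid, bandwidth=config.landscape_bandwidth
    )
    _fmt(
        pd.DataFrame(land.heights, index=land.grid_y, columns=land.grid_x),
        out / "landscape.tsv",
    )
    manifest["stages"]["entropy"] = {
        "mean_xi": float(xi.xi.mean()),
        "max_xi": float(xi.xi.max()),
    }

    # --- trajectory (off-trajectory clusters excluded) ------------------
    excluded = set(config.off_trajectory_clusters)
    if truth is not None and not excluded:
        # synthetic driver: clusters dominated by off-trajectory truth labels
        for j in range(K):
            members = truth_labels[labels == j]
            if len(members) and np.mean(np.isnan(truth_latent[labels == j])) > 0.5:
                excluded.add(j)
    epi_mask = ~np.isin(labels, list(excluded))
    fe = io_qc.filter_genes(
        filtered.subset(cell_mask=epi_mask), config.min_cells_per_gene
    )
    nme = io_qc.normalize_log(fe)
    hvgs_t = io_qc.select_hvgs(nme, config.n_hvgs_trajectory)
    Se = clustering.build_similarity(nme, hvgs_t)
    if config.root_cell == "auto":
        if truth is None:
            raise ValueError("root_cell='auto' requires simulated input")
        lat = truth_latent[epi_mask]
        root = int(np.nanargmin(lat))
    else:
        pos = nme.obs.index.get_indexer([config.root_cell])
        if pos[0] < 0:
            raise ValueError(f"root cell {config.root_cell!r} not found")
        root = int(pos[0])
    pt = trajectory.compute_pseudotime(Se, root, restrict_to_root_component=True)
    _fmt(
        pd.DataFrame({"t": pt.t, "distance": pt.distances}, index=nme.obs.index),
        out / "pseudotime.tsv",
    )
    Ke = clustering.estimate_num_clusters(Se)
    sae = clustering.soft_cluster(Se, Ke, seed=rng_seed)
    labels_e = sae.hard_labels
    tree = trajectory.infer_lineage(Se, labels_e, sae, pt, seed=rng_seed)
    (out / "lineage.json").write_text(json.dumps(tree.to_json_dict(), indent=2))
    markers_e = clustering.find_markers(nme, labels_e)
    profs = trajectory.pseudotime_dependent_genes(
        nme,
        labels_e,
        pt,
        top_n=config.deg_top_n,
        bins=config.wave_bins,
        window=config.wave_window,
        markers=markers_e,
    )
    wave = profs.profiles.loc[profs.rolling_wave_order]
    _fmt(wave, out / "rolling_wave.tsv")
    pat_profs = trajectory.pseudotime_dependent_genes(
        nme,
        labels_e,
        pt,
        top_n=config.deg_top_n,
        bins=config.pattern_bins,
        window=config.pattern_window,
        markers=markers_e,
    )
    patterns, pattern_means = trajectory.cluster_temporal_patterns(pat_profs)
    patterns.to_frame().to_csv(out / "pattern_labels.tsv", sep="\t")
    _fmt(pattern_means, out / "pattern_means.tsv")
    manifest["stages"]["trajectory"] = {
        "cells": nme.n_cells,
        "K": int(Ke),
        "excluded_clusters": sorted(int(c) for c in excluded),
        "n_deg": int(len(profs.profiles)),
        "n_patterns": int(patterns.nunique()),
        "lineage_edges": [[str(u), str(v)] for u, v in tree.tree.edges],
    }

    # --- signaling ------------------------------------------------------
    if config.pathway_file:
        spec = signaling.load_pathways(config.pathway_file)
    elif truth is not None:
        spec = signaling.PathwaySpec(
            [
                signaling.PathwayRecord(
                    r.pathway, r.ligand, r.receptor, r.targets_up, r.targets_down
                )
                for r in truth.signaling_plan
            ]
        )
    else:
        spec = signaling.PathwaySpec([])
    cluster_mats: dict[str, pd.DataFrame] = {}
    edge_rows = []
    per_library: dict[str, dict[str, pd.DataFrame]] = {}
    if len(spec):
        signaling.write_pathways(spec, out / "pathways.tsv")
        for rec in spec.records:
            cs = signaling.signaling_probability(
                nm, rec, phi=config.phi,
                apply_threshold=config.threshold_level == "cell",
            )
            if cs is None:
                continue
            M = signaling.aggregate_cluster_signaling(cs, labels)
            if config.threshold_level == "cluster":
                M = M.where(M >= config.phi, 0.0)
            cluster_mats[rec.pair_id] = M
            for a in M.index:
                for b in M.columns:
                    if M.loc[a, b] > 0:
                        edge_rows.append(
                            {
                                "pair": rec.pair_id,
                                "sender": a,
                                "receiver": b,
                                "probability": M.loc[a, b],
                            }
                        )
        # per-library networks for the consistency report
        libs = pd.unique(nm.obs["library"])
        for lib in libs:
            mask = (nm.obs["library"] == lib).to_numpy()
            nml = io_qc.NormalizedMatrix(
                nm.values[mask], nm.obs.iloc[mask], nm.var, nm.scale_factor
            )
            per_library[lib] = {}
            for rec in spec.records:
                cs = signaling.signaling_probability(
                    nml, rec, phi=config.phi, apply_threshold=False
                )
                if cs is None:
                    continue
                per_library[lib][rec.pair_id] = signaling.aggregate_cluster_signaling(
                    cs, labels[mask]
                )
        ref = config.reference_library or (
            "library_3" if "library_3" in per_library else sorted(per_library)[0]
        )
        cons = signaling.consistency_report(per_library, ref)
        _fmt(cons, out / "consistency.tsv", index=False)
        if cluster_mats:
            groups, group_means = signaling.group_lr_pairs(cluster_mats, seed=rng_seed)
            groups.to_frame().to_csv(out / "lr_groups.tsv", sep="\t")
        _fmt(
            pd.DataFrame(edge_rows, columns=["pair", "sender", "receiver", "probability"]),
            out / "signaling_edges.tsv",
            index=False,
        )
        manifest["stages"]["signaling"] = {
            "pairs": len(spec),
            "edges": len(edge_rows),
            "reference_library": ref,
        }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
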