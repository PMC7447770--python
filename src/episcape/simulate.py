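"""Synthetic epidermal scRNA-seq generator with full ground truth.

Emulates the statistical structure of neonatal human interfollicular
epidermis profiled by droplet scRNA-seq: seven cell communities (four
basal stem-cell states BAS-I..BAS-IV, spinous SPN, granular GRN and an
off-trajectory melanocyte community MEL) at realistic proportions,
disjoint marker-gene programs, a bifurcating basal->spinous->granular
latent differentiation trajectory with six temporal expression
archetypes, five sequencing libraries, mitochondrial-fraction and
library-depth variation including planted low-quality cells, and planted
ligand-receptor sender/receiver relationships for four signaling
pathways.

Counts are negative binomial around a per-cell, per-gene mean that
combines a gene baseline, the community marker program, the temporal
archetype evaluated at the cell's latent time, and signaling-plan
multipliers, all rescaled to a lognormal per-cell sequencing depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from .io_qc import CountMatrix

__all__ = [
    "CommunitySpec",
    "TemporalArchetype",
    "SignalingRoute",
    "SimulationConfig",
    "GroundTruth",
    "epidermis_preset",
    "generate",
    "write_fixture",
    "default_archetypes",
]

MITO_SYMBOLS = (
    "MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-ATP8", "MT-ATP6", "MT-CO3",
    "MT-ND3", "MT-ND4L", "MT-ND4", "MT-ND5", "MT-ND6", "MT-CYB",
)


@dataclass(frozen=True)
class CommunitySpec:
    name: str
    proportion: float
    n_markers: int


@dataclass(frozen=True)
class TemporalArchetype:
    """A gene-expression shape over latent time t in [0, 1]."""

    name: str
    shape: Callable[[np.ndarray], np.ndarray]
    peak: float  # latent-time position of the maximum


@dataclass(frozen=True)
class SignalingRoute:
    pathway: str
    ligand: str
    receptor: str
    sender: str
    receiver: str
    targets_up: tuple[str, ...]
    targets_down: tuple[str, ...]


def _bump(center: float, width: float) -> Callable[[np.ndarray], np.ndarray]:
    def f(t: np.ndarray) -> np.ndarray:
        return np.exp(-(((np.asarray(t) - center) / width) ** 2))

    return f


def default_archetypes() -> list[TemporalArchetype]:
    """Six temporal archetypes: one early-declining program, four
    transient peaks at staggered times, and one late-rising program."""
    return [
        TemporalArchetype("early_decline", _bump(0.0, 0.30), 0.0),
        TemporalArchetype("peak_t20", _bump(0.2, 0.12), 0.2),
        TemporalArchetype("peak_t40", _bump(0.4, 0.12), 0.4),
        TemporalArchetype("peak_t60", _bump(0.6, 0.12), 0.6),
        TemporalArchetype("peak_t80", _bump(0.8, 0.12), 0.8),
        TemporalArchetype("late_rise", _bump(1.0, 0.30), 1.0),
    ]


@dataclass
class SimulationConfig:
    n_cells: int = 3000
    n_genes: int = 2000
    n_libraries: int = 5
    communities: list[CommunitySpec] = field(default_factory=list)
    lineage: list[tuple[str, str]] = field(default_factory=list)
    off_trajectory: tuple[str, ...] = ()
    archetypes: list[TemporalArchetype] = field(default_factory=default_archetypes)
    n_temporal_per_archetype: int = 50
    nb_dispersion: float = 0.3
    library_size_lognormal: tuple[float, float] = (math.log(6000.0), 0.35)
    mito_fraction_beta: tuple[float, float] = (2.0, 70.0)
    lowquality_fraction: float = 0.08
    signaling_plan: list[SignalingRoute] = field(default_factory=list)
    marker_effect: float = 6.0
    transition_width: float = 0.02
    temporal_floor: float = 0.3
    temporal_amplitude: float = 1.0
    signal_effect: float = 4.0
    suppress_effect: float = 0.25
    baseline_log_sd: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.communities:
            total = sum(c.proportion for c in self.communities)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"community proportions sum to {total}, not 1")
            names = [c.name for c in self.communities]
            if len(set(names)) != len(names):
                raise ValueError("duplicate community names")
            on_traj = [n for n in names if n not in self.off_trajectory]
            if self.lineage:
                nodes = {n for e in self.lineage for n in e}
                if nodes != set(on_traj):
                    raise ValueError(
                        "lineage must cover every on-trajectory community exactly"
                    )
                if len(self.lineage) != len(on_traj) - 1:
                    raise ValueError("lineage edge count != n_communities - 1")
                children = [c for _, c in self.lineage]
                if len(set(children)) != len(children):
                    raise ValueError("lineage is not a tree (a node has 2 parents)")

    # -- gene bookkeeping ------------------------------------------------
    def gene_demand(self) -> int:
        n_sig = len(
            {g for r in self.signaling_plan
             for g in (r.ligand, r.receptor, *r.targets_up, *r.targets_down)}
        )
        return (
            len(MITO_SYMBOLS)
            + sum(c.n_markers for c in self.communities)
            + len(self.archetypes) * self.n_temporal_per_archetype
            + n_sig
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["archetypes"] = [
            {"name": a.name, "peak": a.peak} for a in self.archetypes
        ]
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class GroundTruth:
    """Planted truth accompanying a simulated count matrix."""

    labels: np.ndarray  # community name per cell
    latent_time: np.ndarray  # in [0,1]; NaN for off-trajectory cells
    library_id: np.ndarray
    markers: dict[str, list[str]]  # community -> marker symbols
    temporal_assignment: dict[str, int]  # temporal gene -> archetype index
    lowquality_flags: np.ndarray
    lowquality_mode: np.ndarray  # "none" | "low_genes" | "high_mito" | "many_genes"
    signaling_plan: list[SignalingRoute]
    lineage: list[tuple[str, str]]
    archetype_peaks: list[float]

    def to_frame(self, barcodes: Sequence[str]) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell": list(barcodes),
                "library": self.library_id,
                "label": self.labels,
                "latent_time": self.latent_time,
                "lowquality": self.lowquality_flags,
                "lowquality_mode": self.lowquality_mode,
            }
        )


def epidermis_preset() -> SimulationConfig:
    """Default epidermis configuration.

    Seven communities at the proportions observed in neonatal foreskin
    epidermis (BAS-I 4%, BAS-II 9%, BAS-III 7%, BAS-IV 3%, SPN 54%,
    GRN 17%, MEL 6%; the granular share absorbs the rounding remainder),
    150 disjoint markers each, a bifurcating lineage
    BAS-I -> BAS-II -> BAS-III -> {BAS-IV, SPN}, SPN -> GRN with MEL off
    the trajectory, six temporal archetypes, five libraries, 3,000 cells
    and 2,000 genes.
    """
    communities = [
        CommunitySpec("BAS-I", 0.04, 150),
        CommunitySpec("BAS-II", 0.09, 150),
        CommunitySpec("BAS-III", 0.07, 150),
        CommunitySpec("BAS-IV", 0.03, 150),
        CommunitySpec("SPN", 0.54, 150),
        CommunitySpec("GRN", 0.17, 150),
        CommunitySpec("MEL", 0.06, 150),
    ]
    lineage = [
        ("BAS-I", "BAS-II"),
        ("BAS-II", "BAS-III"),
        ("BAS-III", "BAS-IV"),
        ("BAS-III", "SPN"),
        ("SPN", "GRN"),
    ]
    plan = [
        _route("WNT", "BAS-I", "BAS-II"),
        _route("NOTCH", "BAS-III", "SPN"),
        _route("TGFB", "BAS-IV", "BAS-III"),
        _route("JAKSTAT", "SPN", "GRN"),
    ]
    return SimulationConfig(
        communities=communities,
        lineage=lineage,
        off_trajectory=("MEL",),
        signaling_plan=plan,
    )


def _route(pathway: str, sender: str, receiver: str) -> SignalingRoute:
    return SignalingRoute(
        pathway=pathway,
        ligand=f"{pathway}-LIG",
        receptor=f"{pathway}-REC",
        sender=sender,
        receiver=receiver,
        targets_up=tuple(f"{pathway}-UP{i}" for i in range(1, 6)),
        targets_down=tuple(f"{pathway}-DN{i}" for i in range(1, 6)),
    )


def _time_windows(
    lineage: list[tuple[str, str]]
) -> dict[str, tuple[float, float]]:
    """Latent-time window per community from its position in the lineage.

    Each community occupies a unit-length window. At a bifurcation the
    main continuation (largest subtree) starts where the parent's window
    ends, while side branches bud from the middle of the parent's
    window — so a terminal side branch is metrically farther from the
    main trunk's continuation than the parent is, and the planted tree
    is also the tree of shortest generative distances. Windows are
    finally rescaled so the latest leaf ends at 1.
    """
    children: dict[str, list[str]] = {}
    parents = {c for _, c in lineage}
    nodes = {n for e in lineage for n in e}
    for p, c in lineage:
        children.setdefault(p, []).append(c)
    roots = sorted(nodes - parents)
    if len(roots) != 1:
        raise ValueError(f"lineage must have exactly one root, got {roots}")

    def subtree_size(n: str) -> int:
        return 1 + sum(subtree_size(c) for c in children.get(n, []))

    raw: dict[str, tuple[float, float]] = {}

    def assign(node: str, start: float) -> None:
        raw[node] = (start, start + 1.0)
        kids = children.get(node, [])
        if not kids:
            return
        main = max(kids, key=subtree_size)
        for c in kids:
            assign(c, start + (1.0 if c == main else 0.5))

    assign(roots[0], 0.0)
    end = max(hi for _, hi in raw.values())
    return {n: (lo / end, hi / end) for n, (lo, hi) in raw.items()}


def _build_gene_table(config: SimulationConfig) -> tuple[pd.DataFrame, dict, dict]:
    """Lay out the gene universe: mito, markers, temporal, signaling, filler."""
    symbols: list[str] = list(MITO_SYMBOLS)
    markers: dict[str, list[str]] = {}
    for comm in config.communities:
        tag = comm.name.replace("-", "")
        ms = [f"{tag}-MK{i:03d}" for i in range(1, comm.n_markers + 1)]
        markers[comm.name] = ms
        symbols.extend(ms)
    temporal: dict[str, int] = {}
    for ai in range(len(config.archetypes)):
        for gi in range(1, config.n_temporal_per_archetype + 1):
            g = f"TMP{ai + 1}-{gi:03d}"
            temporal[g] = ai
            symbols.append(g)
    sig_genes: list[str] = []
    for r in config.signaling_plan:
        for g in (r.ligand, r.receptor, *r.targets_up, *r.targets_down):
            if g not in sig_genes:
                sig_genes.append(g)
    symbols.extend(sig_genes)
    if len(symbols) > config.n_genes:
        raise ValueError(
            f"gene demands ({len(symbols)}) exceed n_genes ({config.n_genes})"
        )
    n_filler = config.n_genes - len(symbols)
    symbols.extend(f"GENE{i:04d}" for i in range(1, n_filler + 1))
    var = pd.DataFrame(
        {
            "symbol": symbols,
            "mito": [s.startswith("MT-") for s in symbols],
        },
        index=pd.Index([f"SYN{i:05d}" for i in range(len(symbols))], name="gene_id"),
    )
    return var, markers, temporal


def generate(
    config: SimulationConfig, seed: int | None = None
) -> tuple[CountMatrix, GroundTruth]:
    """Draw a synthetic count matrix and its ground truth.

    Identical ``(config, seed)`` yields bit-identical output. ``seed``
    defaults to ``config.seed``.
    """
    if not config.communities:
        raise ValueError("config has no communities")
    if config.gene_demand() > config.n_genes:
        raise ValueError(
            f"gene demands ({config.gene_demand()}) exceed n_genes "
            f"({config.n_genes})"
        )
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n, g = config.n_cells, config.n_genes
    var, markers, temporal = _build_gene_table(config)
    symbols = var["symbol"].to_numpy()
    sym_index = {s: i for i, s in enumerate(symbols)}
    mito_idx = np.flatnonzero(var["mito"].to_numpy())
    nonmito_idx = np.flatnonzero(~var["mito"].to_numpy())

    # --- cell attributes -------------------------------------------------
    names = [c.name for c in config.communities]
    props = np.array([c.proportion for c in config.communities])
    labels = rng.choice(names, size=n, p=props)
    library_num = rng.integers(0, config.n_libraries, size=n)
    # group cells by library so on-disk fixtures round-trip in order
    order = np.argsort(library_num, kind="stable")
    labels = labels[order]
    library_num = library_num[order]
    library_id = np.array([f"library_{i + 1}" for i in library_num])

    windows = _time_windows(config.lineage) if config.lineage else {}
    latent = np.full(n, np.nan)
    for comm, (lo, hi) in windows.items():
        mask = labels == comm
        latent[mask] = rng.uniform(lo, hi, size=int(mask.sum()))

    # --- per-cell per-gene relative rates --------------------------------
    base = rng.lognormal(mean=0.0, sigma=config.baseline_log_sd, size=g)
    sig_syms = sorted(
        {s for r in config.signaling_plan
         for s in (r.ligand, r.receptor, *r.targets_up, *r.targets_down)}
    )
    if sig_syms:
        # keep signaling genes sparse enough that detection is informative
        base[[sym_index[s] for s in sig_syms]] = 0.3 * np.median(base)
    rates = np.tile(base, (n, 1))
    # Marker-program exponents per (cell, community): each cell expresses
    # its own community's program at full strength, except near a lineage
    # boundary where the two adjacent programs cross-fade, making
    # transitional cells genuinely intermediate (differentiation is a
    # continuum, not a set of disconnected islands).
    comm_names = list(markers)
    comm_pos = {c: i for i, c in enumerate(comm_names)}
    expo = np.zeros((n, len(comm_names)))
    for comm in comm_names:
        expo[labels == comm, comm_pos[comm]] = 1.0
    if config.lineage and config.transition_width > 0:
        tw = config.transition_width
        for parent, child in config.lineage:
            b = windows[child][0]  # boundary latent time between the two
            for src, dst in ((parent, child), (child, parent)):
                rows = np.flatnonzero(labels == src)
                lam = 0.5 * np.exp(-(((latent[rows] - b) / tw) ** 2))
                expo[rows, comm_pos[src]] -= lam
                expo[rows, comm_pos[dst]] += lam
    np.clip(expo, 0.0, None, out=expo)
    for comm, ms in markers.items():
        cols = [sym_index[s] for s in ms]
        mult = config.marker_effect ** expo[:, comm_pos[comm]]
        active = np.flatnonzero(mult != 1.0)
        rates[np.ix_(active, cols)] *= mult[active, None]
    if temporal:
        on_traj = ~np.isnan(latent)
        t = latent[on_traj]
        for ai, arch in enumerate(config.archetypes):
            cols = [sym_index[s] for s, a in temporal.items() if a == ai]
            factor = config.temporal_floor + config.temporal_amplitude * arch.shape(t)
            rates[np.ix_(on_traj, cols)] *= factor[:, None]
    for r in config.signaling_plan:
        send = labels == r.sender
        recv = labels == r.receiver
        rates[send, sym_index[r.ligand]] *= config.signal_effect
        rates[recv, sym_index[r.receptor]] *= config.signal_effect
        up = [sym_index[s] for s in r.targets_up]
        dn = [sym_index[s] for s in r.targets_down]
        if up:
            rates[np.ix_(recv, up)] *= config.signal_effect
        if dn:
            rates[np.ix_(recv, dn)] *= config.suppress_effect

    # --- depth and mitochondrial composition -----------------------------
    mu_log, sd_log = config.library_size_lognormal
    depth = rng.lognormal(mean=mu_log, sigma=sd_log, size=n)
    a_b = config.mito_fraction_beta
    mito_frac = rng.beta(a_b[0], a_b[1], size=n)
    mito_w = rng.lognormal(0.0, 0.5, size=len(mito_idx))
    mito_w /= mito_w.sum()
    nonmito_rates = rates[:, nonmito_idx]
    nonmito_rates /= nonmito_rates.sum(axis=1, keepdims=True)
    mu = np.empty_like(rates)
    mu[:, nonmito_idx] = nonmito_rates * ((1.0 - mito_frac) * depth)[:, None]
    mu[:, mito_idx] = mito_w[None, :] * (mito_frac * depth)[:, None]

    # --- negative binomial sampling --------------------------------------
    phi = config.nb_dispersion
    p_nb = 1.0 / (1.0 + phi * mu)
    counts = rng.negative_binomial(1.0 / phi, p_nb).astype(np.int64)

    # --- planted low-quality cells ---------------------------------------
    n_bad = int(round(config.lowquality_fraction * n))
    bad_cells = rng.choice(n, size=n_bad, replace=False) if n_bad else np.array([], int)
    modes = np.full(n, "none", dtype=object)
    feasible = ["low_genes", "high_mito"]
    if g > 5000:
        feasible.append("many_genes")
    for c in bad_cells:
        mode = feasible[rng.integers(0, len(feasible))]
        modes[c] = mode
        if mode == "low_genes":
            keep = rng.choice(nonmito_idx, size=120, replace=False)
            row = np.zeros(g, dtype=np.int64)
            row[keep] = counts[c, keep]
            if (row > 0).sum() == 0:
                row[keep[0]] = 1
            counts[c] = row  # mito genes zeroed: fails only the min-genes filter
        elif mode == "high_mito":
            target = rng.uniform(0.15, 0.35)
            nonmito_total = int(counts[c, nonmito_idx].sum())
            m_total = max(1, int(math.ceil(target / (1 - target) * nonmito_total)))
            counts[c, mito_idx] = rng.multinomial(m_total, mito_w)
        else:  # many_genes: push detected genes over the doublet-like cap
            extra = rng.choice(g, size=5200, replace=False)
            counts[c, extra] += 1
    lowq = modes != "none"

    barcodes = pd.Index(
        [f"CELL{i:05d}-{library_num[i] + 1}" for i in range(n)], name="barcode"
    )
    obs = pd.DataFrame({"library": library_id}, index=barcodes)
    cm = CountMatrix(sp.csr_matrix(counts), obs, var)
    truth = GroundTruth(
        labels=labels,
        latent_time=latent,
        library_id=library_id,
        markers=markers,
        temporal_assignment=temporal,
        lowquality_flags=lowq,
        lowquality_mode=modes.astype(str),
        signaling_plan=list(config.signaling_plan),
        lineage=list(config.lineage),
        archetype_peaks=[a.peak for a in config.archetypes],
    )
    return cm, truth


def write_fixture(counts: CountMatrix, truth: GroundTruth, directory) -> None:
    """Write a 10x-style per-library fixture plus ground truth and config.

    Layout: one subdirectory per library with ``matrix.mtx`` (Matrix
    Market coordinate, genes x cells, 1-based), ``barcodes.tsv`` and
    ``features.tsv``; a top-level ``ground_truth.tsv``.
    """
    from .io_qc import write_count_matrix

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_count_matrix(counts, directory)
    truth.to_frame(counts.obs.index).to_csv(
        directory / "ground_truth.tsv", sep="\t", index=False
    )
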