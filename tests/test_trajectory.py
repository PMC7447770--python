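"""Pseudotime, lineage MST, temporal dynamics and differentiation score."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.stats import spearmanr
from sklearn.metrics import adjusted_rand_score

from episcape.clustering import SimilarityMatrix, SoftAssignment
from episcape.trajectory import (
    _cluster_distances,
    cluster_temporal_patterns,
    compute_pseudotime,
    differentiation_score,
    infer_lineage,
    pseudotime_dependent_genes,
)

from conftest import toy_normalized


def sim_from_dense(a) -> SimilarityMatrix:
    a = np.asarray(a, float)
    return SimilarityMatrix(sp.csr_matrix(a), k=a.shape[0] - 1)


def exhaustive_shortest_paths(S: np.ndarray, root: int) -> np.ndarray:
    """Independent oracle: minimum over all simple paths (edge length 1-S)."""
    n = S.shape[0]
    G = nx.Graph()
    G.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if S[i, j] > 0:
                G.add_edge(i, j, w=1.0 - S[i, j])
    out = np.full(n, np.inf)
    out[root] = 0.0
    for tgt in range(n):
        if tgt == root:
            continue
        best = np.inf
        try:
            for path in nx.all_simple_paths(G, root, tgt):
                w = sum(G.edges[u, v]["w"] for u, v in zip(path, path[1:]))
                best = min(best, w)
        except nx.NodeNotFound:
            pass
        out[tgt] = best
    return out


class TestComputePseudotime:
    def test_root_is_zero(self, epi_run):
        assert epi_run.pt.t[epi_run.pt.root] == 0.0

    def test_three_cell_path_normalizes(self):
        S = np.array([[0, 0.5, 0], [0.5, 0, 0.5], [0, 0.5, 0]])
        pt = compute_pseudotime(sim_from_dense(S), 0)
        assert np.allclose(pt.t, [0.0, 0.5, 1.0])

    def test_matches_exhaustive_oracle_on_small_graphs(self):
        rng = np.random.default_rng(0)
        for trial in range(5):
            n = 8
            S = np.triu(rng.random((n, n)) * (rng.random((n, n)) < 0.5), 1)
            S = S + S.T
            S[0, 1] = S[1, 0] = 0.9  # keep the root connected
            pt = compute_pseudotime(
                sim_from_dense(S), 0, restrict_to_root_component=True
            )
            oracle = exhaustive_shortest_paths(S, 0)
            finite = np.isfinite(oracle)
            assert np.allclose(
                pt.distances[finite], oracle[finite], atol=1e-9
            )

    def test_small_root_component_is_error(self):
        S = np.zeros((4, 4))
        S[0, 1] = S[1, 0] = 0.5  # root component of 2 < 50% of 5? (2/4 = exactly half)
        S = np.zeros((5, 5))
        S[0, 1] = S[1, 0] = 0.5
        S[2, 3] = S[3, 2] = S[3, 4] = S[4, 3] = 0.5
        with pytest.raises(ValueError, match="component"):
            compute_pseudotime(sim_from_dense(S), 0)

    def test_unreachable_cells_need_flag(self):
        S = np.zeros((5, 5))
        for i, j in [(0, 1), (1, 2), (2, 3)]:
            S[i, j] = S[j, i] = 0.5
        with pytest.raises(ValueError, match="unreachable"):
            compute_pseudotime(sim_from_dense(S), 0)
        pt = compute_pseudotime(sim_from_dense(S), 0, restrict_to_root_component=True)
        assert np.isnan(pt.t[4])
        assert pt.n_unreachable == 1

    def test_preset_correlates_with_latent_time(self, epi_run):
        rho = spearmanr(epi_run.pt.t, epi_run.true_latent).statistic
        assert rho >= 0.9


def bruteforce_mst(D: pd.DataFrame) -> set[frozenset]:
    """Minimum spanning tree by enumeration over all spanning trees."""
    nodes = list(D.index)
    edges = [
        (a, b, D.loc[a, b])
        for i, a in enumerate(nodes)
        for b in nodes[i + 1 :]
    ]
    best, best_w = None, np.inf
    for combo in itertools.combinations(edges, len(nodes) - 1):
        G = nx.Graph()
        G.add_nodes_from(nodes)
        G.add_edges_from([(a, b) for a, b, _ in combo])
        if nx.is_connected(G):
            w = sum(w for _, _, w in combo)
            if w < best_w:
                best_w, best = w, {frozenset((a, b)) for a, b, _ in combo}
    return best


class TestInferLineage:
    def make_instance(self, seed=0):
        """Five chained 6-cell blobs -> clusters A..E along a line."""
        rng = np.random.default_rng(seed)
        n_per, k = 6, 5
        n = n_per * k
        S = np.zeros((n, n))
        for c in range(k):
            s = c * n_per
            S[s : s + n_per, s : s + n_per] = 0.9 + 0.05 * rng.random((n_per, n_per))
        for c in range(k - 1):  # weak bridges between consecutive blobs
            i, j = c * n_per + n_per - 1, (c + 1) * n_per
            S[i, j] = S[j, i] = 0.4
        S = np.triu(S, 1)
        S = S + S.T
        labels = np.repeat(list("ABCDE"), n_per)
        P = np.full((n, k), 0.02)
        for c in range(k):
            P[c * n_per : (c + 1) * n_per, c] = 1 - 0.02 * (k - 1)
        sa = SoftAssignment(P=P, K=k, objective=0.0, n_iter=0,
                            objective_trace=np.zeros(1))
        sim = sim_from_dense(S)
        pt = compute_pseudotime(sim, 0)
        return sim, labels, sa, pt

    def test_two_clusters_single_edge_weight_one(self):
        S = np.array(
            [[0, 0.9, 0.3, 0.2], [0.9, 0, 0.3, 0.2], [0.3, 0.3, 0, 0.9], [0.2, 0.2, 0.9, 0]]
        )
        labels = np.array(["a", "a", "b", "b"])
        P = np.array([[0.9, 0.1]] * 2 + [[0.1, 0.9]] * 2)
        sa = SoftAssignment(P=P, K=2, objective=0.0, n_iter=0, objective_trace=np.zeros(1))
        sim = sim_from_dense(S)
        tree = infer_lineage(sim, labels, sa, compute_pseudotime(sim, 0))
        assert tree.edges == [("a", "b")]
        assert tree.tree.edges["a", "b"]["weight"] == 1.0

    def test_mst_matches_bruteforce_enumeration(self):
        sim, labels, sa, pt = self.make_instance()
        tree = infer_lineage(sim, labels, sa, pt)
        oracle = bruteforce_mst(tree.distances)
        assert tree.undirected_edge_set() == oracle

    def test_chain_topology_and_monotone_order(self):
        sim, labels, sa, pt = self.make_instance()
        tree = infer_lineage(sim, labels, sa, pt)
        assert tree.undirected_edge_set() == {
            frozenset(p) for p in [("A", "B"), ("B", "C"), ("C", "D"), ("D", "E")]
        }
        assert tree.root_cluster == "A"
        order = [tree.order[c] for c in "ABCDE"]
        assert order == sorted(order)

    def test_preset_topology_matches_planted(self, preset_run, epi_run):
        sa = epi_run.assignment
        # map NMF clusters to community names by majority truth label
        name = {}
        for j in range(sa.K):
            members = epi_run.true_labels[sa.hard_labels == j]
            name[j] = pd.Series(members).mode()[0] if len(members) else str(j)
        tree = infer_lineage(epi_run.S, sa.hard_labels, sa, epi_run.pt, seed=1)
        got = {frozenset((name[u], name[v])) for u, v in tree.tree.edges}
        planted = {frozenset(e) for e in preset_run.truth.lineage}
        assert got == planted
        # order increases along every root-to-leaf path of the planted tree
        for leaf in [n for n in tree.tree.nodes if tree.tree.out_degree(n) == 0]:
            path = nx.shortest_path(tree.tree, tree.root_cluster, leaf)
            orders = [tree.order[c] for c in path]
            assert orders == sorted(orders)
        for parent in tree.tree.nodes:
            children = list(tree.tree.successors(parent))
            if children:
                s = sum(tree.tree.edges[parent, c]["weight"] for c in children)
                assert s == pytest.approx(1.0, abs=1e-8)

    def test_subsampled_distances_close_to_exact(self, preset_run):
        S, labels = preset_run.S, preset_run.true_labels
        exact = _cluster_distances(S.S, labels, max_cells=10_000, seed=0)
        sub = _cluster_distances(S.S, labels, max_cells=200, seed=0)
        E, U = exact.to_numpy(), sub.to_numpy()
        finite = np.isfinite(E)  # off-graph pairs (melanocytes) excluded
        rel = np.abs(U[finite] - E[finite]) / np.maximum(E[finite], 1e-12)
        assert rel.max() <= 0.10


class TestPseudotimeDependentGenes:
    def make_marker_table(self, lists):
        rows = []
        for cl, genes in lists.items():
            for r, g in enumerate(genes):
                rows.append({"cluster": cl, "gene": g, "rank": r + 1})
        return pd.DataFrame(rows)

    def make_nm_and_pt(self, genes, n_cells=60, seed=0):
        rng = np.random.default_rng(seed)
        nm = toy_normalized(rng.random((n_cells, len(genes))), symbols=genes)
        t = np.linspace(0, 1, n_cells)
        from episcape.trajectory import PseudotimeVector

        pt = PseudotimeVector(t=t, distances=t.copy(), root=0, n_unreachable=0)
        return nm, pt

    def test_disjoint_top100_lists_union_700(self):
        lists = {
            c: [f"c{c}_g{i}" for i in range(100)] for c in range(7)
        }
        genes = [g for gs in lists.values() for g in gs]
        nm, pt = self.make_nm_and_pt(genes)
        labels = np.zeros(60, dtype=int)
        profs = pseudotime_dependent_genes(
            nm, labels, pt, markers=self.make_marker_table(lists)
        )
        assert len(profs.profiles) == 700

    def test_identical_lists_deduplicate(self):
        shared = [f"g{i}" for i in range(100)]
        lists = {0: shared, 1: list(shared)}
        nm, pt = self.make_nm_and_pt(shared)
        profs = pseudotime_dependent_genes(
            nm, np.zeros(60, int), pt, markers=self.make_marker_table(lists)
        )
        assert len(profs.profiles) == 100

    def test_rolling_wave_order_invariant_to_input_order(self, epi_run):
        mk = epi_run.markers
        shuffled = mk.sample(frac=1.0, random_state=0)
        a = pseudotime_dependent_genes(
            epi_run.nm, epi_run.true_labels, epi_run.pt, markers=mk
        )
        b = pseudotime_dependent_genes(
            epi_run.nm, epi_run.true_labels, epi_run.pt, markers=shuffled
        )
        assert a.rolling_wave_order == b.rolling_wave_order

    def test_planted_early_gene_precedes_late_gene(self, preset_run, epi_run):
        truth = preset_run.truth
        arch_of = truth.temporal_assignment
        peaks = truth.archetype_peaks
        early = [g for g, a in arch_of.items() if peaks[a] == 0.0]
        late = [g for g, a in arch_of.items() if peaks[a] == 1.0]
        table = self.make_marker_table({"e": early, "l": late})
        profs = pseudotime_dependent_genes(
            epi_run.nm, epi_run.true_labels, epi_run.pt, markers=table
        )
        pos = {g: i for i, g in enumerate(profs.rolling_wave_order)}
        mean_early = np.mean([pos[g] for g in early if g in pos])
        mean_late = np.mean([pos[g] for g in late if g in pos])
        assert mean_early < mean_late


class TestClusterTemporalPatterns:
    def synth_profiles(self, centers, n_per=50, bins=40, noise=0.05, seed=0):
        rng = np.random.default_rng(seed)
        t = np.linspace(0, 1, bins)
        rows, truth = [], []
        for ai, c in enumerate(centers):
            for _ in range(n_per):
                prof = np.exp(-(((t - c) / 0.15) ** 2))
                prof = prof + rng.normal(0, noise, bins)
                prof = (prof - prof.mean()) / prof.std()
                rows.append(prof)
                truth.append(ai)
        idx = [f"g{i}" for i in range(len(rows))]
        return pd.DataFrame(rows, index=idx), np.array(truth)

    def test_three_separated_archetypes_recovered_exactly(self):
        prof, truth = self.synth_profiles([0.1, 0.5, 0.9])
        labels, means = cluster_temporal_patterns(prof, k="auto")
        assert labels.nunique() == 3
        assert adjusted_rand_score(truth, labels) == 1.0
        assert means.shape == (3, prof.shape[1])

    def test_identical_profiles_one_cluster(self):
        prof = pd.DataFrame(np.tile(np.linspace(-1, 1, 20), (10, 1)))
        with pytest.warns(UserWarning, match="identical"):
            labels, _ = cluster_temporal_patterns(prof, k="auto")
        assert labels.nunique() == 1

    def test_fixed_k_respected(self):
        prof, _ = self.synth_profiles([0.2, 0.8])
        labels, _ = cluster_temporal_patterns(prof, k=4)
        assert labels.nunique() == 4


class TestDifferentiationScore:
    def test_extremes(self):
        x = np.zeros((3, 2))
        x[1] = [5.0, 3.0]  # maximal in every set gene
        nm = toy_normalized(x, symbols=["A", "B"])
        score, _ = differentiation_score(nm, ["A", "B"])
        assert score[0] == 0.0
        assert score[1] == 1.0

    def test_missing_gene_set_is_error(self):
        nm = toy_normalized(np.ones((3, 2)))
        with pytest.raises(ValueError, match="no genes"):
            differentiation_score(nm, ["nope"])

    def test_granular_scores_above_basal(self, preset_run, epi_run):
        grn_program = preset_run.truth.markers["GRN"]
        score, per_cluster = differentiation_score(
            epi_run.nm, grn_program, epi_run.true_labels
        )
        assert per_cluster["GRN"] > per_cluster["BAS-I"]
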