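"""Similarity graph, eigengap, symmetric NMF, markers and embedding."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from episcape import clustering
from episcape.clustering import (
    build_similarity,
    embed_2d,
    estimate_num_clusters,
    find_markers,
    marker_overlap,
    soft_cluster,
    top_markers,
)

from conftest import block_similarity, toy_normalized


class TestBuildSimilarity:
    def test_identical_profiles_have_similarity_one(self):
        rng = np.random.default_rng(0)
        x = rng.random((6, 40))
        x[1] = x[0]  # two identical cells
        S = build_similarity(toy_normalized(x)).S.toarray()
        assert S[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_single_cell_degenerate(self):
        S = build_similarity(toy_normalized(np.ones((1, 5))))
        assert S.S.shape == (1, 1)
        assert S.S.nnz == 0

    def test_symmetric_nonneg_zero_diagonal(self, preset_run):
        S = preset_run.S.S
        assert (abs(S - S.T) > 1e-12).nnz == 0
        assert S.data.min() >= 0 and S.data.max() <= 1
        assert np.all(S.diagonal() == 0)

    def test_within_community_similarity_exceeds_between(self, preset_run):
        S = preset_run.S.S
        labels = preset_run.true_labels
        for comm in np.unique(labels):
            mask = labels == comm
            within = S[np.ix_(mask, mask)].mean()
            between = S[np.ix_(mask, ~mask)].mean()
            assert within > between, comm


class TestEstimateNumClusters:
    @pytest.mark.parametrize("n_blocks", [1, 2, 3, 4, 5, 6])
    def test_block_diagonal_recovers_block_count(self, n_blocks):
        S = block_similarity([8] * n_blocks)
        assert estimate_num_clusters(S) == n_blocks

    def test_empty_graph_is_error(self):
        import scipy.sparse as sp

        S = clustering.SimilarityMatrix(sp.csr_matrix((0, 0)), k=0)
        with pytest.raises(ValueError):
            estimate_num_clusters(S)


class TestSoftCluster:
    def test_exact_two_block_gives_one_hot_rows(self):
        S = block_similarity([10, 15])
        sa = soft_cluster(S, 2, seed=0)
        onehot = np.max(sa.P, axis=1)
        assert np.all(onehot > 1 - 1e-3)
        # the two blocks land in different clusters
        assert sa.hard_labels[0] != sa.hard_labels[-1]

    def test_row_sums_and_nonnegativity(self, preset_run):
        P = preset_run.assignment.P
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-8)
        assert P.min() >= 0

    def test_objective_monotone_nonincreasing(self, preset_run):
        trace = preset_run.assignment.objective_trace
        diffs = np.diff(trace)
        assert np.all(diffs <= 1e-10 * np.maximum(np.abs(trace[:-1]), 1.0))

    def test_k_out_of_range(self):
        S = block_similarity([5])
        with pytest.raises(ValueError):
            soft_cluster(S, 6, seed=0)

    def test_permutation_equivariance_on_separated_blocks(self):
        import scipy.sparse as sp

        rng = np.random.default_rng(3)
        S0 = block_similarity([20, 30], within=0.8).S.toarray()
        S0 += rng.uniform(0, 0.05, S0.shape)
        S0 = np.triu(S0, 1)
        S0 = S0 + S0.T
        Sm = clustering.SimilarityMatrix(sp.csr_matrix(S0), k=49)
        perm = rng.permutation(50)
        Sp = clustering.SimilarityMatrix(sp.csr_matrix(S0[np.ix_(perm, perm)]), k=49)
        a = soft_cluster(Sm, 2, seed=0)
        b = soft_cluster(Sp, 2, seed=0)
        # partitions agree after undoing the permutation (up to column order)
        assert adjusted_rand_score(a.hard_labels[perm], b.hard_labels) == 1.0

    def test_preset_recovery_vs_spectral_oracle(self, preset_run):
        """NMF hard labels agree with ground truth and with an independent
        spectral clustering of the same similarity matrix."""
        from sklearn.cluster import SpectralClustering

        labels = preset_run.assignment.hard_labels
        assert adjusted_rand_score(preset_run.true_labels, labels) >= 0.8
        spect = SpectralClustering(
            n_clusters=7, affinity="precomputed", random_state=0, assign_labels="discretize"
        ).fit_predict(preset_run.S.S.toarray() + 1e-12)
        assert adjusted_rand_score(spect, labels) >= 0.7


class TestFindMarkers:
    def make_two_cluster_data(self):
        rng = np.random.default_rng(4)
        x = rng.random((40, 30)) * 0.1
        x[:20, 0] = 2.0  # perfect marker of cluster 0
        x[:20, 1] = 0.0
        x[np.flatnonzero(rng.random(40) < 0.1), 2] = 1.0
        labels = np.array([0] * 20 + [1] * 20)
        return toy_normalized(x), labels

    def test_perfect_separation_tops_ranking(self):
        nm, labels = self.make_two_cluster_data()
        mk = find_markers(nm, labels)
        assert top_markers(mk, 0, 1) == ["G0"]

    def test_low_fraction_gene_excluded(self):
        x = np.zeros((40, 5))
        x[:4, 0] = 5.0  # only 20% of cluster 0 (n=20) express it
        x[:20, 1] = 1.0  # a genuine marker so the table is non-degenerate
        labels = np.array([0] * 20 + [1] * 20)
        mk = find_markers(toy_normalized(x), labels)
        sub = mk[(mk.cluster == 0) & (mk.gene == "G0")]
        assert sub.empty
        assert "G1" in set(mk[mk.cluster == 0].gene)

    def test_small_cluster_skipped_with_warning(self):
        rng = np.random.default_rng(1)
        x = rng.random((23, 10))
        labels = np.array([0] * 20 + [1] * 2 + [2])
        with pytest.warns(UserWarning, match="skipped"):
            mk = find_markers(toy_normalized(x), labels)
        assert set(mk["cluster"]) <= {0}

    def test_invariant_under_cluster_relabeling(self):
        nm, labels = self.make_two_cluster_data()
        a = find_markers(nm, labels)
        b = find_markers(nm, 1 - labels)
        a0 = a[a.cluster == 0].drop(columns="cluster").reset_index(drop=True)
        b1 = b[b.cluster == 1].drop(columns="cluster").reset_index(drop=True)
        pd.testing.assert_frame_equal(a0, b1)

    def test_preset_markers_recovered(self, preset_run):
        """>=80% of each community's planted markers appear in the
        community's top-100 list (clusters matched by majority label)."""
        import warnings as _w

        labels = preset_run.assignment.hard_labels
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            mk = find_markers(preset_run.nm, labels)
        for comm, planted in preset_run.truth.markers.items():
            mask = preset_run.true_labels == comm
            cl = np.bincount(labels[mask]).argmax()
            top = set(top_markers(mk, cl, 100))
            recovered = len(top & set(planted)) / 100
            assert recovered >= 0.8, (comm, recovered)


class TestMarkerOverlap:
    def make_table(self, lists):
        rows = []
        for cl, genes in lists.items():
            for r, g in enumerate(genes):
                rows.append({"cluster": cl, "gene": g, "rank": r + 1})
        return pd.DataFrame(rows)

    def test_self_comparison_diagonal(self):
        t = self.make_table({"a": [f"g{i}" for i in range(30)], "b": ["x", "y"]})
        ov = marker_overlap(t, t, top_n=500)
        assert ov.loc["a", "a"] == 30
        assert ov.loc["b", "b"] == 2

    def test_disjoint_lists_give_zero(self):
        t1 = self.make_table({"a": ["g1", "g2"]})
        t2 = self.make_table({"c": ["h1", "h2"]})
        assert marker_overlap(t1, t2).loc["a", "c"] == 0

    def test_matches_bruteforce_set_intersection(self):
        t1 = self.make_table(
            {"a": ["g1", "g2", "g3"], "b": ["g3", "g4"], "c": ["g5"]}
        )
        t2 = self.make_table({"x": ["g2", "g3", "g9"], "y": ["g5", "g1"]})
        ov = marker_overlap(t1, t2, top_n=2)
        expect = {
            ("a", "x"): len({"g1", "g2"} & {"g2", "g3"}),
            ("a", "y"): len({"g1", "g2"} & {"g5", "g1"}),
            ("b", "x"): len({"g3", "g4"} & {"g2", "g3"}),
            ("b", "y"): 0,
            ("c", "x"): 0,
            ("c", "y"): len({"g5"} & {"g5", "g1"}),
        }
        for (a, b), v in expect.items():
            assert ov.loc[a, b] == v


@pytest.fixture(scope="module")
def small_run():
    from episcape.simulate import epidermis_preset, generate
    from episcape import io_qc

    cfg = epidermis_preset()
    cfg.n_cells = 600
    counts, truth = generate(cfg, seed=2)
    filtered = io_qc.filter_genes(io_qc.filter_cells(counts))
    keep = counts.obs.index.get_indexer(filtered.obs.index)
    nm = io_qc.normalize_log(filtered)
    S = build_similarity(nm)
    return S, truth.labels[keep]


class TestEmbed2D:
    def test_shape_finite_deterministic(self, small_run):
        S, _ = small_run
        e1 = embed_2d(S, seed=3)
        e2 = embed_2d(S, seed=3)
        assert e1.coords.shape == (S.n_cells, 2)
        assert np.all(np.isfinite(e1.coords))
        assert np.array_equal(e1.coords, e2.coords)

    def test_communities_compact_in_layout(self, small_run):
        S, labels = small_run
        coords = embed_2d(S, seed=0).coords
        from scipy.spatial.distance import pdist, squareform

        D = squareform(pdist(coords))
        for comm in np.unique(labels):
            mask = labels == comm
            within = D[np.ix_(mask, mask)].mean()
            between = D[np.ix_(mask, ~mask)].mean()
            assert within < between, comm
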