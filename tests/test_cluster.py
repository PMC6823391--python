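import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from rgcmark import (
    SimConfig,
    average_linkage,
    cluster_enriched_genes,
    correlation_distance,
    cut_tree,
    generate_dataset,
)
from rgcmark.cluster import Dendrogram, Merge

from conftest import log2_matrix, make_matrix


def brute_force_upgma(dist: pd.DataFrame):
    """Independent oracle: recompute every inter-cluster average from the raw
    pairwise leaf distances each round (no Lance-Williams update)."""
    raw = dist.to_numpy()
    index = {leaf: i for i, leaf in enumerate(dist.index)}
    clusters = {leaf: (leaf,) for leaf in dist.index}
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            avg = np.mean(
                [raw[index[x], index[y]] for x in clusters[a] for y in clusters[b]]
            )
            key = (avg, tuple(sorted((min(clusters[a]), min(clusters[b])))))
            if best is None or key < best[0]:
                best = (key, a, b)
        (avg, _), a, b = best
        merges.append((frozenset(clusters[a]) | frozenset(clusters[b]), avg))
        clusters[f"{a}+{b}"] = clusters.pop(a) + clusters.pop(b)
    return merges


class TestCorrelationDistance:
    def test_affine_profiles_have_zero_distance(self):
        x = np.array([1.0, 2.0, 3.0])
        m = log2_matrix(np.column_stack([x, 2 * x + 3]), cells=["a", "b"])
        d = correlation_distance(m)
        assert d.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_profiles_distance_two(self):
        m = log2_matrix(np.column_stack([[1, 2, 3], [3, 2, 1]]), cells=["a", "b"])
        assert correlation_distance(m).loc["a", "b"] == pytest.approx(2.0)

    def test_hand_computed_r(self):
        # r([1,2,3,4],[1,2,3,10]) = 14/sqrt(250)
        m = log2_matrix(np.column_stack([[1, 2, 3, 4], [1, 2, 3, 10]]), cells=["a", "b"])
        expected = 1.0 - 14.0 / math.sqrt(250.0)
        assert correlation_distance(m).loc["a", "b"] == pytest.approx(expected)

    def test_symmetry_zero_diagonal_and_range(self):
        rng = np.random.default_rng(0)
        m = log2_matrix(rng.gamma(3, 2, (50, 6)))
        d = correlation_distance(m)
        arr = d.to_numpy()
        assert np.allclose(arr, arr.T)
        assert np.allclose(np.diag(arr), 0)
        assert (arr >= 0).all() and (arr <= 2).all()

    def test_zero_variance_cell_named_in_error(self):
        m = log2_matrix(np.column_stack([[1, 2, 3], [5, 5, 5]]), cells=["ok", "flat"])
        with pytest.raises(ValueError, match="flat"):
            correlation_distance(m)

    def test_probe_restriction(self):
        rng = np.random.default_rng(1)
        m = log2_matrix(rng.gamma(3, 2, (20, 4)))
        d_all = correlation_distance(m)
        d_sub = correlation_distance(m, m.probe_ids[:10])
        assert not np.allclose(d_all.to_numpy(), d_sub.to_numpy())


def random_distance_frame(rng, n):
    d = rng.uniform(0.05, 2.0, size=(n, n))
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    labels = [f"c{i:02d}" for i in range(n)]
    return pd.DataFrame(d, index=labels, columns=labels)


class TestAverageLinkage:
    def test_two_cells_single_merge(self):
        d = pd.DataFrame([[0, 0.3], [0.3, 0]], index=["a", "b"], columns=["a", "b"])
        dend = average_linkage(d)
        assert len(dend.merges) == 1
        assert dend.merges[0].height == pytest.approx(0.3)

    def test_matches_brute_force_oracle_small(self):
        rng = np.random.default_rng(99)
        for _ in range(30):
            n = rng.integers(3, 9)
            d = random_distance_frame(rng, int(n))
            dend = average_linkage(d)
            oracle = brute_force_upgma(d)
            members = dend.members()
            for merge, (oracle_set, oracle_h) in zip(dend.merges, oracle):
                assert frozenset(members[merge.new_node]) == oracle_set
                assert merge.height == pytest.approx(oracle_h, rel=1e-12)

    def test_matches_scipy_cophenetic_distances(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n = int(rng.integers(3, 9))
            d = random_distance_frame(rng, n)
            dend = average_linkage(d)
            Z_mine, leaves = dend.to_scipy_linkage()
            Z_scipy = linkage(squareform(d.to_numpy(), checks=False), method="average")
            coph_mine = cophenet(Z_mine)
            coph_scipy = cophenet(Z_scipy)
            assert np.allclose(coph_mine, coph_scipy, atol=1e-10)

    def test_heights_nondecreasing(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            d = random_distance_frame(rng, int(rng.integers(3, 12)))
            heights = [m.height for m in average_linkage(d).merges]
            assert all(b >= a - 1e-12 for a, b in zip(heights, heights[1:]))

    def test_deterministic_tie_break(self):
        # all pairwise distances equal: first merge must involve the two
        # lexicographically smallest ids
        labels = ["delta", "alpha", "charlie", "bravo"]
        d = pd.DataFrame(0.5, index=labels, columns=labels)
        np.fill_diagonal(d.to_numpy(), 0)
        d = pd.DataFrame(np.where(np.eye(4, dtype=bool), 0.0, 0.5), index=labels, columns=labels)
        dend = average_linkage(d)
        first = dend.merges[0]
        assert {first.node_a, first.node_b} == {"alpha", "bravo"}

    def test_single_cell_is_error(self):
        d = pd.DataFrame([[0.0]], index=["a"], columns=["a"])
        with pytest.raises(ValueError):
            average_linkage(d)


@pytest.fixture(scope="module")
def dend():
    rng = np.random.default_rng(3)
    return average_linkage(random_distance_frame(rng, 8))


class TestCutTree:
    def test_k_equals_n_gives_singletons(self, dend):
        asg = cut_tree(dend, 8)
        assert sorted(asg.sizes().values()) == [1] * 8

    def test_k_one_gives_single_cluster(self, dend):
        asg = cut_tree(dend, 1)
        assert asg.sizes() == {1: 8}

    def test_refinement_across_k(self, dend):
        for k in range(1, 8):
            coarse = cut_tree(dend, k)
            fine = cut_tree(dend, k + 1)
            for label in range(1, k + 2):
                cells = set(fine.cells_in(label))
                parents = {coarse.labels[c] for c in cells}
                assert len(parents) == 1

    def test_labels_ordered_by_decreasing_size(self, dend):
        asg = cut_tree(dend, 3)
        sizes = [len(asg.cells_in(l)) for l in range(1, 4)]
        assert sizes == sorted(sizes, reverse=True)

    def test_k_out_of_range(self, dend):
        with pytest.raises(ValueError):
            cut_tree(dend, 0)
        with pytest.raises(ValueError):
            cut_tree(dend, 9)


class TestNewick:
    def test_parses_and_is_ultrametric(self):
        dendropy = pytest.importorskip("dendropy")
        rng = np.random.default_rng(11)
        d = random_distance_frame(rng, 6)
        dend = average_linkage(d)
        tree = dendropy.Tree.get(data=dend.to_newick(), schema="newick")
        taxa = {t.label for t in tree.taxon_namespace}
        assert taxa == set(d.index)
        # ultrametric: every root-to-leaf path length equals half the root height
        root_height = dend.merges[-1].height / 2.0
        depths = [leaf.distance_from_root() for leaf in tree.leaf_node_iter()]
        assert np.allclose(depths, root_height, atol=1e-9)


class TestClusterEnriched:
    def _planted(self):
        cfg = SimConfig(
            n_probes=2000,
            n_markers_per_type=10,
            n_pan_markers=10,
            n_module_genes=0,
            noise_sd_mean=0.06,
            noise_sd_sd=0.0,
            noise_sd_clip=(0.05, 0.06),
            seed=2,
        )
        return cfg, *generate_dataset(cfg)

    def test_planted_markers_recovered_with_score_one(self):
        cfg, m, anns, truth, pmap = self._planted()
        from rgcmark.cluster import ClusterAssignment

        labels = {c: truth.cell_types[c] for c in m.cell_ids}
        asg = ClusterAssignment(labels=labels, k=4)
        for t in (1, 2, 4):  # multi-cell planted types
            table = cluster_enriched_genes(m, asg, t, 6.0)
            got = set(table["probe_id"])
            assert set(truth.marker_probes(t)) <= got
            scores = table.set_index("probe_id").loc[truth.marker_probes(t), "score"]
            assert np.allclose(scores, 1.0)
            assert not any(truth.probe_roles[p] == "noise" for p in got)

    def test_vacuous_thresholds_list_every_detected_gene(self):
        cfg, m, anns, truth, pmap = self._planted()
        from rgcmark.cluster import ClusterAssignment

        asg = ClusterAssignment({c: truth.cell_types[c] for c in m.cell_ids}, k=4)
        table = cluster_enriched_genes(m, asg, 1, 6.0, min_in_prev=0.0, max_out_prev=1.0)
        assert len(table) == m.shape[0]

    def test_ubiquitous_gene_fails_default_thresholds(self):
        m = log2_matrix([[10.0] * 4, [10, 10, 2, 2]], cells=["a", "b", "c", "d"])
        from rgcmark.cluster import ClusterAssignment

        asg = ClusterAssignment({"a": 1, "b": 1, "c": 2, "d": 2}, k=2)
        table = cluster_enriched_genes(m, asg, 1, 6.0)
        assert list(table["probe_id"]) == ["p2"]

    def test_empty_cluster_is_error(self):
        m = log2_matrix([[10.0, 2.0]], cells=["a", "b"])
        from rgcmark.cluster import ClusterAssignment

        asg = ClusterAssignment({"a": 1, "b": 2}, k=2)
        with pytest.raises(ValueError):
            cluster_enriched_genes(m, asg, 3, 6.0)
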