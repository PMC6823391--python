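import numpy as np
import pandas as pd
import pytest

from rgcmark import (
    ProbeAnnotation,
    SimConfig,
    class_restricted_genes,
    coexpression_overlap,
    cross_dataset_intersection,
    generate_dataset,
    panel_query,
    prevalence_markers,
    seed_correlates,
)
from rgcmark.markers import CorrelateList

from conftest import log2_matrix


def clist(seed, entries, threshold=0.5):
    frame = pd.DataFrame(
        [(g, f"probe_{g}", r) for g, r in entries], columns=["gene", "probe_id", "r"]
    )
    return CorrelateList(seed, threshold, frame)


class TestPrevalenceMarkers:
    def test_majority_at_seven_of_fourteen(self):
        cells = [f"c{i}" for i in range(14)]
        vals = [[10.0] * 7 + [2.0] * 7]
        m = log2_matrix(vals, cells=cells)
        report = prevalence_markers(m, cells, 6.0, 7)
        row = report.iloc[0]
        assert row["category"] == "majority_subset"
        assert row["prevalence"] == pytest.approx(0.5)
        assert row["n_cells_detected"] == 7

    def test_undetected_gene_absent_from_report(self):
        m = log2_matrix([[2.0, 2.0], [10.0, 2.0]], cells=["a", "b"])
        report = prevalence_markers(m, ["a", "b"], 6.0, 2)
        assert list(report["probe_id"]) == ["p2"]
        assert report.iloc[0]["category"] == "restricted_subset"

    def test_min_cells_exceeding_cells_is_error(self):
        m = log2_matrix([[10.0, 10.0]], cells=["a", "b"])
        with pytest.raises(ValueError, match="min_cells"):
            prevalence_markers(m, ["a", "b"], 6.0, 3)

    def test_planted_pan_markers_majority_with_prevalence_one(self, default_dataset):
        _, m, anns, truth, pmap = default_dataset
        target = [a.cell_id for a in anns if a.group == "target"]
        report = prevalence_markers(m, target, 6.0, 7, pmap).set_index("probe_id")
        pan = truth.probes_with_role("pan_marker")
        assert (report.loc[pan, "category"] == "majority_subset").all()
        assert np.allclose(report.loc[pan, "prevalence"], 1.0)


class TestSeedCorrelates:
    def test_duplicated_seed_probe_ranks_first_with_r_one(self):
        rng = np.random.default_rng(4)
        base = rng.normal(7, 2, 10)
        vals = np.vstack([base, base, rng.normal(7, 2, 10)])
        m = log2_matrix(np.clip(vals, 0, None), probes=["seed", "twin", "other"])
        out = seed_correlates(m, "seed", 0.0)
        assert out.entries.iloc[0]["gene"] == "twin"
        assert out.entries.iloc[0]["r"] == pytest.approx(1.0)
        assert "seed" not in set(out.entries["gene"])

    def test_threshold_above_one_gives_empty_list(self):
        rng = np.random.default_rng(4)
        m = log2_matrix(np.clip(rng.normal(7, 2, (5, 8)), 0, None))
        assert seed_correlates(m, "p1", 1.0 + 1e-9).entries.empty

    def test_threshold_nesting(self):
        rng = np.random.default_rng(9)
        m = log2_matrix(np.clip(rng.normal(7, 2, (40, 12)), 0, None))
        lo = set(seed_correlates(m, "p1", 0.1).genes())
        hi = set(seed_correlates(m, "p1", 0.5).genes())
        assert hi <= lo

    def test_zero_variance_seed_is_error(self):
        m = log2_matrix([[5.0, 5.0, 5.0], [1, 2, 3]])
        with pytest.raises(ValueError, match="p1"):
            seed_correlates(m, "p1", 0.5)

    def test_unmapped_seed_is_error(self):
        m = log2_matrix([[1, 2, 3]])
        with pytest.raises(KeyError, match="Opn4"):
            seed_correlates(m, "Opn4", 0.5)

    def test_planted_module_recovered_on_filtered_substrate(self, default_dataset, groups_of):
        from rgcmark import dual_sd_filter, per_group_sd

        cfg, m, anns, truth, pmap = default_dataset
        retained = dual_sd_filter(per_group_sd(m, groups_of), 2.5).retained_probe_ids
        out = seed_correlates(m.subset(probes=retained), "Modseed", 0.53, None, pmap)
        module_genes = {
            pmap.symbol_for(p)
            for p in truth.module_probes()
            if p != truth.module_seed_probe
        }
        got = set(out.genes())
        assert module_genes <= got
        probe_of = dict(zip(out.entries["gene"], out.entries["probe_id"]))
        noise_fp = [g for g in got if truth.probe_roles[probe_of[g]] == "noise"]
        assert noise_fp == []


class TestCrossDatasetIntersection:
    def test_disjoint_lists_empty(self):
        out = cross_dataset_intersection(clist("s", [("A", 0.9)]), clist("s", [("B", 0.8)]))
        assert out.empty

    def test_identical_lists_full(self):
        a = clist("s", [("A", 0.9), ("B", 0.6)])
        out = cross_dataset_intersection(a, a)
        assert list(out["gene"]) == ["A", "B"]

    def test_enumeration_example(self):
        a = clist("s", [("A", 0.9), ("B", 0.6)])
        b = clist("s", [("B", 0.7), ("C", 0.8)])
        out = cross_dataset_intersection(a, b)
        assert list(out["gene"]) == ["B"]
        assert out.iloc[0]["r_a"] == pytest.approx(0.6)
        assert out.iloc[0]["r_b"] == pytest.approx(0.7)

    def test_commutative_up_to_column_order(self):
        a = clist("s", [("A", 0.9), ("B", 0.6)])
        b = clist("s", [("B", 0.7), ("A", 0.8)])
        ab = cross_dataset_intersection(a, b)
        ba = cross_dataset_intersection(b, a)
        assert list(ab["gene"]) == list(ba["gene"])
        assert np.allclose(ab["r_a"], ba["r_b"])

    def test_different_seeds_warn(self):
        with pytest.warns(UserWarning, match="different seeds"):
            cross_dataset_intersection(
                clist("Pvalb", [("A", 0.9)]), clist("Opn4", [("A", 0.8)])
            )


class TestClassRestricted:
    def _annotated(self):
        cfg = SimConfig(
            n_probes=2000,
            n_markers_per_type=10,
            n_pan_markers=5,
            n_module_genes=0,
            noise_sd_mean=0.06,
            noise_sd_sd=0.0,
            noise_sd_clip=(0.05, 0.06),
            type_class_labels=("ONOFF_DS", "ON_alpha", "SbC", None),
            seed=6,
        )
        return cfg, *generate_dataset(cfg)

    def test_planted_type_markers_returned_for_its_class(self):
        cfg, m, anns, truth, pmap = self._annotated()
        table = class_restricted_genes(m, anns, {"ONOFF_DS"}, 6.0, probe_map=pmap)
        assert set(truth.marker_probes(1)) <= set(table["probe_id"])
        assert table["category"].eq("class_restricted").all()

    def test_class_set_covering_all_labelled_cells_is_error(self):
        cfg, m, anns, truth, pmap = self._annotated()
        with pytest.raises(ValueError, match="outside"):
            class_restricted_genes(m, anns, {"ONOFF_DS", "ON_alpha", "SbC"}, 6.0)

    def test_empty_class_set_is_error(self):
        cfg, m, anns, truth, pmap = self._annotated()
        with pytest.raises(ValueError):
            class_restricted_genes(m, anns, set(), 6.0)

    def test_ubiquitous_gene_excluded_under_defaults(self):
        cfg, m, anns, truth, pmap = self._annotated()
        table = class_restricted_genes(m, anns, {"ONOFF_DS"}, 0.0)
        assert table.empty  # at tau 0 everything is detected everywhere


class TestCoexpressionOverlap:
    def test_toy_partition(self):
        cells = [f"c{i}" for i in range(1, 7)]
        vals = [
            [10, 10, 10, 2, 2, 2],  # a on in c1..c3
            [2, 2, 10, 10, 2, 2],  # b on in c3, c4
        ]
        m = log2_matrix(vals, probes=["a", "b"], cells=cells)
        out = coexpression_overlap(m, "a", "b", cells, 6.0)
        assert (out["n_both"], out["n_a_only"], out["n_b_only"], out["n_neither"]) == (
            1, 2, 1, 2,
        )
        assert out["cells_both"] == ["c3"]

    def test_identity_gene_has_no_exclusive_cells(self):
        m = log2_matrix([[10, 2, 10]], probes=["a"], cells=["x", "y", "z"])
        out = coexpression_overlap(m, "a", "a", ["x", "y", "z"], 6.0)
        assert out["n_a_only"] == out["n_b_only"] == 0
        assert out["n_both"] == 2 and out["n_neither"] == 1

    def test_partition_sums_to_cell_count(self):
        rng = np.random.default_rng(12)
        m = log2_matrix(np.clip(rng.normal(6, 2, (2, 9)), 0, None), probes=["a", "b"])
        out = coexpression_overlap(m, "a", "b", m.cell_ids, 6.0)
        assert out["n_both"] + out["n_a_only"] + out["n_b_only"] + out["n_neither"] == 9

    def test_unmapped_gene_is_error(self):
        m = log2_matrix([[1, 2]], probes=["a"])
        with pytest.raises(KeyError, match="zzz"):
            coexpression_overlap(m, "a", "zzz", m.cell_ids, 6.0)


class TestPanelQuery:
    def test_counts_and_order(self):
        m = log2_matrix(
            [[10, 2, 2], [10, 10, 2], [2, 2, 2]],
            probes=["scn5a", "kcnb1", "silent"],
            cells=["c1", "c2", "c3"],
        )
        report, grid, unmapped = panel_query(
            m, ["kcnb1", "scn5a", "ghost"], m.cell_ids, 6.0
        )
        assert list(report["gene"]) == ["kcnb1", "scn5a"]
        assert unmapped == ["ghost"]
        assert report.set_index("gene").loc["scn5a", "n_cells_detected"] == 1
        assert list(grid.index) == ["kcnb1", "scn5a"]

    def test_empty_cells_is_error(self):
        m = log2_matrix([[1, 2]], probes=["a"])
        with pytest.raises(ValueError):
            panel_query(m, ["a"], [], 6.0)

    def test_entirely_unmapped_panel_is_error(self):
        m = log2_matrix([[1, 2]], probes=["a"])
        with pytest.raises(ValueError, match="no panel gene"):
            panel_query(m, ["x", "y"], m.cell_ids, 6.0)
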