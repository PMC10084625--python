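from statistics import mean

import pytest

from markerclust.detect import (
    MarkerStats,
    MclParams,
    TaxonCall,
    Thresholds,
    build_marker_graph,
    build_taxon_graph,
    call_taxa,
    compute_marker_stats,
    detect_taxa,
    filter_by_length,
    reject_inferior_taxa,
)
from markerclust.io_model import AlignmentRecord
from markerclust.mcl_core import Clustering
from markerclust.simulate import (
    ambiguous_cluster_scenario,
    ambiguous_trio_scenario,
    detection_floor_scenario,
    inferior_marker_scenario,
)

from conftest import records_for


def rec(read, marker, taxon=None, length=100, identity=1.0, mapq=42):
    return AlignmentRecord(
        read_id=read,
        marker_id=marker,
        taxon_id=taxon or marker.split("_")[0],
        aln_length=length,
        identity=identity,
        coverage_fraction=0.1,
        mapq=mapq,
    )


class TestFilterByLength:
    def test_boundary_at_60(self):
        records = [rec(f"r{n}", "t_m0", length=n) for n in (59, 60, 61)]
        assert [a.aln_length for a in filter_by_length(records)] == [60, 61]

    def test_empty_input(self):
        assert filter_by_length([]) == []

    def test_identity_case(self):
        records = [rec(f"r{n}", "t_m0", length=n) for n in (60, 80, 100)]
        assert filter_by_length(records) == records


class TestBuildMarkerGraph:
    def test_shared_reads_count(self):
        records = [
            rec("r1", "t_m1"), rec("r1", "t_m2"),
            rec("r2", "t_m1"), rec("r2", "t_m2"),
        ]
        g = build_marker_graph(records)
        assert g.weight("t_m1", "t_m2") == 2

    def test_no_sharing_no_edges(self):
        g = build_marker_graph([rec("r1", "t_m1"), rec("r2", "t_m2")])
        assert g.edges() == []
        assert set(g.nodes) == {"t_m1", "t_m2"}

    def test_triangle_from_one_read(self):
        g = build_marker_graph([rec("r1", "t_m1"), rec("r1", "t_m2"), rec("r1", "t_m3")])
        assert {(u, v) for u, v, _ in g.edges()} == {
            ("t_m1", "t_m2"), ("t_m1", "t_m3"), ("t_m2", "t_m3")
        }
        assert all(w == 1 for _, _, w in g.edges())


def stats(marker, taxon, identity, cluster, n_reads=2):
    return MarkerStats(marker, taxon, identity, n_reads, cluster)


class TestRejectInferiorTaxa:
    def test_half_inferior_is_rejected(self):
        # four markers of taxX in cluster 0 with rival markers dragging two below average
        marker_stats = [
            stats("x1", "taxX", 0.90, 0), stats("y1", "taxY", 1.0, 0),
            stats("x2", "taxX", 0.90, 1), stats("y2", "taxY", 1.0, 1),
            stats("x3", "taxX", 1.0, 2), stats("x4", "taxX", 1.0, 3),
        ]
        survivors = reject_inferior_taxa(marker_stats)
        assert "taxX" not in survivors
        assert "taxY" in survivors

    def test_singleton_cluster_never_inferior(self):
        survivors = reject_inferior_taxa([stats("x1", "taxX", 0.5, 0)])
        assert survivors == {"taxX"}

    def test_quarter_inferior_survives(self):
        marker_stats = [
            stats("x1", "taxX", 0.90, 0), stats("y1", "taxY", 1.0, 0),
            stats("x2", "taxX", 1.0, 1), stats("x3", "taxX", 1.0, 2),
            stats("x4", "taxX", 1.0, 3),
        ]
        assert "taxX" in reject_inferior_taxa(marker_stats)

    def test_fraction_boundary_is_inclusive(self):
        marker_stats = [
            stats("x1", "taxX", 0.9, 0), stats("y1", "taxY", 1.0, 0),
            stats("x2", "taxX", 1.0, 1),
        ]
        assert "taxX" not in reject_inferior_taxa(marker_stats, 0.5)
        assert "taxX" in reject_inferior_taxa(marker_stats, 0.51)


class TestBuildTaxonGraph:
    def test_single_shared_read(self):
        records = [rec("r1", "a_m1"), rec("r1", "b_m1")]
        g = build_taxon_graph(records, {"a", "b"})
        assert g.weight("a", "b") == 1

    def test_no_multiply_aligned_reads(self):
        records = [rec("r1", "a_m1"), rec("r2", "b_m1")]
        g = build_taxon_graph(records, {"a", "b"})
        assert g.edges() == []

    def test_triangle_of_shared_reads(self):
        records = [
            rec(f"r{i}", f"{t}_m1") for i in range(5) for t in ("a", "b", "c")
        ]
        g = build_taxon_graph(records, {"a", "b", "c"})
        assert all(w == 5 for _, _, w in g.edges())
        assert len(g.edges()) == 3

    def test_excluded_taxa_absent(self):
        records = [rec("r1", "a_m1"), rec("r1", "b_m1")]
        g = build_taxon_graph(records, {"a"})
        assert g.nodes == ["a"]


class TestCallTaxa:
    def test_unambiguous_call(self):
        records = [rec("r1", "t1_m1", identity=0.98), rec("r2", "t1_m2", identity=0.98)]
        calls = call_taxa(Clustering([{"t1"}]), records)
        assert len(calls) == 1
        assert calls[0].call_type == "unambiguous"
        assert calls[0].label == "t1"

    def test_strong_ambiguous_pair(self):
        # cluster {t1, t2}: union 5 markers / 10 reads at identity 0.93
        records = []
        for i in range(10):
            records.append(rec(f"r{i}", f"t1_m{i % 3}", identity=0.93))
            records.append(rec(f"r{i}", f"t2_m{i % 2}", identity=0.93))
        calls = call_taxa(Clustering([{"t1", "t2"}]), records)
        assert [c.label for c in calls] == ["?t1,t2"]
        assert calls[0].call_type == "strong_ambiguous"
        assert calls[0].n_markers == 5
        assert calls[0].n_reads == 10

    def test_marker_floor_unmet_drops_cluster(self):
        records = []
        for i in range(20):
            records.append(rec(f"r{i}", f"t1_m{i % 2}", identity=0.93))
            records.append(rec(f"r{i}", "t2_m0", identity=0.93))
        calls = call_taxa(Clustering([{"t1", "t2"}]), records)
        assert calls == []

    def test_below_floor_single_read(self):
        calls = call_taxa(Clustering([{"t1"}]), [rec("r1", "t1_m1", identity=1.0)])
        assert calls == []

    def test_ambiguous_mates_of_unambiguous_are_rejected(self):
        records = [
            rec("r1", "t1_m1", identity=1.0),
            rec("r2", "t1_m2", identity=1.0),
            rec("r3", "t2_m1", identity=0.90),
        ]
        calls = call_taxa(Clustering([{"t1", "t2"}]), records)
        assert [c.label for c in calls] == ["t1"]

    def test_member_taxa_disjoint_across_calls(self):
        records = [
            rec("r1", "t1_m1"), rec("r2", "t1_m2"),
            rec("r3", "t2_m1"), rec("r4", "t2_m2"),
        ]
        calls = call_taxa(Clustering([{"t1"}, {"t2"}]), records)
        taxa = [t for c in calls for t in c.member_taxa]
        assert len(taxa) == len(set(taxa)) == 2

    def test_raising_thresholds_never_adds_calls(self):
        records = []
        for i in range(10):
            records.append(rec(f"r{i}", f"t1_m{i % 4}", identity=0.95))
        clustering = Clustering([{"t1"}])
        base = Thresholds()
        n_base = len(call_taxa(clustering, records, base))
        for override in (
            {"unambiguous_min_identity": 0.99},
            {"unambiguous_min_reads": 20},
            {"unambiguous_min_markers": 8},
            {"strong_ambiguous_min_markers": 8},
            {"strong_ambiguous_min_reads": 20},
        ):
            raised = Thresholds(**override)
            assert len(call_taxa(clustering, records, raised)) <= n_base


class TestThresholds:
    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            Thresholds(min_aln_length=0)
        with pytest.raises(ValueError):
            Thresholds(unambiguous_min_identity=1.5)
        with pytest.raises(ValueError):
            Thresholds(inferior_marker_fraction=0.0)


class TestEndToEnd:
    def test_detection_floor(self, floor_alignments):
        calls = detect_taxa(floor_alignments)
        assert len(calls) == 1
        assert calls[0].call_type == "unambiguous"
        assert calls[0].member_taxa == {"taxA"}

    def test_one_read_short_of_floor(self, tmp_path):
        _, records = records_for(detection_floor_scenario(n_reads=1), tmp_path)
        assert detect_taxa(records) == []

    def test_one_marker_short_of_floor(self, tmp_path):
        _, records = records_for(
            detection_floor_scenario(n_reads=2, n_markers=1), tmp_path
        )
        assert detect_taxa(records) == []

    def test_inferior_marker_rejection_pipeline(self, tmp_path):
        for k, expect_rejected in [(1, False), (2, True), (4, True)]:
            _, records = records_for(
                inferior_marker_scenario(n_inferior=k), tmp_path, prefix=f"inf{k}"
            )
            kept = filter_by_length(records)
            clusters = MclParams().run(build_marker_graph(kept))
            survivors = reject_inferior_taxa(compute_marker_stats(kept, clusters))
            assert ("taxT" not in survivors) is expect_rejected

    def test_strong_ambiguous_end_to_end(self, tmp_path):
        _, records = records_for(ambiguous_cluster_scenario(), tmp_path)
        calls = detect_taxa(records)
        assert [c.label for c in calls] == ["?taxP"]

    def test_joined_label_sorted_lexicographically(self, tmp_path):
        _, records = records_for(
            ambiguous_trio_scenario(taxa=("taxC", "taxA", "taxB")), tmp_path
        )
        calls = detect_taxa(records)
        assert [c.label for c in calls] == ["?taxA,taxB,taxC"]

    def test_uniquely_aligned_reads_reduce_to_thresholding(self, tmp_path):
        # two independent taxa, each meeting the unambiguous floor
        records = [
            rec("r1", "a_m1"), rec("r2", "a_m2"),
            rec("r3", "b_m1"), rec("r4", "b_m2"),
            rec("r5", "c_m1"),  # below floor
        ]
        calls = detect_taxa(records)
        assert sorted(c.label for c in calls) == ["a", "b"]
        assert all(c.call_type == "unambiguous" for c in calls)

    def test_empty_input(self):
        assert detect_taxa([]) == []

    def test_identity_average_matches_mean(self, tmp_path):
        _, records = records_for(ambiguous_cluster_scenario(identity=0.93), tmp_path)
        calls = detect_taxa(records)
        assert calls[0].identity_average == pytest.approx(
            mean(r.identity for r in records)
        )
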