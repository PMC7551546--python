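"""Homolog search filters, cluster construction, special cases, event detection."""

import numpy as np
import pytest

from conftest import make_orf, random_protein
from mirrorphage.clustering import (
    build_clusters,
    build_paralog_clusters,
    deduplicate_contigs,
    detect_duplications,
    filter_contigs,
    filter_imported_hits,
    merge_split_reference,
    search_homologs,
    split_cluster_by_region,
)
from mirrorphage.errors import ConfigError, DataError, ParseError
from mirrorphage.io import read_hits_table, write_hits_table
from mirrorphage.records import HitRecord, HomologCluster, MultipleAlignment


@pytest.fixture(scope="module")
def query_and_fragments():
    rng = np.random.default_rng(77)
    query = make_orf("ref", 1, random_protein(100, rng))
    subjects = [
        make_orf("c1", 1, query.sequence),          # 100% coverage
        make_orf("c2", 1, query.sequence[:85]),     # 85%
        make_orf("c3", 1, query.sequence[20:80]),   # 60%
        make_orf("c4", 1, query.sequence[:97]),     # 97%
        make_orf("c5", 1, random_protein(200, rng)),  # unrelated
    ]
    return query, subjects


class TestSearchHomologs:
    def test_self_hit_has_full_coverage_at_every_threshold(self, query_and_fragments):
        query, subjects = query_and_fragments
        for threshold in (0.5, 0.8, 0.95):
            hits = search_homologs([query], [query], threshold, 1e-3)
            assert len(hits) == 1
            assert hits[0].query_coverage == 1.0

    def test_partial_fragment_passes_only_lenient_threshold(self, query_and_fragments):
        query, subjects = query_and_fragments
        frag = subjects[2]  # covers 60% of the query
        kept = {
            t: [h.subject_id for h in search_homologs([query], [frag], t, 1e-3)]
            for t in (0.5, 0.8, 0.95)
        }
        assert kept[0.5] == [frag.orf_id]
        assert kept[0.8] == [] and kept[0.95] == []

    def test_unrelated_random_sequences_are_not_significant(self):
        rng = np.random.default_rng(123)
        a = make_orf("r", 1, random_protein(200, rng))
        b = make_orf("x", 1, random_protein(200, rng))
        assert search_homologs([a], [b], 0.5, 1e-3) == []

    def test_coverage_threshold_nesting(self, query_and_fragments):
        query, subjects = query_and_fragments
        sets = {
            t: {h.subject_id for h in search_homologs([query], subjects, t, 1e-3)}
            for t in (0.5, 0.8, 0.95)
        }
        assert sets[0.95] <= sets[0.8] <= sets[0.5]
        assert sets[0.95] == {"c1_1", "c4_1"}
        assert sets[0.8] == {"c1_1", "c2_1", "c4_1"}
        assert sets[0.5] == {"c1_1", "c2_1", "c3_1", "c4_1"}

    def test_empty_reference_set_rejected(self, query_and_fragments):
        with pytest.raises(ConfigError):
            search_homologs([], query_and_fragments[1], 0.8, 1e-3)


def hit(q, s, cov=1.0):
    return HitRecord(q, s, score=500.0, significance=1e-30, query_coverage=cov)


class TestBuildClusters:
    def setup_method(self):
        rng = np.random.default_rng(5)
        self.refs = [make_orf("ref", i, random_protein(50, rng)) for i in (1, 2, 3)]
        self.orfs = [make_orf(f"c{i}", 1, random_protein(50, rng)) for i in range(5)]
        self.cats = {r.orf_id: "Replication" for r in self.refs}

    def test_single_hit_orfs_partition_into_their_clusters(self):
        hits = [
            hit("ref_1", "c0_1"), hit("ref_1", "c1_1"),
            hit("ref_2", "c2_1"),
            hit("ref_3", "c3_1"), hit("ref_3", "c4_1"),
        ]
        clusters = build_clusters(hits, self.orfs, self.refs, self.cats)
        assert len(clusters) == 3
        sizes = {c.cluster_id: c.member_ids for c in clusters}
        assert sizes["ref_1"] == {"ref_1", "c0_1", "c1_1"}
        assert sizes["ref_2"] == {"ref_2", "c2_1"}
        assert sizes["ref_3"] == {"ref_3", "c3_1", "c4_1"}

    def test_orf_hitting_two_references_joins_both_clusters(self):
        hits = [hit("ref_1", "c0_1"), hit("ref_2", "c0_1")]
        clusters = build_clusters(hits, self.orfs, self.refs, self.cats)
        by_id = {c.cluster_id: c for c in clusters}
        assert "c0_1" in by_id["ref_1"].member_ids
        assert "c0_1" in by_id["ref_2"].member_ids

    def test_reference_with_no_hits_forms_singleton_cluster(self):
        clusters = build_clusters([], self.orfs, self.refs, self.cats)
        assert all(c.member_ids == {c.cluster_id} for c in clusters)
        assert len(clusters) == len(self.refs)

    def test_missing_category_is_a_configuration_error(self):
        with pytest.raises(ConfigError):
            build_clusters([], self.orfs, self.refs, {"ref_1": "Capsid"})


class TestParalogClusters:
    def setup_method(self):
        rng = np.random.default_rng(8)
        self.orfs = [make_orf(c, 1, random_protein(40, rng)) for c in "xyz"]

    def test_three_cluster_rule(self):
        hits = [hit("a", "x_1"), hit("b", "y_1"), hit("a", "z_1"), hit("b", "z_1")]
        a, b, ab = build_paralog_clusters(hits, "a", "b", self.orfs)
        assert a.member_ids == {"x_1"}
        assert b.member_ids == {"y_1"}
        assert ab.member_ids == {"x_1", "y_1", "z_1"}

    def test_no_hits_to_second_reference(self):
        hits = [hit("a", "x_1"), hit("a", "y_1")]
        a, b, ab = build_paralog_clusters(hits, "a", "b", self.orfs)
        assert b.member_ids == set()
        assert ab.member_ids == a.member_ids

    def test_union_size_identity(self):
        hits = [hit("a", "x_1"), hit("b", "y_1"), hit("a", "z_1"), hit("b", "z_1")]
        a, b, ab = build_paralog_clusters(hits, "a", "b", self.orfs)
        both = a.member_ids | b.member_ids
        assert len(ab) == len(a) + len(b) + len(ab.member_ids - both)


class TestMergeAndSplit:
    def test_merge_unions_members(self):
        rng = np.random.default_rng(1)
        x, y, z = (make_orf(c, 1, random_protein(30, rng)) for c in "xyz")
        a = HomologCluster("ra", ("ra",), [x, y], 0.8, "Other")
        b = HomologCluster("rb", ("rb",), [y, z], 0.8, "Other")
        merged = merge_split_reference(a, b)
        assert merged.member_ids == {"x_1", "y_1", "z_1"}
        assert merged.reference_orf_ids == ("ra", "rb")

    def test_merge_with_empty_cluster_is_identity(self):
        rng = np.random.default_rng(2)
        x = make_orf("x", 1, random_protein(30, rng))
        a = HomologCluster("ra", ("ra",), [x], 0.8, "Other")
        b = HomologCluster("rb", ("rb",), [], 0.8, "Other")
        assert merge_split_reference(a, b).member_ids == a.member_ids

    def test_split_gapless_alignment_and_concatenation_inverse(self):
        aln = MultipleAlignment(
            [("a_1", "a", "ACDEFGHIKL"), ("b_1", "b", "ACDEFGHIKM")]
        )
        left, right = split_cluster_by_region(aln, 5)
        assert len(left) == len(right) == 2
        rebuilt = [l[2] + r[2] for l, r in zip(left.rows, right.rows)]
        assert rebuilt == [row[2] for row in aln.rows]

    def test_row_all_gap_in_second_half_is_dropped_there(self):
        aln = MultipleAlignment(
            [("a_1", "a", "ACDEFGHIKL"), ("b_1", "b", "ACDEF-----")]
        )
        left, right = split_cluster_by_region(aln, 5)
        assert left.orf_ids() == ["a_1", "b_1"]
        assert right.orf_ids() == ["a_1"]

    def test_breakpoint_out_of_range(self):
        aln = MultipleAlignment([("a_1", "a", "ACDEF")])
        with pytest.raises(ConfigError):
            split_cluster_by_region(aln, 5)


class TestContigFilter:
    def build(self, contributions):
        # contig i contributes one ORF to each of its first k clusters
        rng = np.random.default_rng(3)
        clusters = [
            HomologCluster(f"r{k}", (f"r{k}",), [], 0.8, "Other") for k in range(3)
        ]
        for i, k in enumerate(contributions):
            for j in range(k):
                clusters[j].members.append(
                    make_orf(f"c{i}", j + 1, random_protein(20, rng))
                )
        return [
            HomologCluster(c.cluster_id, c.reference_orf_ids, c.members, 0.8, "Other")
            for c in clusters
        ]

    def test_threshold_count(self):
        retained, _ = filter_contigs(self.build([3, 1, 2, 0]), min_orfs=2)
        assert retained == {"c0", "c2"}

    def test_min_one_keeps_every_clustered_contig(self):
        retained, _ = filter_contigs(self.build([3, 1, 2, 0]), min_orfs=1)
        assert retained == {"c0", "c1", "c2"}

    def test_idempotent_and_never_grows(self):
        clusters = self.build([3, 1, 2, 0])
        _, once = filter_contigs(clusters, 2)
        _, twice = filter_contigs(once, 2)
        for before, after1, after2 in zip(clusters, once, twice):
            assert len(after1) <= len(before)
            assert after1.member_ids == after2.member_ids

    def test_truncated_dataset_filter_matches_truth_windows(self):
        from mirrorphage.simulate import SimulationConfig, simulate

        cfg = SimulationConfig(
            n_genomes=15, n_core_families=40, n_accessory_families=0,
            family_lengths=[30] * 40, truncation=(0.05, 0.05),
            duplications=(), split_gene=None, seed=21,
        )
        ds = simulate(cfg)
        # build clusters from ground truth membership and recheck the filter
        clusters = [
            HomologCluster(
                f"fam{f}", (f"fam{f}",),
                [
                    ds.orfs(g)[pos]
                    for g in ds.genome_ids
                    for pos, fam in enumerate(ds.gene_slots[g]) if fam == f
                ],
                0.8, "Other",
            )
            for f in range(40)
        ]
        retained, _ = filter_contigs(clusters, min_orfs=2)
        expected = {
            g for g in ds.genome_ids
            if ds.truth.windows[g][1] - ds.truth.windows[g][0] >= 2
        }
        assert retained == expected


class TestDuplications:
    def test_contig_with_two_members_yields_one_event(self):
        rng = np.random.default_rng(4)
        members = [
            make_orf("c1", 3, random_protein(20, rng)),
            make_orf("c1", 7, random_protein(20, rng)),
            make_orf("c2", 1, random_protein(20, rng)),
        ]
        events = detect_duplications(
            [HomologCluster("r1", ("r1",), members, 0.8, "Other")]
        )
        assert len(events) == 1
        assert events[0].contig_id == "c1"
        assert events[0].orf_ids == ("c1_3", "c1_7")

    def test_no_repeat_contigs_means_no_events(self):
        rng = np.random.default_rng(4)
        members = [make_orf(f"c{i}", 1, random_protein(20, rng)) for i in range(4)]
        assert detect_duplications(
            [HomologCluster("r1", ("r1",), members, 0.8, "Other")]
        ) == []


class TestHitsTableIO:
    def test_round_trip_and_filtering(self, tmp_path):
        hits = [
            HitRecord("ref_1", "c1_1", 200.0, 1e-10, 0.9, 5, 95),
            HitRecord("ref_1", "c2_1", 80.0, 1e-4, 0.6, 1, 60),
        ]
        path = tmp_path / "hits.tsv"
        write_hits_table(hits, {"ref_1": 100}, str(path))
        raw = read_hits_table(str(path))
        assert len(raw) == 2
        filtered = filter_imported_hits(raw, {"ref_1": 100}, 0.8, 1e-3)
        assert [h.subject_id for h in filtered] == ["c1_1"]
        lenient = filter_imported_hits(raw, {"ref_1": 100}, 0.5, 1e-3)
        assert [h.subject_id for h in lenient] == ["c1_1", "c2_1"]

    def test_malformed_line_names_the_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("q\ts\t1\t2\t3\n")
        with pytest.raises(ParseError, match="line|12"):
            read_hits_table(str(path))

    def test_unknown_query_rejected(self, tmp_path):
        hits = [HitRecord("refX_1", "c1_1", 200.0, 1e-10, 0.9, 1, 90)]
        path = tmp_path / "hits.tsv"
        write_hits_table(hits, {"refX_1": 100}, str(path))
        with pytest.raises(DataError):
            filter_imported_hits(read_hits_table(str(path)), {"ref_1": 100})


def test_deduplicate_contigs_drops_exact_copies():
    rng = np.random.default_rng(6)
    seq1, seq2 = random_protein(30, rng), random_protein(30, rng)
    orfs = [
        make_orf("a", 1, seq1), make_orf("a", 2, seq2),
        make_orf("b", 1, seq1), make_orf("b", 2, seq2),  # exact copy of a
        make_orf("c", 1, seq2),
    ]
    kept = deduplicate_contigs(orfs)
    assert {o.contig_id for o in kept} == {"a", "c"}
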