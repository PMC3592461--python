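"""Coding-exon filtering, clustering, segmentation, assignment and
positional classification."""

import numpy as np
import pytest

from lncexon.annotation import (
    assign_probes,
    build_coding_exon_mask,
    classify_cluster,
    cluster_lncrnas,
    filter_probes_against_coding,
    filter_short_lncrnas,
    segment_all,
    segment_probesets,
)
from lncexon.core import (
    Biotype,
    GenomicInterval,
    Parameters,
    PositionalCategory,
    Probe,
    ProbeStatus,
    TranscriptCluster,
    TranscriptModel,
    ValidationError,
)

from oracles import brute_force_components, label_segments, random_transcripts


def _lnc(tid, exons, strand="+", chrom="chr1"):
    return TranscriptModel(
        tid, tid,
        [GenomicInterval(chrom, s, e, strand) for s, e in exons],
        Biotype.LNCRNA,
    )


def _gene(tid, exons, strand="+", chrom="chr1"):
    return TranscriptModel(
        tid, tid,
        [GenomicInterval(chrom, s, e, strand) for s, e in exons],
        Biotype.CODING,
    )


def _probe(pid, start, end, strand="+", chrom="chr1"):
    n = end - start
    return Probe(pid, "A" * n, alignment=GenomicInterval(chrom, start, end, strand),
                 status=ProbeStatus.UNASSIGNED)


class TestLengthFilter:
    @pytest.mark.parametrize(
        "spliced, kept",
        [(200, False), (201, True), (199, False), (202, True)],
    )
    def test_200nt_boundary_is_strict(self, params, spliced, kept):
        t = _lnc("T", [(0, spliced)])
        assert (filter_short_lncrnas([t], params) == [t]) is kept

    def test_uses_spliced_not_genomic_length(self, params):
        # 150 + 100 bp exons over a 1000 bp span: spliced length 250
        t = _lnc("T", [(0, 150), (900, 1000)])
        assert filter_short_lncrnas([t], params) == [t]

    def test_empty_in_empty_out(self, params):
        assert filter_short_lncrnas([], params) == []


class TestCodingExonMask:
    def test_overlapping_exons_merge(self):
        mask = build_coding_exon_mask([_gene("G1", [(100, 200)]),
                                       _gene("G2", [(150, 250)])])
        starts, ends = mask.intervals[("chr1", "+")]
        assert starts.tolist() == [100] and ends.tolist() == [250]

    def test_strands_kept_separate(self):
        mask = build_coding_exon_mask([_gene("G1", [(100, 200)], "+"),
                                       _gene("G2", [(100, 200)], "-")])
        assert set(mask.intervals) == {("chr1", "+"), ("chr1", "-")}

    def test_union_over_sources_equals_concatenation(self):
        rng = np.random.default_rng(5)
        sources = [
            random_transcripts(rng, 15, Biotype.CODING, prefix=f"S{i}_")
            for i in range(3)
        ]
        separate = build_coding_exon_mask(*sources)
        merged = build_coding_exon_mask([t for s in sources for t in s])
        # base-by-base coverage must be identical
        for key in set(separate.intervals) | set(merged.intervals):
            for pos in range(0, 4000, 7):
                iv = GenomicInterval(key[0], pos, pos + 1, key[1])
                assert separate.overlaps(iv) == merged.overlaps(iv)

    def test_lncrna_input_rejected(self):
        with pytest.raises(ValidationError):
            build_coding_exon_mask([_lnc("T", [(0, 100)])])


class TestProbeCodingFilter:
    def test_one_bp_same_strand_overlap_excludes(self):
        mask = build_coding_exon_mask([_gene("G", [(100, 200)])])
        p = _probe("p", 195, 220)
        filter_probes_against_coding([p], mask)
        assert p.status == ProbeStatus.CODING_OVERLAP

    def test_opposite_strand_overlap_retained(self):
        mask = build_coding_exon_mask([_gene("G", [(100, 200)])])
        p = _probe("p", 195, 220, strand="-")
        filter_probes_against_coding([p], mask)
        assert p.status == ProbeStatus.UNASSIGNED

    def test_intronic_probe_retained(self):
        mask = build_coding_exon_mask([_gene("G", [(100, 200), (300, 400)])])
        p = _probe("p", 210, 235)
        filter_probes_against_coding([p], mask)
        assert p.status == ProbeStatus.UNASSIGNED

    def test_unplaced_probe_rejected(self):
        mask = build_coding_exon_mask([_gene("G", [(100, 200)])])
        with pytest.raises(ValidationError):
            filter_probes_against_coding([Probe("p", "A" * 25)], mask)


class TestClustering:
    def test_disjoint_transcripts_stay_separate(self):
        a, b = _lnc("A", [(0, 100)]), _lnc("B", [(200, 300)])
        assert len(cluster_lncrnas([a, b])) == 2

    def test_transitive_overlap_chains_merge(self):
        a = _lnc("A", [(0, 100)])
        b = _lnc("B", [(50, 150)])
        c = _lnc("C", [(140, 240)])
        (cluster,) = cluster_lncrnas([a, b, c])
        assert {t.transcript_id for t in cluster.members} == {"A", "B", "C"}

    def test_same_coordinates_opposite_strands_split(self):
        a = _lnc("A", [(0, 100)], "+")
        b = _lnc("B", [(0, 100)], "-")
        assert len(cluster_lncrnas([a, b])) == 2

    def test_span_overlap_without_exon_overlap_does_not_merge(self):
        # B sits inside A's intron: spans overlap, exons do not
        a = _lnc("A", [(0, 100), (500, 600)])
        b = _lnc("B", [(200, 300)])
        assert len(cluster_lncrnas([a, b])) == 2

    def test_cluster_ids_deterministic_under_input_order(self):
        rng = np.random.default_rng(8)
        transcripts = random_transcripts(rng, 30)
        ids1 = {
            c.cluster_id: frozenset(t.transcript_id for t in c.members)
            for c in cluster_lncrnas(transcripts)
        }
        ids2 = {
            c.cluster_id: frozenset(t.transcript_id for t in c.members)
            for c in cluster_lncrnas(list(reversed(transcripts)))
        }
        assert ids1 == ids2

    def test_matches_brute_force_components(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            n = int(rng.integers(2, 40))
            transcripts = random_transcripts(rng, n, coord_range=1500)
            got = {
                frozenset(t.transcript_id for t in c.members)
                for c in cluster_lncrnas(transcripts)
            }
            assert got == brute_force_components(transcripts)


class TestSegmentation:
    def _segments(self, members):
        cluster = TranscriptCluster("TC1", members[0].chrom, members[0].strand,
                                    members)
        return [(ps.interval.start, ps.interval.end)
                for ps in segment_probesets(cluster)]

    def test_single_transcript_exons_pass_through(self):
        assert self._segments([_lnc("A", [(100, 200), (300, 400)])]) == [
            (100, 200), (300, 400)]

    def test_staggered_pair_cuts_at_internal_boundaries(self):
        got = self._segments([_lnc("A", [(100, 200)]), _lnc("B", [(150, 250)])])
        assert got == [(100, 150), (150, 200), (200, 250)]

    def test_bridging_exon_splits_both_sides(self):
        got = self._segments([
            _lnc("A", [(100, 200), (300, 400)]),
            _lnc("B", [(150, 350)]),
        ])
        assert got == [(100, 150), (150, 200), (200, 300), (300, 350), (350, 400)]

    def test_matches_base_by_base_oracle_and_invariants(self):
        rng = np.random.default_rng(29)
        for _ in range(50):
            transcripts = random_transcripts(
                rng, int(rng.integers(1, 8)), coord_range=1000,
                strands=("+",), max_exons=6,
            )
            for cluster in cluster_lncrnas(transcripts):
                got = [(ps.interval.start, ps.interval.end)
                       for ps in segment_probesets(cluster)]
                assert got == label_segments(cluster.members)
                # pairwise disjoint, sorted, covering the footprint
                for (s1, e1), (s2, e2) in zip(got, got[1:]):
                    assert e1 <= s2

    def test_adding_a_transcript_never_merges_segments(self):
        """Boundary sets grow monotonically: a new member can split or
        keep existing probe-set boundaries, never remove them."""
        rng = np.random.default_rng(31)
        for _ in range(20):
            base = random_transcripts(rng, 3, coord_range=600, strands=("+",))
            extra = random_transcripts(rng, 1, coord_range=600, strands=("+",),
                                       prefix="X")[0]
            merged = TranscriptCluster("TC", "chrA", "+", base)
            merged_plus = TranscriptCluster("TC", "chrA", "+", base + [extra])
            cuts = lambda c: {p for ps in segment_probesets(c)
                              for p in (ps.interval.start, ps.interval.end)}
            assert cuts(merged) <= cuts(merged_plus)


class TestAssignProbes:
    def _cluster(self, exons_by_member):
        members = [_lnc(f"T{i}", ex) for i, ex in enumerate(exons_by_member)]
        clusters = cluster_lncrnas(members)
        segment_all(clusters)
        return clusters

    def test_contained_probe_assigned(self, params):
        clusters = self._cluster([[(100, 150)], [(150, 200)]])
        p = _probe("p", 120, 145)
        probes, kept = assign_probes([p], clusters, params)
        assert p.status == ProbeStatus.ASSIGNED
        assert p.probeset_id is not None

    def test_straddling_probe_dropped(self, params):
        clusters = self._cluster([[(100, 200)], [(150, 250)]])  # cut at 150
        p = _probe("p", 140, 165)
        probes, kept = assign_probes([p], clusters, params)
        assert p.status == ProbeStatus.UNASSIGNED

    def test_wrong_strand_probe_not_assigned(self, params):
        clusters = self._cluster([[(100, 200)]])
        p = _probe("p", 120, 145, strand="-")
        assign_probes([p], clusters, params)
        assert p.status == ProbeStatus.UNASSIGNED

    def test_empty_probe_sets_and_clusters_pruned(self, params):
        clusters = self._cluster([[(100, 200)], [(1000, 1100)]])
        p = _probe("p", 120, 145)
        _, kept = assign_probes([p], clusters, params)
        assert len(kept) == 1
        assert kept[0].probesets[0].probe_ids == ["p"]

    def test_every_assigned_probe_in_exactly_one_set(self, params, workspace):
        truth, _ = workspace
        seen = {}
        for c in truth.clusters:
            for ps in c.probesets:
                assert len(ps.probe_ids) >= params.min_probes_per_set
                for pid in ps.probe_ids:
                    assert pid not in seen
                    seen[pid] = ps.probeset_id
        for p in truth.probes:
            if p.status == ProbeStatus.ASSIGNED:
                assert seen[p.probe_id] == p.probeset_id


class TestClassification:
    GENE = [(10_000, 12_000), (15_000, 17_000), (19_000, 20_000)]

    def _classify(self, exons, strand, genes=None, shift=0):
        members = [_lnc("L", [(s + shift, e + shift) for s, e in exons], strand)]
        cluster = TranscriptCluster("TC1", "chr1", strand, members)
        if genes is None:
            genes = [_gene("G", [(s + shift, e + shift) for s, e in self.GENE], "+")]
        return classify_cluster(cluster, genes, Parameters())

    @pytest.mark.parametrize("shift", [0, 1_000_000])
    def test_seven_categories(self, shift):
        """Each geometry maps to its category; translation-invariant."""
        cases = {
            PositionalCategory.SENSE: ([(11_900, 12_500)], "+"),
            PositionalCategory.ANTISENSE: ([(11_900, 12_500)], "-"),
            PositionalCategory.INTRONIC: ([(12_500, 13_000)], "+"),
            PositionalCategory.BIDIRECTIONAL: ([(9_500, 9_900)], "-"),
            PositionalCategory.EXTENSION: ([(20_100, 20_600)], "+"),
            PositionalCategory.CLOSE: ([(20_100, 20_600)], "-"),
            PositionalCategory.INTERGENIC: ([(50_000, 51_000)], "+"),
        }
        for expected, (exons, strand) in cases.items():
            got = self._classify(exons, strand, shift=shift)
            assert got.category == expected, expected

    def test_bidirectional_requires_head_to_head(self):
        # upstream, opposite strand, gap 100 -> divergent 5' ends
        got = self._classify([(9_500, 9_900)], "-")
        assert got.category == PositionalCategory.BIDIRECTIONAL
        assert got.distance == 100
        # same geometry downstream is tail-to-tail -> close
        got = self._classify([(20_100, 20_600)], "-")
        assert got.category == PositionalCategory.CLOSE
        assert got.distance == 100

    def test_extension_is_downstream_same_strand(self):
        got = self._classify([(20_100, 20_600)], "+")
        assert got.category == PositionalCategory.EXTENSION
        assert got.distance == 100

    def test_intergenic_distance_reported(self):
        got = self._classify([(50_000, 51_000)], "+")
        assert got.category == PositionalCategory.INTERGENIC
        assert got.distance == 30_000
        assert got.nearest_gene_id == "G"

    def test_proximate_needs_gap_below_1000(self):
        got = self._classify([(21_000, 21_500)], "+")  # gap exactly 1000
        assert got.category == PositionalCategory.INTERGENIC

    def test_no_genes_gives_intergenic_without_neighbour(self):
        got = self._classify([(100, 200)], "+", genes=[])
        assert got.category == PositionalCategory.INTERGENIC
        assert got.nearest_gene_id is None
        assert got.distance == 0

    def test_sense_beats_antisense_precedence(self):
        genes = [_gene("Gp", self.GENE, "+"), _gene("Gm", self.GENE, "-")]
        got = self._classify([(11_900, 12_500)], "+", genes=genes)
        assert got.category == PositionalCategory.SENSE
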