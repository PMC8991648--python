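"""Call emission, clustering, support, filtering and taxonomy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polysv.containment import classify_reads
from polysv.formats_io import (AvaMapping, GenomeInterval, RepeatAnnotation,
                               ThresholdConfig)
from polysv.read_layout import RepeatIndex, build_anchor_clusters, \
    classify_alignment, distribute_alignments
from polysv.sv_calls import (INSERTION, LOCAL_DUPLICATION, REARRANGEMENT,
                             AvaIndex, SVCall, call_insertions,
                             call_local_duplications, call_rearrangements,
                             classify_calls, classify_strandedness,
                             cluster_calls, count_support, filter_calls,
                             insertion_density_track)
from tests.conftest import make_ref_alignment as aln


def _layout_with_junction(junction_target=("chr7", 100_000, 105_000),
                          gap=50, repeat_ivs=(("chr7", 99_000, 106_000),)):
    """Two 10 kb anchors on chr1 separated by `gap` bp on the reference,
    with a 5 kb junction alignment between them on the read."""
    a1 = aln(read_start=0, read_end=10_000, start=50_000, end=60_000)
    jc, js, je = junction_target
    j = aln(read_start=10_000, read_end=15_000, chrom=jc, start=js, end=je,
            score=je - js)
    a2 = aln(read_start=15_000, read_end=25_000, start=60_000 + gap,
             end=70_000 + gap)
    idx = RepeatIndex([RepeatAnnotation(GenomeInterval(*iv), "Gypsy",
                                        "LTR/Gypsy", 7_469)
                       for iv in repeat_ivs])
    layout = distribute_alignments([a1, j, a2])
    for d in layout:
        classify_alignment(d, idx)
    acs, junctions = build_anchor_clusters(layout, idx)
    return acs, junctions, idx


class TestInsertions:
    def test_junction_between_adjacent_anchors_called(self):
        acs, junctions, _ = _layout_with_junction()
        (call,) = call_insertions(acs, junctions)
        assert call.call_type == INSERTION
        assert call.insertion_len == 5_000
        assert call.breakpoint_distance == 50
        assert (call.pos1, call.pos2) == (60_000, 60_050)
        assert call.junction_composition.get("Gypsy") == 5_000

    def test_contiguous_anchors_no_call(self):
        a1 = aln(read_start=0, read_end=10_000, start=0, end=10_000)
        a2 = aln(read_start=10_000, read_end=20_000, start=10_000, end=20_000)
        idx = RepeatIndex()
        layout = distribute_alignments([a1, a2])
        for d in layout:
            classify_alignment(d, idx)
        acs, junctions = build_anchor_clusters(layout, idx)
        assert call_insertions(acs, junctions) == []

    def test_reverse_read_gives_same_canonical_breakpoints(self):
        """A read crossing the junction in reverse orientation yields an
        identical canonical call (position-ordered, strands flipped)."""
        # reverse-orientation read: first anchor maps downstream, '-' strand
        a1 = aln(read_start=0, read_end=10_000, start=60_050, end=70_050,
                 strand="-")
        j = aln(read_start=10_000, read_end=15_000, chrom="chr7",
                start=100_000, end=105_000, strand="-", score=5_000)
        a2 = aln(read_start=15_000, read_end=25_000, start=50_000, end=60_000,
                 strand="-")
        idx = RepeatIndex([RepeatAnnotation(
            GenomeInterval("chr7", 99_000, 106_000), "Gypsy", "LTR/Gypsy")])
        layout = distribute_alignments([a1, j, a2])
        for d in layout:
            classify_alignment(d, idx)
        acs, junctions = build_anchor_clusters(layout, idx)
        (call,) = call_insertions(acs, junctions)
        assert (call.pos1, call.pos2) == (60_000, 60_050)
        assert (call.strand1, call.strand2) == ("+", "+")


class TestDuplications:
    def _ac_with_overlap(self, s2, e2):
        a1 = aln(read_start=0, read_end=10_000, chrom="chr2",
                 start=100_000, end=110_000)
        a2 = aln(read_start=10_000, read_end=10_000 + (e2 - s2), chrom="chr2",
                 start=s2, end=e2)
        idx = RepeatIndex()
        layout = distribute_alignments([a1, a2])
        for d in layout:
            classify_alignment(d, idx)
        acs, _ = build_anchor_clusters(layout, idx)
        return acs

    def test_reference_overlap_yields_duplication(self):
        acs = self._ac_with_overlap(105_000, 115_000)
        (call,) = call_local_duplications(acs)
        assert call.call_type == LOCAL_DUPLICATION
        assert (call.duplicated_interval.start,
                call.duplicated_interval.end) == (105_000, 110_000)

    def test_disjoint_members_no_call(self):
        acs = self._ac_with_overlap(111_000, 121_000)
        assert call_local_duplications(acs) == []


class TestRearrangements:
    def _two_ac_read(self, span, chrom2="chr3"):
        a1 = aln(read_len=2 * span, read_start=0, read_end=span,
                 start=1_000_000, end=1_000_000 + span)
        a2 = aln(read_len=2 * span, read_start=span, read_end=2 * span,
                 chrom=chrom2, start=4_000_000, end=4_000_000 + span)
        idx = RepeatIndex()
        layout = distribute_alignments([a1, a2])
        for d in layout:
            classify_alignment(d, idx)
        acs, _ = build_anchor_clusters(layout, idx)
        return acs

    def test_trans_chromosomal_call(self):
        (call,) = call_rearrangements(self._two_ac_read(200_000))
        assert call.call_type == REARRANGEMENT
        assert call.breakpoint_distance is None
        assert call.distance_class == ""  # taxonomy assigned separately

    def test_small_clusters_below_3kbp_excluded(self):
        assert call_rearrangements(self._two_ac_read(2_000)) == []

    def test_span_gate_is_strict(self):
        assert call_rearrangements(self._two_ac_read(3_000)) == []
        assert len(call_rearrangements(self._two_ac_read(3_001))) == 1


def _call(pos1, pos2, s1="+", s2="+", reads=1, ctype=INSERTION, chrom="chr1"):
    c = SVCall(ctype, chrom, pos1, s1, chrom, pos2, s2,
               source_reads={f"r{pos1}_{i}" for i in range(reads)})
    return c


class TestClustering:
    def test_nearby_same_strand_calls_merge(self):
        merged = cluster_calls([_call(10_000, 10_000),
                                _call(10_300, 10_300)])
        assert len(merged) == 1

    def test_beyond_window_stays_separate(self):
        assert len(cluster_calls([_call(10_000, 10_000),
                                  _call(10_600, 10_600)])) == 2

    def test_opposite_strand_at_second_breakpoint_stays_separate(self):
        assert len(cluster_calls([_call(10_000, 20_000, "+", "+"),
                                  _call(10_000, 20_000, "+", "-")])) == 2

    def test_merged_reads_unioned(self):
        a = _call(10_000, 10_000, reads=2)
        b = _call(10_200, 10_200, reads=3)
        (m,) = cluster_calls([a, b])
        assert len(m.source_reads) == 5

    @given(st.integers(0, 6))
    @settings(max_examples=7, deadline=None, derandomize=True)
    def test_idempotence(self, seed):
        rng = np.random.default_rng(seed)
        calls = [_call(int(p), int(p) + int(rng.integers(0, 2_000)))
                 for p in rng.integers(0, 50_000, 20)]
        once = cluster_calls(calls)
        twice = cluster_calls(once)
        assert sorted((c.pos1, c.pos2) for c in twice) == \
            sorted((c.pos1, c.pos2) for c in once)


class TestSupport:
    def _fixture(self):
        """A call with 3 informative source reads and contained reads whose
        mappings either span or miss the breakpoint on a source read."""
        call = _call(5_000, 5_000, reads=0)
        call.source_reads = {"s1", "s2", "s3"}
        call.read_breakpoints = {"s1": 10_000, "s2": 12_000, "s3": 9_000}
        reads = {"s1": 30_000, "s2": 30_000, "s3": 30_000}
        ava = []
        # 8 distinct contained reads spanning s1's breakpoint
        for i in range(8):
            rid = f"c{i}"
            reads[rid] = 8_000
            ava.append(AvaMapping(rid, 8_000, 0, 8_000, "s1", 30_000,
                                  6_000, 14_000, "+", 8_000, 8_000))
        # the same contained read also spans on s2: must count once
        ava.append(AvaMapping("c0", 8_000, 0, 8_000, "s2", 30_000,
                              8_000, 16_000, "+", 8_000, 8_000))
        # a contained read NOT spanning (ends exactly at the breakpoint)
        reads["miss"] = 5_000
        ava.append(AvaMapping("miss", 5_000, 0, 5_000, "s1", 30_000,
                              5_000, 10_000, "+", 5_000, 5_000))
        containment = classify_reads(reads, ava)
        return call, containment, AvaIndex(ava)

    def test_informative_plus_spanning_contained(self):
        call, cont, index = self._fixture()
        assert count_support(call, cont, index) == 11

    def test_no_contained_reads_support_is_informative_count(self):
        call = _call(5_000, 5_000, reads=0)
        call.source_reads = {"a", "b"}
        call.read_breakpoints = {"a": 100, "b": 100}
        cont = classify_reads({"a": 1_000, "b": 1_000}, [])
        assert count_support(call, cont, AvaIndex([])) == 2


class TestFilter:
    @pytest.mark.parametrize("informative,support,kept", [
        (3, 4, True),
        (2, 10, False),   # informative-read rule is strict > 2
        (3, 3, False),    # support rule is strict > 3
        (6, 4, True),
        (1, 100, False),
    ])
    def test_low_frequency_filter(self, informative, support, kept):
        c = _call(0, 0, reads=informative)
        c.support = support
        assert (filter_calls([c]) == [c]) is kept

    @given(st.integers(0, 8), st.integers(0, 8))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_raising_thresholds_never_keeps_more(self, min_inf, min_sup):
        rng = np.random.default_rng(0)
        calls = []
        for _ in range(30):
            c = _call(int(rng.integers(0, 10_000)), 0,
                      reads=int(rng.integers(1, 8)))
            c.support = int(rng.integers(1, 12))
            calls.append(c)
        base = len(filter_calls(calls))
        stricter = ThresholdConfig(min_informative_reads=2 + min_inf,
                                   min_read_support=3 + min_sup)
        assert len(filter_calls(calls, stricter)) <= base


class TestTaxonomy:
    def _classified_insertion(self, length, comp, repeats=None):
        c = _call(10_000, 10_050)
        c.insertion_len = length
        c.junction_composition = comp
        idx = repeats or RepeatIndex(
            [RepeatAnnotation(GenomeInterval("chrZ", 0, 7_469), "Gypsy",
                              "LTR/Gypsy", 7_469)])
        classify_calls([c], idx)
        return c

    def test_single_element_majority_labels_and_full_length(self):
        c = self._classified_insertion(7_200, {"Gypsy": 7_000,
                                               "unaligned": 200})
        assert c.element == "Gypsy"
        assert c.element_class == "LTR/Gypsy"
        assert c.full_length  # 7200/7469 = 96% of library length
        assert c.event_class == "repetitive_indel_gt1kbp"
        assert c.length_class == "1-10 kbp"
        assert c.repeat_class == "75-100%"

    def test_short_insertion_binned_below_1kbp(self):
        c = self._classified_insertion(800, {"unaligned": 800})
        assert c.length_class == "<1 kbp"
        assert c.event_class == "short_indel"

    def test_element_purity_below_90pct_unlabeled(self):
        c = self._classified_insertion(
            7_000, {"Gypsy": 4_000, "Copia": 3_000})
        assert c.element == ""

    def test_missing_library_length_warns_and_unsets_flag(self):
        idx = RepeatIndex([RepeatAnnotation(
            GenomeInterval("chrZ", 0, 5_000), "Mystery", "LTR/Unknown")])
        with pytest.warns(UserWarning, match="library length"):
            c = self._classified_insertion(5_000, {"Mystery": 5_000},
                                           repeats=idx)
        assert not c.full_length

    def test_distance_classes(self):
        calls = []
        for p2 in (10_500, 15_000, 80_000, 500_000, 2_000_000):
            calls.append(_call(10_000, p2, ctype=REARRANGEMENT))
        trans = SVCall(REARRANGEMENT, "chr1", 0, "+", "chr2", 0, "+")
        calls.append(trans)
        classify_calls(calls, RepeatIndex())
        assert [c.distance_class for c in calls] == \
            ["<1 kbp", "1-10 kbp", "10-100 kbp", "100 kbp-1 Mbp", ">1 Mbp",
             "trans_chromosomal"]

    def test_four_most_abundant_classes_kept_rest_pooled(self):
        anns = []
        for i, name in enumerate(["A", "B", "C", "D", "E", "F"]):
            anns.append(RepeatAnnotation(
                GenomeInterval("chrZ", i * 10_000, i * 10_000 + 5_000),
                name, f"class{name}", 5_000))
        idx = RepeatIndex(anns)
        calls = []
        counts = {"A": 5, "B": 4, "C": 3, "D": 2, "E": 1, "F": 1}
        for name, n in counts.items():
            for _ in range(n):
                c = _call(10_000, 10_050)
                c.insertion_len = 5_000
                c.junction_composition = {name: 5_000}
                calls.append(c)
        classify_calls(calls, idx)
        pooled = {c.element_class: c.element_class_pooled for c in calls}
        assert pooled["classA"] == "classA"
        assert pooled["classD"] == "classD"
        assert pooled["classE"] == "Other"
        assert pooled["classF"] == "Other"


class TestStrandedness:
    def test_equal_strands_maintained(self):
        assert classify_strandedness(_call(0, 0, "+", "+")) == "maintained"
        assert classify_strandedness(_call(0, 0, "-", "-")) == "maintained"

    def test_unequal_strands_changed(self):
        assert classify_strandedness(_call(0, 0, "+", "-")) == "changed"


class TestDensityTrack:
    def _insertion(self, pos, comp, length=5_000):
        c = _call(pos, pos + 10)
        c.insertion_len = length
        c.junction_composition = comp
        return c

    def test_counts_and_conservation(self):
        idx = RepeatIndex([RepeatAnnotation(
            GenomeInterval("chrZ", 0, 7_469), "Gypsy", "LTR/Gypsy", 7_469)])
        calls = [self._insertion(p, {"Gypsy": 5_000})
                 for p in (10_000, 20_000, 90_000, 150_000)]
        # 65% repeat: excluded by the 70% rule
        calls.append(self._insertion(30_000, {"Gypsy": 3_250,
                                              "unaligned": 1_750}))
        track = insertion_density_track(calls, idx, {"chr1": 300_000})
        assert track["chr1"][0] == 3
        assert track["chr1"][1] == 1
        assert track["chr1"].sum() == 4
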