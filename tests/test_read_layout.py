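"""Alignment distribution, classification and adjacent clusters."""

import numpy as np
import pytest

from polysv.formats_io import GenomeInterval, RepeatAnnotation
from polysv.read_layout import (ANCHOR, JUNCTION, REPETITIVE, RepeatIndex,
                                build_anchor_clusters, classify_alignment,
                                distribute_alignments)
from tests.conftest import make_ref_alignment as aln


def repeats(*intervals, name="Gypsy", klass="LTR/Gypsy"):
    return RepeatIndex([RepeatAnnotation(GenomeInterval(*iv), name, klass)
                        for iv in intervals])


class TestDistribute:
    def test_lower_score_trimmed_to_unrepresented_region(self):
        high = aln(read_start=0, read_end=8_000, start=0, end=8_000,
                   score=8_000)
        low = aln(read_start=6_000, read_end=12_000, chrom="chr2",
                  start=50_000, end=56_000, score=6_000)
        placed = distribute_alignments([high, low])
        spans = [(d.read_start, d.read_end) for d in placed]
        assert spans == [(0, 8_000), (8_000, 12_000)]
        # target rescaled linearly to the kept read fraction
        trimmed = placed[1]
        assert trimmed.target.start == 52_000
        assert trimmed.target.end == 56_000

    def test_single_alignment_identity(self):
        a = aln(read_start=100, read_end=9_000, start=1_000, end=9_900)
        (d,) = distribute_alignments([a])
        assert (d.read_start, d.read_end) == (100, 9_000)
        assert d.target == a.target

    def test_remainder_below_100bp_dropped(self):
        high = aln(read_start=0, read_end=8_000, score=9_999)
        low = aln(read_start=7_950, read_end=8_040, chrom="chr2",
                  start=0, end=90, score=10)
        placed = distribute_alignments([high, low])
        assert [(d.read_start, d.read_end) for d in placed] == [(0, 8_000)]

    def test_empty_input(self):
        assert distribute_alignments([]) == []

    def test_mixed_read_ids_rejected(self):
        with pytest.raises(ValueError):
            distribute_alignments([aln(read_id="a"), aln(read_id="b")])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_occupancy_oracle(self, seed):
        """Greedy bp-level occupancy replay must reproduce the layout."""
        rng = np.random.default_rng(seed)
        read_len = 20_000
        alns = []
        for i in range(10):
            s = int(rng.integers(0, read_len - 200))
            e = int(rng.integers(s + 100, min(read_len, s + 8_000)))
            alns.append(aln(read_len=read_len, read_start=s, read_end=e,
                            start=10 * s, end=10 * e,
                            score=float(rng.integers(1, 10_000))))
        placed = distribute_alignments(alns)
        # oracle: bp occupancy array, same tie-break order
        order = sorted(alns, key=lambda a: (-a.score,
                                            -(a.read_end - a.read_start),
                                            a.read_start, a.target.chrom,
                                            a.target.start))
        occ = np.zeros(read_len, dtype=bool)
        expected = []
        for a in order:
            free = ~occ[a.read_start:a.read_end]
            edges = np.flatnonzero(np.diff(np.concatenate(
                [[0], free.astype(int), [0]])))
            for s, e in edges.reshape(-1, 2):
                if e - s >= 100:
                    expected.append((a.read_start + s, a.read_start + e))
                    occ[a.read_start + s:a.read_start + e] = True
        assert sorted((d.read_start, d.read_end) for d in placed) == \
            sorted(expected)

    @pytest.mark.parametrize("seed", range(5))
    def test_spans_disjoint_and_bounded(self, seed):
        rng = np.random.default_rng(100 + seed)
        read_len = 15_000
        alns = [aln(read_len=read_len,
                    read_start=int(s := rng.integers(0, read_len - 200)),
                    read_end=int(rng.integers(s + 100,
                                              min(read_len, s + 6_000))),
                    score=float(rng.integers(1, 5_000)))
                for _ in range(8)]
        placed = sorted(distribute_alignments(alns),
                        key=lambda d: d.read_start)
        for a, b in zip(placed, placed[1:]):
            assert a.read_end <= b.read_start
        assert sum(d.effective_len for d in placed) <= read_len


class TestClassify:
    def test_majority_repeat_beats_anchor_length(self):
        idx = repeats(("chr1", 1_000, 4_000))
        d = distribute_alignments([aln(read_start=0, read_end=5_000,
                                       start=0, end=5_000)])[0]
        assert classify_alignment(d, idx) == REPETITIVE  # 60% masked

    def test_long_low_repeat_is_anchor(self):
        idx = repeats(("chr1", 0, 150))
        d = distribute_alignments([aln(read_start=0, read_end=1_500,
                                       start=0, end=1_500)])[0]
        assert classify_alignment(d, idx) == ANCHOR

    def test_short_clean_is_junction(self):
        d = distribute_alignments([aln(read_start=0, read_end=400,
                                       start=0, end=400)])[0]
        assert classify_alignment(d, RepeatIndex()) == JUNCTION

    @pytest.mark.parametrize("eff_len,expected", [
        (1_000, JUNCTION),   # anchor rule is strict > 1 kbp
        (1_001, ANCHOR),
    ])
    def test_anchor_length_boundary(self, eff_len, expected):
        d = distribute_alignments([aln(read_start=0, read_end=eff_len,
                                       start=0, end=eff_len)])[0]
        assert classify_alignment(d, RepeatIndex()) == expected


def _two_anchor_layout(gap, strand2="+", chrom2="chr1", second_start=None):
    second_start = 20_000 + gap if second_start is None else second_start
    a1 = aln(read_start=0, read_end=10_000, start=10_000, end=20_000)
    a2 = aln(read_start=10_000, read_end=16_000, chrom=chrom2,
             start=second_start, end=second_start + 6_000, strand=strand2)
    layout = distribute_alignments([a1, a2])
    idx = RepeatIndex()
    for d in layout:
        classify_alignment(d, idx)
    return layout


class TestAnchorClusters:
    def test_small_reference_gap_joins(self):
        layout = _two_anchor_layout(gap=4_000)
        acs, _ = build_anchor_clusters(layout, RepeatIndex())
        assert len(acs) == 1 and len(acs[0].members) == 2

    def test_gap_above_5kbp_splits(self):
        layout = _two_anchor_layout(gap=5_001)
        acs, _ = build_anchor_clusters(layout, RepeatIndex())
        assert len(acs) == 2

    def test_repeat_masked_gap_is_discounted(self):
        # raw gap 20 kbp of which 18 kbp repeat-masked: effective 2 kbp
        layout = _two_anchor_layout(gap=20_000)
        idx = repeats(("chr1", 21_000, 39_000))
        acs, _ = build_anchor_clusters(layout, idx)
        assert len(acs) == 1

    def test_mask_subtraction_capped_at_25kbp(self):
        # raw gap 31 kbp fully masked; cap leaves effective 6 kbp > 5 kbp
        layout = _two_anchor_layout(gap=31_000)
        idx = repeats(("chr1", 20_000, 51_000))
        acs, _ = build_anchor_clusters(layout, idx)
        assert len(acs) == 2

    def test_single_anchor_singleton_cluster(self):
        layout = distribute_alignments([aln(read_start=0, read_end=9_000,
                                            start=0, end=9_000)])
        for d in layout:
            classify_alignment(d, RepeatIndex())
        acs, junctions = build_anchor_clusters(layout, RepeatIndex())
        assert len(acs) == 1
        assert acs[0].ref_span == GenomeInterval("chr1", 0, 9_000, "+")
        assert junctions == []

    def test_strand_change_terminates_cluster(self):
        layout = _two_anchor_layout(gap=1_000, strand2="-")
        acs, _ = build_anchor_clusters(layout, RepeatIndex())
        assert len(acs) == 2

    def test_chromosome_change_terminates_cluster(self):
        layout = _two_anchor_layout(gap=1_000, chrom2="chr9")
        acs, _ = build_anchor_clusters(layout, RepeatIndex())
        assert len(acs) == 2

    def test_overlapping_anchors_share_cluster(self):
        # reference overlap (a duplication pattern) still joins the AC
        layout = _two_anchor_layout(gap=0, second_start=14_000)
        acs, _ = build_anchor_clusters(layout, RepeatIndex())
        assert len(acs) == 1

    def test_junction_composition_between_anchors(self):
        a1 = aln(read_start=0, read_end=10_000, start=10_000, end=20_000)
        ins = aln(read_start=10_000, read_end=15_000, chrom="chr7",
                  start=100_000, end=105_000, score=5_000)
        a2 = aln(read_start=15_000, read_end=21_000, start=20_000, end=26_000)
        idx = repeats(("chr7", 99_000, 106_000))
        layout = distribute_alignments([a1, ins, a2])
        for d in layout:
            classify_alignment(d, idx)
        acs, junctions = build_anchor_clusters(layout, idx)
        (j,) = junctions
        assert j.same_ac
        assert j.span == 5_000
        assert j.composition.get("Gypsy") == 5_000


def test_no_sv_reads_yield_one_cluster_per_chromosome(sv_free_dataset):
    """On an SV-free genome every informative read maps as one AC."""
    from collections import defaultdict

    from polysv.containment import classify_reads, informative_ids
    from polysv.read_layout import layout_read

    ds = sv_free_dataset
    informative = informative_ids(
        classify_reads(ds.read_lengths, ds.ava))
    by_read = defaultdict(list)
    for a in ds.ref_alignments:
        if a.read_id in informative:
            by_read[a.read_id].append(a)
    idx = ds.repeat_index
    checked = 0
    for rid, alns in list(by_read.items())[:300]:
        _, acs, _ = layout_read(alns, idx)
        assert len(acs) <= 1, rid
        # short or repeat-dominated reads legitimately have no anchor
        t = alns[0].target
        if ds.read_lengths[rid] > 5_000 and idx.fraction(
                t.chrom, t.start, t.end) < 0.4:
            assert len(acs) == 1, rid
            checked += 1
    assert checked > 50
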