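"""Turn a read's reference alignments into a classified, non-overlapping layout.

Alignments of one informative read are distributed greedily along the read in
descending score order; a later alignment overlapping an already occupied read
region keeps only the unrepresented remainder (target coordinates rescaled
linearly), and remainders shorter than 100 bp are dropped. Each placed
alignment is classified repetitive (> 50% of its target span repeat-masked),
anchor (> 1 kbp), or junction material. Read-consecutive anchors that are
locally collinear on the reference — gap at most 5 kbp after discounting up to
25 kbp of repeat-masked gap sequence — are grouped into adjacent clusters
(ACs); everything between anchors accumulates into junctions.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .formats_io import (GenomeInterval, RefAlignment, RepeatAnnotation,
                         ThresholdConfig)

REPETITIVE = "repetitive"
ANCHOR = "anchor"
JUNCTION = "junction"


# ---------------------------------------------------------------------------
# Repeat annotation index
# ---------------------------------------------------------------------------

class RepeatIndex:
    """Per-chromosome interval index over repeat annotations."""

    def __init__(self, repeats: list[RepeatAnnotation] | None = None):
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self.library: dict[str, int] = {}
        self.classes: dict[str, str] = {}
        for r in repeats or []:
            iv = r.interval
            if iv.end > iv.start:
                self._trees[iv.chrom].addi(iv.start, iv.end, r)
            if r.element_full_length:
                self.library[r.element_name] = r.element_full_length
            if r.element_class:
                self.classes[r.element_name] = r.element_class

    def _hits(self, chrom: str, start: int, end: int):
        if end <= start or chrom not in self._trees:
            return []
        return self._trees[chrom].overlap(start, end)

    def masked_bp(self, chrom: str, start: int, end: int) -> int:
        """Total repeat-masked bp in [start,end), overlaps merged."""
        spans = sorted((max(h.begin, start), min(h.end, end))
                       for h in self._hits(chrom, start, end))
        total, cur_s, cur_e = 0, None, None
        for s, e in spans:
            if cur_e is None or s > cur_e:
                if cur_e is not None:
                    total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            total += cur_e - cur_s
        return total

    def fraction(self, chrom: str, start: int, end: int) -> float:
        if end <= start:
            return 0.0
        return self.masked_bp(chrom, start, end) / (end - start)

    def composition(self, chrom: str, start: int, end: int) -> dict[str, int]:
        """bp of [start,end) attributed to each element name (first-come on
        overlap between annotations; total never exceeds span)."""
        out: dict[str, int] = defaultdict(int)
        for h in sorted(self._hits(chrom, start, end),
                        key=lambda h: (h.begin, h.end)):
            s, e = max(h.begin, start), min(h.end, end)
            out[h.data.element_name] += e - s
        return dict(out)


# ---------------------------------------------------------------------------
# Distributed alignments
# ---------------------------------------------------------------------------

@dataclass
class DistributedAlignment:
    """A read-trimmed alignment piece with its layout classification."""

    source: RefAlignment
    read_start: int
    read_end: int
    target: GenomeInterval
    strand: str
    klass: str | None = None
    repeat_fraction: float = 0.0

    @property
    def effective_len(self) -> int:
        return self.read_end - self.read_start

    @property
    def read_id(self) -> str:
        return self.source.read_id


def _free_pieces(span: tuple[int, int],
                 occupied: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sub-intervals of span not covered by the sorted disjoint occupancy."""
    s, e = span
    pieces, cur = [], s
    for os_, oe in occupied:
        if oe <= s:
            continue
        if os_ >= e:
            break
        if os_ > cur:
            pieces.append((cur, min(os_, e)))
        cur = max(cur, oe)
        if cur >= e:
            break
    if cur < e:
        pieces.append((cur, e))
    return pieces


def _rescale_target(aln: RefAlignment, piece: tuple[int, int]) -> GenomeInterval:
    """Map a read sub-span onto the target linearly (no CIGAR replay)."""
    rs, re_ = aln.read_start, aln.read_end
    ts, te = aln.target.start, aln.target.end
    f = (te - ts) / (re_ - rs)
    a, b = piece
    if aln.strand == "+":
        ns, ne = ts + (a - rs) * f, ts + (b - rs) * f
    else:
        ns, ne = ts + (re_ - b) * f, ts + (re_ - a) * f
    return GenomeInterval(aln.target.chrom, int(round(ns)),
                          max(int(round(ns)) + 1, int(round(ne))), aln.strand)


def distribute_alignments(alignments: list[RefAlignment],
                          cfg: ThresholdConfig | None = None
                          ) -> list[DistributedAlignment]:
    """Greedy score-ordered placement of one read's alignments.

    Ties broken by longer alignment, then lower read start, then target
    order, so the layout is deterministic for equal-score inputs.
    """
    cfg = cfg or ThresholdConfig()
    if not alignments:
        return []
    if len({a.read_id for a in alignments}) != 1:
        raise ValueError("distribute_alignments expects a single read")
    order = sorted(alignments,
                   key=lambda a: (-a.score, -(a.read_end - a.read_start),
                                  a.read_start, a.target.chrom, a.target.start))
    occupied: list[tuple[int, int]] = []
    placed: list[DistributedAlignment] = []
    for aln in order:
        for piece in _free_pieces((aln.read_start, aln.read_end), occupied):
            if piece[1] - piece[0] < cfg.min_distributed_aln:
                continue
            placed.append(DistributedAlignment(
                source=aln, read_start=piece[0], read_end=piece[1],
                target=_rescale_target(aln, piece), strand=aln.strand))
            occupied.append(piece)
            occupied.sort()
    placed.sort(key=lambda d: d.read_start)
    return placed


def classify_alignment(a: DistributedAlignment, repeats: RepeatIndex,
                       cfg: ThresholdConfig | None = None) -> str:
    """Repetitive (> 50% masked target) beats anchor (> 1 kbp) beats junction."""
    cfg = cfg or ThresholdConfig()
    a.repeat_fraction = repeats.fraction(a.target.chrom, a.target.start,
                                         a.target.end)
    if a.repeat_fraction > cfg.repetitive_fraction:
        a.klass = REPETITIVE
    elif a.effective_len > cfg.anchor_min_len:
        a.klass = ANCHOR
    else:
        a.klass = JUNCTION
    return a.klass


# ---------------------------------------------------------------------------
# Adjacent clusters and junctions
# ---------------------------------------------------------------------------

@dataclass
class AnchorCluster:
    """A maximal run of read-consecutive, locally collinear anchors."""

    read_id: str
    members: list[DistributedAlignment]
    masked_bp: int = 0
    ac_id: int = -1

    @property
    def chrom(self) -> str:
        return self.members[0].target.chrom

    @property
    def strand(self) -> str:
        return self.members[0].strand

    @property
    def ref_start(self) -> int:
        return min(m.target.start for m in self.members)

    @property
    def ref_end(self) -> int:
        return max(m.target.end for m in self.members)

    @property
    def ref_span(self) -> GenomeInterval:
        return GenomeInterval(self.chrom, self.ref_start, self.ref_end,
                              self.strand)

    @property
    def span_len(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def read_start(self) -> int:
        return self.members[0].read_start

    @property
    def read_end(self) -> int:
        return self.members[-1].read_end


@dataclass
class Junction:
    """Read material between two flanking anchors."""

    read_id: str
    read_start: int
    read_end: int
    left: DistributedAlignment | None
    right: DistributedAlignment | None
    members: list[DistributedAlignment] = field(default_factory=list)
    unaligned: int = 0
    composition: dict[str, int] = field(default_factory=dict)
    same_ac: bool = False

    @property
    def span(self) -> int:
        return self.read_end - self.read_start


def _effective_gap(a: DistributedAlignment, b: DistributedAlignment,
                   repeats: RepeatIndex, cfg: ThresholdConfig
                   ) -> tuple[int, int]:
    """(raw gap, repeat-masked bp in the gap); 0 gap when the spans overlap."""
    gs = min(a.target.end, b.target.end)
    ge = max(a.target.start, b.target.start)
    if ge <= gs:
        return 0, 0
    masked = min(repeats.masked_bp(a.target.chrom, gs, ge),
                 cfg.ac_mask_omit_max)
    return ge - gs, masked


def _junction_between(read_id: str, left, right,
                      members: list[DistributedAlignment],
                      repeats: RepeatIndex) -> Junction:
    rs = left.read_end if left else (members[0].read_start if members else 0)
    re_ = right.read_start if right else (members[-1].read_end if members else rs)
    j = Junction(read_id, rs, re_, left, right, members)
    comp: dict[str, int] = defaultdict(int)
    aligned = 0
    for m in members:
        aligned += m.effective_len
        mcomp = repeats.composition(m.target.chrom, m.target.start,
                                    m.target.end)
        annotated = 0
        for name, bp in mcomp.items():
            # scale annotation bp from target to read space
            scaled = int(round(bp * m.effective_len
                               / max(1, len(m.target))))
            comp[name] += scaled
            annotated += scaled
        leftover = m.effective_len - annotated
        if leftover > 0:
            comp["unannotated"] += leftover
    j.unaligned = max(0, j.span - aligned)
    if j.unaligned:
        comp["unaligned"] += j.unaligned
    j.composition = dict(comp)
    return j


def build_anchor_clusters(layout: list[DistributedAlignment],
                          repeats: RepeatIndex,
                          cfg: ThresholdConfig | None = None
                          ) -> tuple[list[AnchorCluster], list[Junction]]:
    """Group read-ordered anchors into ACs and the rest into junctions.

    Consecutive anchors extend an AC when on the same chromosome and strand
    with an effective reference gap (raw gap minus capped repeat-masked bp)
    of at most `ac_gap`; a strand or chromosome change always terminates the
    AC. Material between anchors becomes a junction keyed by its flanks;
    junctions whose flanks fell in the same AC are the insertion substrate.
    """
    cfg = cfg or ThresholdConfig()
    for d in layout:
        if d.klass is None:
            classify_alignment(d, repeats, cfg)
    read_id = layout[0].read_id if layout else ""
    anchors = [d for d in layout if d.klass == ANCHOR]
    clusters: list[AnchorCluster] = []
    junctions: list[Junction] = []
    if not anchors:
        return clusters, junctions

    by_pos = sorted(layout, key=lambda d: d.read_start)
    # between[i] holds the non-anchor material preceding the i-th anchor
    between: dict[int, list[DistributedAlignment]] = defaultdict(list)
    ai = -1
    for d in by_pos:
        if d.klass == ANCHOR:
            ai += 1
        else:
            between[ai + 1].append(d)

    cur = AnchorCluster(read_id, [anchors[0]])
    cur_masked = 0
    same_ac_flags: list[bool] = []
    for i in range(1, len(anchors)):
        prev, nxt = anchors[i - 1], anchors[i]
        joined = False
        if (nxt.target.chrom == prev.target.chrom
                and nxt.strand == prev.strand):
            raw, masked = _effective_gap(prev, nxt, repeats, cfg)
            if raw - masked <= cfg.ac_gap:
                joined = True
                cur_masked += masked
        if joined:
            cur.members.append(nxt)
        else:
            cur.masked_bp = cur_masked
            clusters.append(cur)
            cur = AnchorCluster(read_id, [nxt])
            cur_masked = 0
        same_ac_flags.append(joined)
    cur.masked_bp = cur_masked
    clusters.append(cur)
    for i, c in enumerate(clusters):
        c.ac_id = i

    for i in range(1, len(anchors)):
        mids = between.get(i, [])
        j = _junction_between(read_id, anchors[i - 1], anchors[i], mids,
                              repeats)
        j.same_ac = same_ac_flags[i - 1]
        junctions.append(j)
    return clusters, junctions


def layout_read(alignments: list[RefAlignment], repeats: RepeatIndex,
                cfg: ThresholdConfig | None = None):
    """Convenience: distribute, classify, and cluster one read's alignments."""
    cfg = cfg or ThresholdConfig()
    layout = distribute_alignments(alignments, cfg)
    for d in layout:
        classify_alignment(d, repeats, cfg)
    acs, junctions = build_anchor_clusters(layout, repeats, cfg)
    return layout, acs, junctions
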