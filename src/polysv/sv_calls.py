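"""Emit, cluster, support-count, filter and classify structural-variant calls.

Calls are read-centered: each informative read's layout yields candidate
events (insertions from junctions inside an AC, local duplications from
reference-overlapping AC members, rearrangements between consecutive large
ACs), which are then clustered across reads (both breakpoints within 500 bp,
strands matching), support-counted with contained reads spanning the
breakpoint on a source read, and filtered for low-frequency events
(> 2 informative reads and > 3 read support required).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .containment import CONTAINED, ContainmentResult, classify_reads, informative_ids
from .formats_io import (AvaMapping, GenomeInterval, RefAlignment,
                         ThresholdConfig)
from .read_layout import AnchorCluster, Junction, RepeatIndex, layout_read

INSERTION = "insertion"
LOCAL_DUPLICATION = "local_duplication"
REARRANGEMENT = "rearrangement"

TRANS = "trans_chromosomal"

MAINTAINED = "maintained"
CHANGED = "changed"


@dataclass
class SVCall:
    call_type: str
    chrom1: str
    pos1: int
    strand1: str
    chrom2: str
    pos2: int
    strand2: str
    insertion_len: int = 0
    junction_composition: dict[str, int] = field(default_factory=dict)
    duplicated_interval: GenomeInterval | None = None
    source_reads: set[str] = field(default_factory=set)
    read_breakpoints: dict[str, int] = field(default_factory=dict)
    support: int = 0
    cluster_id: int = -1
    # taxonomy (filled by classify_calls)
    length_class: str = ""
    repeat_class: str = ""
    distance_class: str = ""
    element: str = ""
    element_class: str = ""
    element_class_pooled: str = ""
    full_length: bool = False
    event_class: str = ""
    repeat_fraction: float = 0.0

    @property
    def breakpoint_distance(self) -> int | None:
        """Genomic distance between breakpoints, None if trans-chromosomal."""
        if self.chrom1 != self.chrom2:
            return None
        return abs(self.pos2 - self.pos1)

    @property
    def informative_reads(self) -> int:
        return len(self.source_reads)

    @property
    def strandedness(self) -> str:
        return classify_strandedness(self)

    @property
    def midpoint(self) -> int:
        """Representative position: midpoint between facing breakpoint ends."""
        if self.chrom1 != self.chrom2:
            return self.pos1
        return (self.pos1 + self.pos2) // 2


_FLIP = {"+": "-", "-": "+"}


def _ordered_breakpoints(c1, p1, s1, c2, p2, s2):
    """Canonicalise a junction to genome order.

    A junction is traversed read-first from bp1 to bp2; putting bp2 first
    means traversing it in reverse, which flips both strands. This makes
    calls from reads crossing the same junction in opposite directions
    identical, so they cluster together.
    """
    if (c1, p1) <= (c2, p2):
        return c1, p1, s1, c2, p2, s2
    return c2, p2, _FLIP[s2], c1, p1, _FLIP[s1]


# ---------------------------------------------------------------------------
# Per-read call emission
# ---------------------------------------------------------------------------

def call_insertions(acs: Sequence[AnchorCluster],
                    junctions: Sequence[Junction],
                    cfg: ThresholdConfig | None = None) -> list[SVCall]:
    """One insertion per junction whose flanking anchors share an AC.

    The insertion length is the read gap between the flanking anchors; the
    breakpoints are the facing reference ends of those anchors.
    """
    cfg = cfg or ThresholdConfig()
    calls = []
    for j in junctions:
        if not j.same_ac or j.span <= 0 or j.left is None or j.right is None:
            continue
        left, right = j.left, j.right
        # facing reference ends of the flanking anchors in read direction
        p1 = left.target.end if left.strand == "+" else left.target.start
        p2 = right.target.start if right.strand == "+" else right.target.end
        c1, p1, s1, c2, p2, s2 = _ordered_breakpoints(
            left.target.chrom, p1, left.strand,
            right.target.chrom, p2, right.strand)
        call = SVCall(INSERTION, c1, p1, s1, c2, p2, s2,
                      insertion_len=j.span,
                      junction_composition=dict(j.composition),
                      source_reads={j.read_id},
                      read_breakpoints={j.read_id: (j.read_start + j.read_end) // 2})
        calls.append(call)
    return calls


def call_local_duplications(acs: Sequence[AnchorCluster],
                            cfg: ThresholdConfig | None = None) -> list[SVCall]:
    """Duplications from reference-overlap of consecutive AC members,
    clustered across reads by reference overlap into merged calls."""
    cfg = cfg or ThresholdConfig()
    per_read: list[SVCall] = []
    for ac in acs:
        for a, b in zip(ac.members, ac.members[1:]):
            if a.strand != b.strand or a.target.chrom != b.target.chrom:
                continue
            ov_s = max(a.target.start, b.target.start)
            ov_e = min(a.target.end, b.target.end)
            if ov_e <= ov_s:
                continue
            per_read.append(SVCall(
                LOCAL_DUPLICATION,
                a.target.chrom, ov_s, a.strand,
                a.target.chrom, ov_e, b.strand,
                duplicated_interval=GenomeInterval(a.target.chrom, ov_s, ov_e),
                source_reads={ac.read_id},
                read_breakpoints={ac.read_id: a.read_end}))
    return _merge_duplications(per_read)


def _merge_duplications(calls: list[SVCall]) -> list[SVCall]:
    """Single-linkage clustering of per-read duplications by reference overlap."""
    by_chrom: dict[str, list[SVCall]] = defaultdict(list)
    for c in calls:
        by_chrom[c.chrom1].append(c)
    merged: list[SVCall] = []
    for chrom, group in by_chrom.items():
        group.sort(key=lambda c: (c.pos1, c.pos2))
        cluster: list[SVCall] = []
        reach = -1
        for c in group:
            if cluster and c.pos1 >= reach:
                merged.append(_fuse_duplication(cluster))
                cluster = []
            cluster.append(c)
            reach = max(reach, c.pos2)
        if cluster:
            merged.append(_fuse_duplication(cluster))
    return merged


def _fuse_duplication(cluster: list[SVCall]) -> SVCall:
    """Merged interval is the union of the per-read overlaps: each read's
    alignment overlap is a (possibly end-truncated) sub-interval of the true
    duplicated span, so the union is its best estimate."""
    if len(cluster) == 1:
        return cluster[0]
    s = min(c.pos1 for c in cluster)
    e = max(c.pos2 for c in cluster)
    out = SVCall(LOCAL_DUPLICATION, cluster[0].chrom1, s, cluster[0].strand1,
                 cluster[0].chrom1, e, cluster[0].strand2,
                 duplicated_interval=GenomeInterval(cluster[0].chrom1, s,
                                                    max(e, s + 1)))
    for c in cluster:
        out.source_reads |= c.source_reads
        out.read_breakpoints.update(c.read_breakpoints)
    return out


def call_rearrangements(acs: Sequence[AnchorCluster],
                        cfg: ThresholdConfig | None = None) -> list[SVCall]:
    """Rearrangements between consecutive ACs on a read when both span > 3 kbp."""
    cfg = cfg or ThresholdConfig()
    by_read: dict[str, list[AnchorCluster]] = defaultdict(list)
    for ac in acs:
        by_read[ac.read_id].append(ac)
    calls = []
    for read_id, group in by_read.items():
        group.sort(key=lambda a: a.read_start)
        for a, b in zip(group, group[1:]):
            if a.span_len <= cfg.ac_min_span or b.span_len <= cfg.ac_min_span:
                continue
            # facing ends in read direction
            p1 = a.ref_end if a.strand == "+" else a.ref_start
            p2 = b.ref_start if b.strand == "+" else b.ref_end
            c1, p1, s1, c2, p2, s2 = _ordered_breakpoints(
                a.chrom, p1, a.strand, b.chrom, p2, b.strand)
            calls.append(SVCall(
                REARRANGEMENT, c1, p1, s1, c2, p2, s2,
                source_reads={read_id},
                read_breakpoints={read_id: (a.read_end + b.read_start) // 2}))
    return calls


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def _weighted_median(values: list[int], weights: list[int]) -> int:
    order = np.argsort(values)
    v = np.asarray(values)[order]
    w = np.asarray(weights, dtype=float)[order]
    cum = np.cumsum(w)
    return int(v[np.searchsorted(cum, cum[-1] / 2.0)])


def cluster_calls(calls: Sequence[SVCall],
                  cfg: ThresholdConfig | None = None) -> list[SVCall]:
    """Single-linkage redundancy clustering, iterated to a fixed point.

    Two calls merge iff both breakpoints lie within the cluster window
    (500 bp) and strands match at both breakpoints; merged breakpoints are
    support-weighted medians and source reads are unioned. Passes repeat
    until no further merges occur so the operation is idempotent.
    """
    cfg = cfg or ThresholdConfig()
    out = list(calls)
    while True:
        merged = _cluster_pass(out, cfg)
        if len(merged) == len(out):
            out = merged
            break
        out = merged
    for i, c in enumerate(sorted(out, key=lambda c: (c.chrom1, c.pos1,
                                                     c.chrom2, c.pos2))):
        c.cluster_id = i
    return sorted(out, key=lambda c: c.cluster_id)


def _cluster_pass(calls: Sequence[SVCall], cfg: ThresholdConfig) -> list[SVCall]:
    win = cfg.call_cluster_window
    groups: dict[tuple, list[SVCall]] = defaultdict(list)
    for c in calls:
        groups[(c.call_type, c.chrom1, c.chrom2, c.strand1, c.strand2)].append(c)
    out: list[SVCall] = []
    for group in groups.values():
        group.sort(key=lambda c: (c.pos1, c.pos2))
        n = len(group)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if group[j].pos1 - group[i].pos1 > win:
                    break
                if abs(group[j].pos2 - group[i].pos2) <= win:
                    parent[find(i)] = find(j)
        clusters: dict[int, list[SVCall]] = defaultdict(list)
        for i in range(n):
            clusters[find(i)].append(group[i])
        for members in clusters.values():
            out.append(_fuse_calls(members))
    return out


def _fuse_calls(members: list[SVCall]) -> SVCall:
    if len(members) == 1:
        m = members[0]
        return m
    w = [max(1, len(m.source_reads)) for m in members]
    pos1 = _weighted_median([m.pos1 for m in members], w)
    pos2 = _weighted_median([m.pos2 for m in members], w)
    ref = members[0]
    out = SVCall(ref.call_type, ref.chrom1, pos1, ref.strand1,
                 ref.chrom2, pos2, ref.strand2)
    comp: dict[str, int] = defaultdict(int)
    total_len = 0
    for m in members:
        out.source_reads |= m.source_reads
        out.read_breakpoints.update(m.read_breakpoints)
        total_len += m.insertion_len
        for k, v in m.junction_composition.items():
            comp[k] += v
    if ref.call_type == INSERTION:
        out.insertion_len = _weighted_median(
            [m.insertion_len for m in members], w)
        scale = out.insertion_len / total_len if total_len else 0.0
        out.junction_composition = {k: int(round(v * scale))
                                    for k, v in comp.items()}
    if ref.call_type == LOCAL_DUPLICATION:
        ivs = [m.duplicated_interval for m in members if m.duplicated_interval]
        if ivs:
            s = min(iv.start for iv in ivs)
            e = max(iv.end for iv in ivs)
            out.duplicated_interval = GenomeInterval(ref.chrom1, s, max(e, s + 1))
    return out


# ---------------------------------------------------------------------------
# Support counting and filtering
# ---------------------------------------------------------------------------

class AvaIndex:
    """Mappings of other reads projected onto each read's own coordinates."""

    def __init__(self, ava: Iterable[AvaMapping]):
        self._onto: dict[str, list[tuple[str, int, int]]] = defaultdict(list)
        for m in ava:
            self._onto[m.target_id].append((m.query_id, m.target_start,
                                            m.target_end))
            self._onto[m.query_id].append((m.target_id, m.query_start,
                                           m.query_end))

    def onto(self, read_id: str) -> list[tuple[str, int, int]]:
        return self._onto.get(read_id, [])


def count_support(call: SVCall,
                  containment: Mapping[str, ContainmentResult],
                  ava: AvaIndex,
                  cfg: ThresholdConfig | None = None) -> int:
    """Distinct reads backing the call: its informative source reads plus
    contained reads whose mapping onto a source read spans the breakpoint
    position on that read with at least the span margin on each side."""
    cfg = cfg or ThresholdConfig()
    margin = cfg.support_span_margin
    supporting = set(call.source_reads)
    for rid, pos in call.read_breakpoints.items():
        for other, s, e in ava.onto(rid):
            if other in supporting:
                continue
            res = containment.get(other)
            if res is None or res.status != CONTAINED:
                continue
            if s <= pos - margin and e >= pos + margin:
                supporting.add(other)
    call.support = len(supporting)
    return call.support


def filter_calls(calls: Sequence[SVCall],
                 cfg: ThresholdConfig | None = None) -> list[SVCall]:
    """Low-frequency filter: keep calls with > 2 informative reads AND
    > 3 read support (strict inequalities)."""
    cfg = cfg or ThresholdConfig()
    return [c for c in calls
            if c.informative_reads > cfg.min_informative_reads
            and c.support > cfg.min_read_support]


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

_LENGTH_BINS = [(1_000, "<1 kbp"), (10_000, "1-10 kbp"),
                (100_000, "10-100 kbp"), (float("inf"), ">100 kbp")]
_DIST_BINS = [(1_000, "<1 kbp"), (10_000, "1-10 kbp"),
              (100_000, "10-100 kbp"), (1_000_000, "100 kbp-1 Mbp"),
              (float("inf"), ">1 Mbp")]

EVENT_REPETITIVE_INDEL = "repetitive_indel_gt1kbp"
EVENT_SHORT_INDEL = "short_indel"
EVENT_LOCAL_DUP = "local_duplication"
EVENT_UNCLASSIFIED = "unclassified"


def _bin_label(value: float, bins) -> str:
    for bound, label in bins:
        if value < bound:
            return label
    return bins[-1][1]


def classify_strandedness(call: SVCall) -> str:
    """Maintained iff both breakpoint strands are equal (a change of strand
    means an inversion happened)."""
    return MAINTAINED if call.strand1 == call.strand2 else CHANGED


def _junction_repeat_bp(call: SVCall) -> int:
    return sum(bp for name, bp in call.junction_composition.items()
               if name not in ("unaligned", "unannotated"))


def classify_calls(calls: Sequence[SVCall], repeats: RepeatIndex,
                   cfg: ThresholdConfig | None = None) -> list[SVCall]:
    """Assign length/repeat/distance bins, element labels, full-length flags
    and the event taxonomy.

    An insertion gets an element label when a single repeat element accounts
    for more than 90% of the inserted sequence; the four most abundant
    element classes across the cohort are kept and the rest pooled as
    'Other'. The full-length flag is set when the insertion is 90-110% of
    the element's library length.
    """
    import warnings

    cfg = cfg or ThresholdConfig()
    for c in calls:
        dist = c.breakpoint_distance
        c.distance_class = TRANS if dist is None else _bin_label(dist, _DIST_BINS)
        if c.call_type == INSERTION:
            c.length_class = _bin_label(c.insertion_len, _LENGTH_BINS)
            rep_bp = _junction_repeat_bp(c)
            c.repeat_fraction = rep_bp / c.insertion_len if c.insertion_len else 0.0
            q = min(3, int(c.repeat_fraction * 4))
            c.repeat_class = f"{q * 25}-{(q + 1) * 25}%"
            best, best_bp = "", 0
            for name, bp in c.junction_composition.items():
                if name in ("unaligned", "unannotated"):
                    continue
                if bp > best_bp:
                    best, best_bp = name, bp
            if c.insertion_len and best_bp > cfg.element_purity * c.insertion_len:
                c.element = best
                c.element_class = repeats.classes.get(best, best)
                lib = repeats.library.get(best)
                if lib:
                    c.full_length = 0.9 * lib <= c.insertion_len <= 1.1 * lib
                else:
                    warnings.warn(f"no library length for element {best}; "
                                  "full-length flag unset")
            # event taxonomy
            if c.insertion_len < 1_000:
                c.event_class = EVENT_SHORT_INDEL
            elif c.repeat_fraction > 0.5:
                c.event_class = EVENT_REPETITIVE_INDEL
            else:
                c.event_class = EVENT_UNCLASSIFIED
        elif c.call_type == LOCAL_DUPLICATION:
            c.event_class = EVENT_LOCAL_DUP
        else:
            # rearrangement: a maintained-strand intra-chromosomal call whose
            # skipped reference is mostly repetitive is a repetitive deletion
            if (dist is not None and classify_strandedness(c) == MAINTAINED
                    and dist > 0
                    and repeats.fraction(c.chrom1, min(c.pos1, c.pos2),
                                         max(c.pos1, c.pos2)) > 0.5):
                c.event_class = (EVENT_REPETITIVE_INDEL if dist >= 1_000
                                 else EVENT_SHORT_INDEL)
            else:
                c.event_class = EVENT_UNCLASSIFIED
    # pool element classes: keep the four most abundant, rest -> Other
    counts = Counter(c.element_class for c in calls if c.element_class)
    top4 = {name for name, _ in counts.most_common(4)}
    for c in calls:
        if c.element_class:
            c.element_class_pooled = (c.element_class if c.element_class in top4
                                      else "Other")
    return list(calls)


def insertion_density_track(calls: Sequence[SVCall], repeats: RepeatIndex,
                            chrom_lengths: Mapping[str, int],
                            cfg: ThresholdConfig | None = None,
                            element_class: str | None = None
                            ) -> dict[str, np.ndarray]:
    """Repetitive-insertion counts per 100 kbp window.

    Qualifying insertions are > 1 kbp, > 70% repeat-annotated, and > 90% of
    the repeat-annotated sequence belongs to a single repeat class; an
    optional element_class restricts the track to that class.
    """
    cfg = cfg or ThresholdConfig()
    win = cfg.density_window
    track = {chrom: np.zeros(-(-length // win), dtype=int)
             for chrom, length in chrom_lengths.items()}
    for c in calls:
        if c.call_type != INSERTION or c.insertion_len <= cfg.density_min_len:
            continue
        rep_bp = _junction_repeat_bp(c)
        if rep_bp <= cfg.density_repeat_fraction * c.insertion_len:
            continue
        by_class: dict[str, int] = defaultdict(int)
        for name, bp in c.junction_composition.items():
            if name in ("unaligned", "unannotated"):
                continue
            by_class[repeats.classes.get(name, name)] += bp
        if not by_class:
            continue
        top_class, top_bp = max(by_class.items(), key=lambda kv: kv[1])
        if top_bp <= cfg.element_purity * rep_bp:
            continue
        if element_class is not None and top_class != element_class:
            continue
        if c.chrom1 in track:
            track[c.chrom1][min(c.midpoint // win, len(track[c.chrom1]) - 1)] += 1
    return track


def density_track_bedgraph(track: Mapping[str, np.ndarray],
                           cfg: ThresholdConfig | None = None):
    cfg = cfg or ThresholdConfig()
    win = cfg.density_window
    for chrom in sorted(track):
        for i, v in enumerate(track[chrom]):
            yield chrom, i * win, (i + 1) * win, float(v)


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

def run_calling_pipeline(ref_alignments: Sequence[RefAlignment],
                         ava: Sequence[AvaMapping],
                         read_lengths: Mapping[str, int],
                         repeats: RepeatIndex,
                         cfg: ThresholdConfig | None = None):
    """Full calling flow: containment, per-read layout, call emission,
    clustering, support counting, filtering, classification.

    Returns (filtered_calls, raw_clustered_calls, containment, acs).
    """
    cfg = cfg or ThresholdConfig()
    cont = classify_reads(read_lengths, ava, cfg)
    informative = informative_ids(cont)
    by_read: dict[str, list[RefAlignment]] = defaultdict(list)
    for a in ref_alignments:
        if a.read_id in informative:
            by_read[a.read_id].append(a)
    all_acs: list[AnchorCluster] = []
    raw: list[SVCall] = []
    for read_id, alns in by_read.items():
        _, acs, junctions = layout_read(alns, repeats, cfg)
        all_acs.extend(acs)
        raw.extend(call_insertions(acs, junctions, cfg))
        raw.extend(call_rearrangements(acs, cfg))
    raw.extend(call_local_duplications(all_acs, cfg))
    clustered = cluster_calls(raw, cfg)
    index = AvaIndex(ava)
    for c in clustered:
        count_support(c, cont, index, cfg)
    kept = filter_calls(clustered, cfg)
    classify_calls(kept, repeats, cfg)
    return kept, clustered, cont, all_acs


# ---------------------------------------------------------------------------
# Output table
# ---------------------------------------------------------------------------

CALL_COLUMNS = ["type", "chrom1", "pos1", "strand1", "chrom2", "pos2",
                "strand2", "insertion_len", "element", "informative_reads",
                "support", "cluster_id", "event_class", "distance_class",
                "strandedness"]


def calls_to_table(calls: Sequence[SVCall]):
    import pandas as pd

    rows = [[c.call_type, c.chrom1, c.pos1, c.strand1, c.chrom2, c.pos2,
             c.strand2, c.insertion_len, c.element or ".",
             c.informative_reads, c.support, c.cluster_id,
             c.event_class or ".", c.distance_class or ".",
             c.strandedness] for c in calls]
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def write_calls_tsv(calls: Sequence[SVCall], path) -> None:
    calls_to_table(calls).to_csv(path, sep="\t", index=False)


def write_bedpe(calls: Sequence[SVCall], path) -> None:
    with open(path, "w") as fh:
        for c in calls:
            fh.write("\t".join(map(str, [
                c.chrom1, c.pos1, c.pos1 + 1, c.chrom2, c.pos2, c.pos2 + 1,
                f"{c.call_type}_{c.cluster_id}", c.support,
                c.strand1, c.strand2])) + "\n")
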