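"""Segment graph of a rearranged genome, exported as GFA 1.0.

Rearrangement calls with reference breakpoints more than 100 kbp apart (or
on different chromosomes) split the reference into segments; each such call
contributes an SV edge between the facing segment ends. A reference edge
re-connects two adjacent segments when at least three reads carry both
within a single adjacent cluster, i.e. traverse the split point without a
rearrangement.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .formats_io import GenomeInterval, ThresholdConfig, write_gfa
from .read_layout import AnchorCluster
from .sv_calls import SVCall


@dataclass
class GraphEdge:
    from_segment: str
    from_orient: str
    to_segment: str
    to_orient: str
    kind: str                 # "sv" | "ref"
    reads: int = 0
    call: SVCall | None = None


@dataclass
class GenomeGraph:
    segments: list[GenomeInterval] = field(default_factory=list)
    sv_edges: list[GraphEdge] = field(default_factory=list)
    ref_edges: list[GraphEdge] = field(default_factory=list)

    @staticmethod
    def segment_name(iv: GenomeInterval) -> str:
        return f"{iv.chrom}:{iv.start}-{iv.end}"

    @property
    def edges(self) -> list[GraphEdge]:
        return self.sv_edges + self.ref_edges


def _merge_split_points(points: list[int], window: int) -> list[int]:
    """Collapse split points within the cluster window into their median."""
    if not points:
        return []
    points = sorted(points)
    merged, cluster = [], [points[0]]
    for p in points[1:]:
        if p - cluster[-1] <= window:
            cluster.append(p)
        else:
            merged.append(int(np.median(cluster)))
            cluster = [p]
    merged.append(int(np.median(cluster)))
    return merged


def build_graph(calls: Sequence[SVCall],
                chrom_lengths: Mapping[str, int],
                acs: Sequence[AnchorCluster] = (),
                cfg: ThresholdConfig | None = None) -> GenomeGraph:
    """Split chromosomes at large-scale call breakpoints and wire the edges.

    Split points come from calls whose breakpoint distance exceeds 100 kbp
    or is trans-chromosomal; split points within 500 bp are merged to avoid
    sliver segments. Reference edges require >= 3 distinct reads whose
    single AC spans the split point.
    """
    cfg = cfg or ThresholdConfig()
    large = [c for c in calls
             if c.breakpoint_distance is None
             or c.breakpoint_distance > cfg.large_sv_distance]
    raw_points: dict[str, list[int]] = defaultdict(list)
    for c in large:
        for chrom, pos in ((c.chrom1, c.pos1), (c.chrom2, c.pos2)):
            if chrom not in chrom_lengths:
                raise ValueError(f"call breakpoint on unknown chromosome "
                                 f"{chrom}")
            if pos > chrom_lengths[chrom]:
                raise ValueError(f"breakpoint {chrom}:{pos} beyond "
                                 f"chromosome end {chrom_lengths[chrom]}")
            raw_points[chrom].append(pos)

    splits = {chrom: _merge_split_points(pts, cfg.call_cluster_window)
              for chrom, pts in raw_points.items()}
    # drop splits at the very chromosome boundaries
    for chrom in list(splits):
        splits[chrom] = [p for p in splits[chrom]
                         if 0 < p < chrom_lengths[chrom]]

    graph = GenomeGraph()
    seg_ending_at: dict[tuple[str, int], GenomeInterval] = {}
    seg_starting_at: dict[tuple[str, int], GenomeInterval] = {}
    for chrom in sorted(chrom_lengths):
        bounds = [0] + splits.get(chrom, []) + [chrom_lengths[chrom]]
        for s, e in zip(bounds, bounds[1:]):
            seg = GenomeInterval(chrom, s, e)
            graph.segments.append(seg)
            seg_starting_at[(chrom, s)] = seg
            seg_ending_at[(chrom, e)] = seg

    def snap(chrom: str, pos: int) -> int:
        pts = splits.get(chrom, [])
        if not pts:
            return pos
        return min(pts, key=lambda p: abs(p - pos))

    for c in large:
        p1, p2 = snap(c.chrom1, c.pos1), snap(c.chrom2, c.pos2)
        if c.strand1 == "+":
            a = seg_ending_at.get((c.chrom1, p1))
            ao = "+"
        else:
            a = seg_starting_at.get((c.chrom1, p1))
            ao = "-"
        if c.strand2 == "+":
            b = seg_starting_at.get((c.chrom2, p2))
            bo = "+"
        else:
            b = seg_ending_at.get((c.chrom2, p2))
            bo = "-"
        if a is None or b is None:
            continue
        graph.sv_edges.append(GraphEdge(
            GenomeGraph.segment_name(a), ao,
            GenomeGraph.segment_name(b), bo, "sv",
            reads=len(c.source_reads), call=c))

    # reference edges: reads whose single AC spans a split point
    ac_by_chrom: dict[str, list[AnchorCluster]] = defaultdict(list)
    for ac in acs:
        ac_by_chrom[ac.chrom].append(ac)
    for chrom, pts in splits.items():
        for p in pts:
            readers = {ac.read_id for ac in ac_by_chrom.get(chrom, [])
                       if ac.ref_start < p < ac.ref_end}
            if len(readers) >= cfg.ref_edge_min_reads:
                a = seg_ending_at[(chrom, p)]
                b = seg_starting_at[(chrom, p)]
                graph.ref_edges.append(GraphEdge(
                    GenomeGraph.segment_name(a), "+",
                    GenomeGraph.segment_name(b), "+", "ref",
                    reads=len(readers)))
    return graph


def export_gfa(graph: GenomeGraph, path) -> None:
    """One S-line per segment (name chrom:start-end, LN tag), one L-line per
    edge with orientations from the call strands."""
    segments = [(GenomeGraph.segment_name(s), len(s)) for s in graph.segments]
    links = [(e.from_segment, e.from_orient, e.to_segment, e.to_orient)
             for e in graph.edges]
    write_gfa(segments, links, path)
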