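"""Short-read comparative layer: duplication signatures, copy gains, bin matrices.

A tandem duplication leaves a diagnostic 'everted' read-pair signature in
paired-end data: mates 5-50 kbp apart with the forward-mapped mate downstream
of its reverse-mapped partner. Signature pairs are clustered (within 3 kbp,
spans > 80% similar) into duplication calls requiring >= 4 supporting pairs.
Copy-number gains are calls >= 150% of the arm basal ploidy (the median of
calls in [1,8]). Per-sample events (SNPs, TE insertions, duplications,
gains) are binarised into 1 kbp genome bins for cross-sample phylogeny.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .formats_io import SNPRecord, ThresholdConfig


@dataclass
class MateAlignment:
    chrom: str
    start: int
    end: int
    strand: str
    match_fraction: float = 1.0
    repeat_fraction: float = 0.0
    read_len: int = 0

    def __post_init__(self):
        if self.read_len == 0:
            self.read_len = self.end - self.start

    @property
    def aligned_fraction(self) -> float:
        return (self.end - self.start) / self.read_len if self.read_len else 0.0


@dataclass
class PairRecord:
    mate1: MateAlignment
    mate2: MateAlignment

    @property
    def same_chrom(self) -> bool:
        return self.mate1.chrom == self.mate2.chrom

    @property
    def separation(self) -> int:
        """Distance between outermost mate coordinates."""
        return (max(self.mate1.end, self.mate2.end)
                - min(self.mate1.start, self.mate2.start))

    @property
    def span_start(self) -> int:
        return min(self.mate1.start, self.mate2.start)

    @property
    def span_end(self) -> int:
        return max(self.mate1.end, self.mate2.end)


@dataclass
class DupSignatureCall:
    chrom: str
    start: int
    end: int
    support: int
    pairs: list[PairRecord] = field(default_factory=list)


def classify_pair(pair: PairRecord,
                  cfg: ThresholdConfig | None = None) -> bool:
    """True iff the pair carries a local-duplication signature.

    All four criteria must hold: (1) mates 5-50 kbp apart (closed interval,
    outermost coordinates), (2) both mates > 95% matched, (3) both mates
    < 70% repeat-annotated, (4) everted orientation — a forward-mapped first
    mate expects its partner reverse-mapped and upstream, a reverse-mapped
    first mate expects its partner forward-mapped and downstream.
    """
    cfg = cfg or ThresholdConfig()
    m1, m2 = pair.mate1, pair.mate2
    if not pair.same_chrom:
        return False
    if not (cfg.pair_sep_min <= pair.separation <= cfg.pair_sep_max):
        return False
    if not (m1.match_fraction > cfg.pair_match_fraction
            and m2.match_fraction > cfg.pair_match_fraction):
        return False
    if not (m1.repeat_fraction < cfg.pair_repeat_max
            and m2.repeat_fraction < cfg.pair_repeat_max):
        return False
    if m1.strand == "+":
        return m2.strand == "-" and m2.start < m1.start
    if m1.strand == "-":
        return m2.strand == "+" and m2.start > m1.start
    return False


def cluster_and_filter_signatures(pairs: Sequence[PairRecord],
                                  cfg: ThresholdConfig | None = None
                                  ) -> list[DupSignatureCall]:
    """Single-linkage clustering of signature pairs into duplication calls.

    Two pairs link when their spans start within 3 kbp of each other, both
    mates of each are > 80% aligned, and the spans are > 80% similar
    (min/max of separations). Clusters with fewer than four pairs are
    dropped.
    """
    cfg = cfg or ThresholdConfig()
    eligible = [p for p in pairs
                if p.mate1.aligned_fraction > cfg.pair_aln_fraction
                and p.mate2.aligned_fraction > cfg.pair_aln_fraction]
    by_chrom: dict[str, list[PairRecord]] = defaultdict(list)
    for p in eligible:
        by_chrom[p.mate1.chrom].append(p)
    calls: list[DupSignatureCall] = []
    for chrom, group in by_chrom.items():
        group.sort(key=lambda p: p.span_start)
        n = len(group)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if group[j].span_start - group[i].span_start > cfg.pair_cluster_window:
                    break
                sa, sb = group[i].separation, group[j].separation
                if min(sa, sb) / max(sa, sb) > cfg.pair_span_similarity:
                    parent[find(i)] = find(j)
        clusters: dict[int, list[PairRecord]] = defaultdict(list)
        for i in range(n):
            clusters[find(i)].append(group[i])
        for members in clusters.values():
            if len(members) < cfg.dup_min_pairs:
                continue
            calls.append(DupSignatureCall(
                chrom,
                int(np.median([p.span_start for p in members])),
                int(np.median([p.span_end for p in members])),
                len(members), members))
    calls.sort(key=lambda c: (c.chrom, c.start))
    return calls


# ---------------------------------------------------------------------------
# Copy-number gains
# ---------------------------------------------------------------------------

@dataclass
class CNSegment:
    chrom: str
    start: int
    end: int
    copy_number: float
    gain: bool = False


def copy_gain_classify(cn_calls: Sequence[CNSegment],
                       cfg: ThresholdConfig | None = None
                       ) -> dict[str, float]:
    """Flag copy-number gains per chromosome arm.

    Basal arm ploidy is the median of copy-number calls with values in
    [1,8]; a call is a gain when it reaches 150% of the basal. Returns the
    per-arm basal map; gain flags are set on the segments in place.
    """
    cfg = cfg or ThresholdConfig()
    by_arm: dict[str, list[float]] = defaultdict(list)
    for c in cn_calls:
        if 1 <= c.copy_number <= 8:
            by_arm[c.chrom].append(c.copy_number)
    basal = {arm: float(np.median(vals)) for arm, vals in by_arm.items()}
    for c in cn_calls:
        if c.chrom not in basal:
            warnings.warn(f"no copy-number calls in [1,8] on {c.chrom}; "
                          "arm skipped")
            c.gain = False
            continue
        c.gain = c.copy_number >= cfg.cn_gain_fraction * basal[c.chrom]
    return basal


# ---------------------------------------------------------------------------
# Binary bin matrices
# ---------------------------------------------------------------------------

def build_bin_matrix(events: Mapping[str, Iterable[tuple[str, int]]],
                     chrom_lengths: Mapping[str, int],
                     cfg: ThresholdConfig | None = None) -> pd.DataFrame:
    """Samples x 1 kbp-bin presence/absence matrix.

    Cell (s, b) is 1 iff sample s has a qualifying event in bin b; bins with
    no event in any sample are not emitted (all-zero columns dropped).
    """
    cfg = cfg or ThresholdConfig()
    bs = cfg.binmat_bin
    samples = sorted(events)
    cells: dict[str, set[str]] = {s: set() for s in samples}
    bins: set[str] = set()
    for sample, evs in events.items():
        for chrom, pos in evs:
            if chrom not in chrom_lengths:
                raise ValueError(f"event on unknown chromosome {chrom}")
            if pos >= chrom_lengths[chrom] or pos < 0:
                raise ValueError(f"event {chrom}:{pos} beyond chromosome end")
            key = f"{chrom}:{(pos // bs) * bs}"
            cells[sample].add(key)
            bins.add(key)
    cols = sorted(bins, key=lambda k: (k.split(":")[0], int(k.split(":")[1])))
    data = np.zeros((len(samples), len(cols)), dtype=int)
    for i, s in enumerate(samples):
        for j, b in enumerate(cols):
            if b in cells[s]:
                data[i, j] = 1
    return pd.DataFrame(data, index=samples, columns=cols)


def snp_matrix_events(per_sample: Mapping[str, Sequence[SNPRecord]],
                      cfg: ThresholdConfig | None = None
                      ) -> dict[str, list[tuple[str, int]]]:
    """SNP events for the bin matrix.

    A SNP site qualifies when it has at least 3 supporting reads in any
    sample and is less than 10% repeat-annotated; it is present in a sample
    when that sample's support fraction exceeds 50%.
    """
    cfg = cfg or ThresholdConfig()
    qualifying: set[tuple[str, int]] = set()
    for snps in per_sample.values():
        for s in snps:
            if (s.alt_support >= cfg.snp_min_support
                    and s.repeat_fraction < cfg.snp_repeat_max):
                qualifying.add((s.chrom, s.pos))
    events: dict[str, list[tuple[str, int]]] = {}
    for sample, snps in per_sample.items():
        events[sample] = [
            (s.chrom, s.pos) for s in snps
            if (s.chrom, s.pos) in qualifying
            and s.support_fraction > cfg.snp_presence_fraction]
    return events


def te_matrix_events(per_sample: Mapping[str, Sequence],
                     cfg: ThresholdConfig | None = None,
                     min_support: int = 2) -> dict[str, list[tuple[str, int]]]:
    """TE-insertion events: calls with at least 2 supporting reads."""
    return {sample: [(t.chrom, t.pos) for t in calls
                     if t.support >= min_support]
            for sample, calls in per_sample.items()}


def subsample_pairs(pairs: Sequence[PairRecord], fraction: float,
                    seed: int = 0) -> list[PairRecord]:
    """Seeded down-sampling used to equalise coverage across samples."""
    rng = np.random.default_rng(seed)
    keep = rng.random(len(pairs)) < fraction
    return [p for p, k in zip(pairs, keep) if k]
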