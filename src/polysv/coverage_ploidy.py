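"""Bin coverage, copy number, tetraploidy tests, SNP classes, gene status.

The genome is tiled into 50 bp bins; bin copy number is depth divided by the
per-copy depth of the chromosome arm (arm mean depth / arm basal ploidy:
4 for autosomes, 2 for the diploid X). Tetraploidy of a locus is tested on
the mean depth of a 3 kbp window against 87.5-112.5% of the autosome
average. SNP haplotype-frequency classes follow right-closed support-fraction
intervals; genes are classified gained or disrupted from coverage and call
breakpoints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .formats_io import GeneModel, RefAlignment, SNPRecord, ThresholdConfig
from .read_layout import RepeatIndex

EXCLUDED = "excluded"
SNP_CLASSES = ("<1", "1", "2", "3", ">3")


def default_ploidy(chrom: str) -> int:
    """Basal ploidy by chromosome name: diploid X, tetraploid autosomes."""
    low = chrom.lower().lstrip("chr")
    if low in ("x",):
        return 2
    if low.startswith(("m", "mito")):
        return 1
    return 4


def is_autosome(chrom: str) -> bool:
    low = chrom.lower().lstrip("chr")
    return not (low in ("x", "y") or low.startswith(("m", "mito")))


# ---------------------------------------------------------------------------
# Coverage track
# ---------------------------------------------------------------------------

@dataclass
class CoverageTrack:
    bin_size: int
    chrom_lengths: dict[str, int]
    depth: dict[str, np.ndarray]                 # per-bin mean depth
    ploidy: dict[str, int] = field(default_factory=dict)
    depth_bp: dict[str, np.ndarray] | None = None  # per-bp depth when available

    def __post_init__(self):
        for chrom in self.chrom_lengths:
            self.ploidy.setdefault(chrom, default_ploidy(chrom))

    def chrom_mean(self, chrom: str) -> float:
        return float(self.depth[chrom].mean()) if len(self.depth[chrom]) else 0.0

    @property
    def autosome_mean(self) -> float:
        depths = [self.depth[c] for c in self.depth if is_autosome(c)]
        if not depths:
            raise ValueError("no autosomes in coverage track")
        return float(np.concatenate(depths).mean())

    def per_copy_depth(self, chrom: str) -> float:
        mean = self.chrom_mean(chrom)
        if mean == 0:
            raise ValueError(f"zero mean coverage on {chrom}")
        return mean / self.ploidy[chrom]

    def copy_number(self, chrom: str) -> np.ndarray:
        """Per-bin copy number: depth rounded on the per-copy scale."""
        return np.rint(self.depth[chrom] / self.per_copy_depth(chrom)).astype(int)

    def window_mean(self, chrom: str, start: int, end: int) -> float:
        b0 = max(0, start // self.bin_size)
        b1 = min(len(self.depth[chrom]), -(-end // self.bin_size))
        if b1 <= b0:
            return 0.0
        return float(self.depth[chrom][b0:b1].mean())

    def to_bedgraph(self) -> Iterable[tuple[str, int, int, float]]:
        for chrom in sorted(self.depth):
            arr = self.depth[chrom]
            length = self.chrom_lengths[chrom]
            for i, v in enumerate(arr):
                yield chrom, i * self.bin_size, min((i + 1) * self.bin_size,
                                                    length), float(v)

    @property
    def total_mass(self) -> float:
        """Sum of depth x bin width; equals total aligned bases up to rounding."""
        total = 0.0
        for chrom, arr in self.depth.items():
            length = self.chrom_lengths[chrom]
            widths = np.full(len(arr), self.bin_size, dtype=float)
            if len(arr) and length % self.bin_size:
                widths[-1] = length % self.bin_size
            total += float((arr * widths).sum())
        return total


def bin_coverage(alignments: Sequence[RefAlignment] | None = None,
                 bedgraph: Iterable[tuple[str, int, int, float]] | None = None,
                 chrom_lengths: Mapping[str, int] | None = None,
                 ploidy: Mapping[str, int] | None = None,
                 cfg: ThresholdConfig | None = None) -> CoverageTrack:
    """Build a 50 bp-bin coverage track from alignments or a bedgraph."""
    cfg = cfg or ThresholdConfig()
    if chrom_lengths is None:
        raise ValueError("chrom_lengths required")
    bs = cfg.cn_bin
    depth_bp: dict[str, np.ndarray] = {}
    depth: dict[str, np.ndarray] = {}
    if alignments is not None:
        diff = {c: np.zeros(l + 1, dtype=np.int32)
                for c, l in chrom_lengths.items()}
        for a in alignments:
            t = a.target
            if t.chrom not in diff:
                continue
            s = max(0, t.start)
            e = min(chrom_lengths[t.chrom], t.end)
            if e > s:
                diff[t.chrom][s] += 1
                diff[t.chrom][e] -= 1
        for chrom, d in diff.items():
            bp = np.cumsum(d[:-1]).astype(np.float64)
            depth_bp[chrom] = bp
            nbins = -(-chrom_lengths[chrom] // bs)
            pad = nbins * bs - len(bp)
            padded = np.concatenate([bp, np.zeros(pad)]) if pad else bp
            sums = padded.reshape(nbins, bs).sum(axis=1)
            widths = np.full(nbins, bs, dtype=float)
            if chrom_lengths[chrom] % bs:
                widths[-1] = chrom_lengths[chrom] % bs
            depth[chrom] = sums / widths
    elif bedgraph is not None:
        acc = {c: np.zeros(-(-l // bs)) for c, l in chrom_lengths.items()}
        for chrom, s, e, v in bedgraph:
            if chrom not in acc:
                continue
            b0, b1 = s // bs, -(-e // bs)
            for b in range(b0, min(b1, len(acc[chrom]))):
                ov = min(e, (b + 1) * bs) - max(s, b * bs)
                acc[chrom][b] += v * ov / bs
        depth = acc
        depth_bp = None
    else:
        raise ValueError("either alignments or bedgraph required")
    track = CoverageTrack(bs, dict(chrom_lengths), depth,
                          dict(ploidy) if ploidy else {},
                          depth_bp=depth_bp or None)
    return track


# ---------------------------------------------------------------------------
# Coverage profile
# ---------------------------------------------------------------------------

def coverage_profile(track: CoverageTrack,
                     repeats: RepeatIndex | None = None,
                     cfg: ThresholdConfig | None = None
                     ) -> list[tuple[str, int, int, float, bool]]:
    """Median depth in 10 kbp sliding windows sampled every 1 kbp.

    Each entry is (chrom, step_start, step_end, window_median, repeat_flag);
    the flag marks windows more than 50% repeat-annotated, where coverage is
    not trusted for ploidy inference.
    """
    cfg = cfg or ThresholdConfig()
    step, win, bs = cfg.profile_step, cfg.profile_window, track.bin_size
    out = []
    for chrom in sorted(track.depth):
        length = track.chrom_lengths[chrom]
        arr = track.depth[chrom]
        for pos in range(0, length, step):
            ws = max(0, pos + step // 2 - win // 2)
            we = min(length, ws + win)
            b0, b1 = ws // bs, max(ws // bs + 1, -(-we // bs))
            med = float(np.median(arr[b0:min(b1, len(arr))]))
            flag = bool(repeats and
                        repeats.fraction(chrom, ws, we) > 0.5)
            out.append((chrom, pos, min(pos + step, length), med, flag))
    return out


# ---------------------------------------------------------------------------
# Tetraploidy test
# ---------------------------------------------------------------------------

def is_tetraploid_window(track: CoverageTrack, chrom: str, pos: int,
                         cfg: ThresholdConfig | None = None) -> bool:
    """True iff the mean depth of the 3 kbp window centered on pos lies in
    [87.5%, 112.5%] of the autosome average coverage (closed interval)."""
    cfg = cfg or ThresholdConfig()
    if chrom not in track.depth:
        raise ValueError(f"unknown chromosome {chrom}")
    half = cfg.tetraploid_window // 2
    ws, we = pos - half, pos + half
    length = track.chrom_lengths[chrom]
    if ws < 0 or we > length:
        warnings.warn(f"tetraploid window at {chrom}:{pos} truncated to "
                      "chromosome bounds")
        ws, we = max(0, ws), min(length, we)
    mean = track.window_mean(chrom, ws, we)
    auto = track.autosome_mean
    eps = 1e-9 * auto   # closed interval, robust to float accumulation
    return (cfg.tetraploid_low * auto - eps <= mean
            <= cfg.tetraploid_high * auto + eps)


# ---------------------------------------------------------------------------
# SNP haplotype-frequency classes
# ---------------------------------------------------------------------------

def snp_haplotype_class(snp: SNPRecord | float) -> str:
    """Classify a SNP's alternate-read support fraction into a haplotype
    frequency: <1 in (0,0.125], 1 in (0.125,0.375], 2 in (0.375,0.625],
    3 in (0.625,0.875], >3 in (0.875,1); a fraction of exactly 1 (all reads
    support the variant) is excluded as indistinguishable from a
    progenitor/reference difference."""
    frac = snp.support_fraction if isinstance(snp, SNPRecord) else float(snp)
    if frac < 0 or frac > 1:
        raise ValueError(f"support fraction {frac} outside [0,1]")
    if frac == 1 or frac == 0:
        return EXCLUDED
    if frac <= 0.125:
        return "<1"
    if frac <= 0.375:
        return "1"
    if frac <= 0.625:
        return "2"
    if frac <= 0.875:
        return "3"
    return ">3"


def select_tetraploid_snps(snps: Iterable[SNPRecord], track: CoverageTrack,
                           repeats: RepeatIndex | None = None,
                           cfg: ThresholdConfig | None = None
                           ) -> list[SNPRecord]:
    """SNPs in autosomal tetraploid-coverage windows, not repeat-annotated."""
    cfg = cfg or ThresholdConfig()
    out = []
    for s in snps:
        if s.chrom not in track.depth or not is_autosome(s.chrom):
            continue
        if repeats is not None:
            s.repeat_fraction = repeats.fraction(s.chrom, s.pos, s.pos + 1)
            if s.repeat_fraction > 0:
                continue
        if is_tetraploid_window(track, s.chrom, s.pos, cfg):
            out.append(s)
    return out


# ---------------------------------------------------------------------------
# Gene gain / disruption
# ---------------------------------------------------------------------------

@dataclass
class GeneStatus:
    gene_id: str
    copy_number: int
    status: str  # gained | disrupted | neutral


def _gene_regions(g: GeneModel, cfg: ThresholdConfig) -> list[tuple[int, int]]:
    """Disruption-sensitive regions: transcription start/stop windows, CDS,
    and the 1 kbp upstream of the transcription start (strand-aware)."""
    w = cfg.gene_flank_window
    up = cfg.gene_upstream
    if g.strand == "-":
        tss, tes = g.end, g.start
        upstream = (g.end, g.end + up)
    else:
        tss, tes = g.start, g.end
        upstream = (max(0, g.start - up), g.start)
    regions = [(max(0, tss - w), tss + w), (max(0, tes - w), tes + w),
               upstream]
    regions.extend(g.cds)
    return regions


def _zero_run_in(track: CoverageTrack, chrom: str, start: int, end: int,
                 min_run: int) -> bool:
    length = track.chrom_lengths.get(chrom, 0)
    start, end = max(0, start), min(length, end)
    if end <= start:
        return False
    if track.depth_bp is not None:
        seg = track.depth_bp[chrom][start:end]
        zero = np.concatenate([[False], seg == 0, [False]])
        edges = np.flatnonzero(np.diff(zero.astype(int)))
        runs = edges.reshape(-1, 2)
        return bool(len(runs) and (runs[:, 1] - runs[:, 0]).max() > min_run)
    # bin-resolution fallback: a zero bin is a >= bin_size zero run
    bs = track.bin_size
    seg = track.depth[chrom][start // bs: -(-end // bs)]
    return bool((seg == 0).any()) and bs > min_run


def gene_status(genes: Sequence[GeneModel], track: CoverageTrack,
                calls: Sequence, repeats: RepeatIndex | None = None,
                cfg: ThresholdConfig | None = None) -> list[GeneStatus]:
    """Classify genes as gained, disrupted, or neutral.

    Disruption: a rearrangement breakpoint supported by at least 10 reads,
    or a > 10 bp zero-coverage run, in the transcription start/stop windows,
    coding regions, or < 1 kbp upstream of the transcription start. Copy
    number: mean coverage over the gene omitting 50 bp bins that are >= 30%
    repeat-annotated, divided by the arm per-copy depth and rounded. Gain:
    not disrupted and copy number above the arm basal ploidy.
    """
    cfg = cfg or ThresholdConfig()
    # breakpoints of sufficiently supported calls
    bps: dict[str, list[int]] = {}
    for c in calls:
        if c.support >= cfg.disruption_min_reads:
            bps.setdefault(c.chrom1, []).append(c.pos1)
            bps.setdefault(c.chrom2, []).append(c.pos2)
    for v in bps.values():
        v.sort()
    out = []
    bs = track.bin_size
    for g in genes:
        if not g.cds:
            warnings.warn(f"gene {g.gene_id} has no CDS; skipped")
            continue
        if g.chrom not in track.depth:
            continue
        regions = _gene_regions(g, cfg)
        disrupted = False
        chrom_bps = bps.get(g.chrom, [])
        for rs, re_ in regions:
            i = np.searchsorted(chrom_bps, rs)
            if i < len(chrom_bps) and chrom_bps[i] < re_:
                disrupted = True
                break
            if _zero_run_in(track, g.chrom, rs, re_, cfg.zero_cov_min_run):
                disrupted = True
                break
        # copy number over non-repetitive gene bins
        b0, b1 = g.start // bs, -(-g.end // bs)
        b1 = min(b1, len(track.depth[g.chrom]))
        vals = []
        for b in range(b0, b1):
            if repeats is not None and repeats.fraction(
                    g.chrom, b * bs, (b + 1) * bs) >= cfg.gene_cn_repeat_omit:
                continue
            vals.append(track.depth[g.chrom][b])
        if not vals:
            warnings.warn(f"gene {g.gene_id} fully repeat-masked; skipped")
            continue
        cn = int(round(float(np.mean(vals)) / track.per_copy_depth(g.chrom)))
        if disrupted:
            status = "disrupted"
        elif cn > track.ploidy[g.chrom]:
            status = "gained"
        else:
            status = "neutral"
        out.append(GeneStatus(g.gene_id, cn, status))
    return out


def write_gene_table(statuses: Sequence[GeneStatus], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tcopy_number\tstatus\n")
        for s in statuses:
            fh.write(f"{s.gene_id}\t{s.copy_number}\t{s.status}\n")
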