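"""Synthetic tetraploid genomes with planted SVs and analytically exact reads.

The simulator emulates the study system: a small multi-chromosome genome
with two tetraploid autosomes, a diploid X and a mitochondrial contig;
annotated ancestral repeat copies (including a 7,469 bp Gypsy-like LTR
element); and planted events — full-length and truncated TE insertions at
haplotype frequencies 1-4 (1-2 on X), local tandem duplications, deletions,
inversions, reciprocal translocations and a mitochondrial-sequence
insertion. Long reads are sampled per haplotype and their reference and
all-vs-all alignments are computed analytically from the known event layout
(inserted sequence maps to its ancestral source copy), so every downstream
module is testable without an external aligner. A truth manifest records
each planted event for recall and haplotype-frequency scoring.

Per-haplotype read depth defaults to 44x so that per-haplotype breakpoint
support matches the published constant.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .formats_io import (AvaMapping, GeneModel, GenomeInterval, RefAlignment,
                         RepeatAnnotation)
from .read_layout import RepeatIndex
from .shortread_comparative import MateAlignment, PairRecord

TE_INSERTION = "te_insertion"
LOCAL_DUPLICATION = "local_duplication"
DELETION = "deletion"
INVERSION = "inversion"
TRANSLOCATION = "translocation"
MITO_INSERTION = "mito_insertion"


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def _default_chroms() -> dict[str, int]:
    return {"chr2": 2_000_000, "chr3": 2_000_000, "chrX": 1_000_000,
            "chrM": 19_000}


def _default_elements() -> list[tuple[str, str, int]]:
    return [("Gypsy", "LTR/Gypsy", 7_469),
            ("Copia", "LTR/Copia", 5_143),
            ("Roo", "LTR/Pao", 9_092),
            ("Jockey", "LINE/Jockey", 5_000),
            ("Pogo", "DNA/Pogo", 2_100)]


@dataclass
class SimConfig:
    chrom_lengths: dict[str, int] = field(default_factory=_default_chroms)
    elements: list[tuple[str, str, int]] = field(
        default_factory=_default_elements)
    ancestral_copies: int = 4         # full-length copies / element / chrom
    truncated_copies: int = 3
    # planted event counts
    n_te_insertions: int = 60
    n_duplications: int = 10
    n_translocations: int = 2
    # translocation breakpoints sit above baseline coverage in the study
    # system, so each reciprocal translocation is carried by this many
    # haplotypes by default
    translocation_haplotypes: int = 2
    n_deletions: int = 4
    n_inversions: int = 2
    n_mito_insertions: int = 1
    full_length_fraction: float = 0.5
    dup_len_range: tuple[int, int] = (5_000, 15_000)
    del_len_range: tuple[int, int] = (6_000, 12_000)
    inv_len_range: tuple[int, int] = (20_000, 40_000)
    mito_insert_len: int = 10_000
    # long reads
    per_haplotype_depth: float = 44.0
    read_len_log_mean: float = math.log(20_000)
    read_len_log_sigma: float = 0.5
    min_read_len: int = 1_000
    min_ava_overlap: int = 2_000
    # short-read pairs
    pair_read_len: int = 150
    pair_insert_mean: int = 600
    pair_insert_sd: int = 50
    pair_depth_per_hap: float = 6.0
    # genome decoration
    gene_spacing: int = 50_000
    gene_len: int = 4_000
    # event placement
    event_end_margin: int = 60_000
    event_spacing: int = 25_000
    event_clean_flank: int = 3_000
    seed: int = 0

    @property
    def ploidy(self) -> dict[str, int]:
        out = {}
        for c in self.chrom_lengths:
            low = c.lower().lstrip("chr")
            out[c] = 2 if low == "x" else (1 if low.startswith("m") else 4)
        return out

    @property
    def haplotypes_of(self) -> dict[str, list[int]]:
        return {c: list(range(1, (p if p > 1 else 4) + 1))
                if c.lower().lstrip("chr").startswith("m")
                else list(range(1, p + 1))
                for c, p in self.ploidy.items()}


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------

@dataclass
class Genome:
    config: SimConfig
    seqs: dict[str, str]
    repeats: list[RepeatAnnotation]
    genes: list[GeneModel]
    element_copies: dict[str, list[GenomeInterval]]  # full-length copies

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.config.chrom_lengths)

    def repeat_index(self) -> RepeatIndex:
        return RepeatIndex(self.repeats)


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, length)]


def generate_genome(cfg: SimConfig | None = None) -> Genome:
    """Random genome with annotated ancestral repeat copies and toy genes."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    for name, _, length in cfg.elements:
        if length >= min(cfg.chrom_lengths.values()):
            raise ValueError(f"element {name} longer than a chromosome")
    element_seqs = {name: _random_seq(rng, length)
                    for name, _, length in cfg.elements}
    classes = {name: klass for name, klass, _ in cfg.elements}
    lengths = {name: length for name, _, length in cfg.elements}

    seq_arrays: dict[str, np.ndarray] = {}
    repeats: list[RepeatAnnotation] = []
    copies: dict[str, list[GenomeInterval]] = {n: [] for n in element_seqs}
    for chrom, L in cfg.chrom_lengths.items():
        seq_arrays[chrom] = _random_seq(rng, L)
    for chrom, L in cfg.chrom_lengths.items():
        if chrom.lower().lstrip("chr").startswith("m"):
            continue
        occupied: list[tuple[int, int]] = []
        for name, _, elen in cfg.elements:
            for k in range(cfg.ancestral_copies + cfg.truncated_copies):
                full = k < cfg.ancestral_copies
                clen = elen if full else int(elen * rng.uniform(0.3, 0.8))
                for _ in range(200):
                    s = int(rng.integers(10_000, L - clen - 10_000))
                    if all(s + clen + 2_000 < os or s > oe + 2_000
                           for os, oe in occupied):
                        break
                else:
                    continue
                occupied.append((s, s + clen))
                seq_arrays[chrom][s:s + clen] = element_seqs[name][:clen]
                iv = GenomeInterval(chrom, s, s + clen)
                repeats.append(RepeatAnnotation(iv, name, classes[name],
                                                lengths[name]))
                if full:
                    copies[name].append(iv)

    genes: list[GeneModel] = []
    for chrom, L in cfg.chrom_lengths.items():
        if chrom.lower().lstrip("chr").startswith("m"):
            continue
        i = 0
        for g in range(cfg.gene_spacing, L - cfg.gene_len - cfg.gene_spacing,
                       cfg.gene_spacing):
            gid = f"{chrom}_g{i}"
            model = GeneModel(gid, chrom, g, g + cfg.gene_len, "+")
            model.cds = [(g + 500, g + 1_500), (g + 2_500, g + 3_500)]
            genes.append(model)
            i += 1

    seqs = {c: a.tobytes().decode() for c, a in seq_arrays.items()}
    return Genome(cfg, seqs, repeats, genes, copies)


# ---------------------------------------------------------------------------
# Event planting
# ---------------------------------------------------------------------------

@dataclass
class PlantedEvent:
    event_type: str
    chrom: str
    pos: int
    end: int = 0                      # for span events (dup/del/inv)
    element: str = ""
    length: int = 0
    haplotypes: frozenset[int] = frozenset()
    chrom2: str = ""
    pos2: int = 0
    source: GenomeInterval | None = None   # inserted-sequence origin

    @property
    def expected_frequency(self) -> int:
        return len(self.haplotypes)


@dataclass
class TruthManifest:
    events: list[PlantedEvent] = field(default_factory=list)

    def of_type(self, *types: str) -> list[PlantedEvent]:
        return [e for e in self.events if e.event_type in types]

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("type\tchrom\tpos\tend\telement\tlength\thaplotypes\t"
                     "chrom2\tpos2\n")
            for e in self.events:
                haps = ",".join(str(h) for h in sorted(e.haplotypes))
                fh.write(f"{e.event_type}\t{e.chrom}\t{e.pos}\t{e.end}\t"
                         f"{e.element or '.'}\t{e.length}\t{haps}\t"
                         f"{e.chrom2 or '.'}\t{e.pos2}\n")


@dataclass
class Segment:
    """A haplotype-sequence piece, pointing at its reference origin."""

    chrom: str
    start: int
    end: int
    orient: str = "+"

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class HaplotypeChrom:
    name: str
    hap: int
    segments: list[Segment]
    _cum: list[int] = field(default_factory=list)

    def __post_init__(self):
        self._cum = [0]
        for s in self.segments:
            self._cum.append(self._cum[-1] + len(s))

    @property
    def length(self) -> int:
        return self._cum[-1]

    def map_interval(self, a: int, b: int
                     ) -> list[tuple[int, int, str, int, int, str]]:
        """Map haplotype span [a,b) to (hap_s, hap_e, chrom, ref_s, ref_e,
        orient) pieces, in haplotype order."""
        out = []
        i = max(0, bisect_right(self._cum, a) - 1)
        while i < len(self.segments) and self._cum[i] < b:
            seg = self.segments[i]
            lo, hi = max(a, self._cum[i]), min(b, self._cum[i + 1])
            if hi > lo:
                off_lo, off_hi = lo - self._cum[i], hi - self._cum[i]
                if seg.orient == "+":
                    rs, re_ = seg.start + off_lo, seg.start + off_hi
                else:
                    rs, re_ = seg.end - off_hi, seg.end - off_lo
                out.append((lo, hi, seg.chrom, rs, re_, seg.orient))
            i += 1
        return out


def _sample_locus(rng, genome: Genome, cfg: SimConfig, chrom: str,
                  span: int, taken: list[tuple[str, int, int]],
                  rep_index: RepeatIndex,
                  clean_interior: bool = False) -> int | None:
    """A locus with repeat-free breakpoint flanks (so flanking alignments
    classify as anchors), away from other events and chromosome ends."""
    L = genome.chrom_lengths[chrom]
    w = cfg.event_clean_flank
    for _ in range(500):
        p = int(rng.integers(cfg.event_end_margin,
                             L - span - cfg.event_end_margin))
        if any(c == chrom and p - cfg.event_spacing < e
               and p + span + cfg.event_spacing > s
               for c, s, e in taken):
            continue
        if clean_interior:
            if rep_index.masked_bp(chrom, p - w, p + span + w):
                continue
        elif (rep_index.masked_bp(chrom, p - w, p + w)
                or rep_index.masked_bp(chrom, p + span - w, p + span + w)):
            continue
        return p
    return None


def _sample_hapset(rng, cfg: SimConfig, chrom: str) -> frozenset[int]:
    haps = cfg.haplotypes_of[chrom]
    f = int(rng.integers(1, len(haps) + 1))
    return frozenset(rng.choice(haps, size=f, replace=False).tolist())


def plant_events(genome: Genome, cfg: SimConfig | None = None
                 ) -> tuple[dict[int, dict[str, HaplotypeChrom]], TruthManifest]:
    """Apply planted events per haplotype; return haplotype chromosome maps
    (haplotype -> reference chromosome -> segment list) and the manifest."""
    cfg = cfg or genome.config
    rng = np.random.default_rng(cfg.seed + 1)
    rep_index = genome.repeat_index()
    manifest = TruthManifest()
    taken: list[tuple[str, int, int]] = []
    autosomes = [c for c in genome.chrom_lengths
                 if cfg.ploidy[c] == 4]
    te_chroms = [c for c in genome.chrom_lengths if cfg.ploidy[c] >= 2]
    te_weights = np.array([genome.chrom_lengths[c] for c in te_chroms],
                          dtype=float)
    te_weights /= te_weights.sum()
    mito = next((c for c in genome.chrom_lengths
                 if c.lower().lstrip("chr").startswith("m")), None)

    # translocations first (each on its own haplotype, autosome pair)
    translocs: list[tuple[str, int, str, int, int]] = []
    for t in range(cfg.n_translocations):
        cA, cB = rng.choice(autosomes, size=2, replace=False).tolist()
        LA, LB = genome.chrom_lengths[cA], genome.chrom_lengths[cB]
        pA = int(rng.integers(int(0.3 * LA), int(0.7 * LA)))
        pB = int(rng.integers(int(0.3 * LB), int(0.7 * LB)))
        # block-disjoint haplotype sets so two translocations never rebuild
        # the same haplotype chromosome
        haps = frozenset(1 + (t * cfg.translocation_haplotypes + i) % 4
                         for i in range(cfg.translocation_haplotypes))
        translocs.append((cA, pA, cB, pB, haps))
        taken.append((cA, pA - 50_000, pA + 50_000))
        taken.append((cB, pB - 50_000, pB + 50_000))
        manifest.events.append(PlantedEvent(
            TRANSLOCATION, cA, pA, haplotypes=haps, chrom2=cB, pos2=pB))

    def add_span_event(ev_type: str, lo: int, hi: int, chroms, n: int):
        for _ in range(n):
            chrom = str(rng.choice(chroms))
            span = int(rng.integers(lo, hi))
            p = _sample_locus(rng, genome, cfg, chrom, span, taken, rep_index,
                              clean_interior=(ev_type == DELETION))
            if p is None:
                continue
            taken.append((chrom, p, p + span))
            manifest.events.append(PlantedEvent(
                ev_type, chrom, p, end=p + span, length=span,
                haplotypes=_sample_hapset(rng, cfg, chrom)))

    # TE insertions; the full-length quota is fixed up front so the planted
    # full-length fraction matches the configured one up to rounding
    n_full = int(round(cfg.n_te_insertions * cfg.full_length_fraction))
    full_flags = np.array([True] * n_full
                          + [False] * (cfg.n_te_insertions - n_full))
    rng.shuffle(full_flags)
    for full in full_flags:
        chrom = str(rng.choice(te_chroms, p=te_weights))
        p = _sample_locus(rng, genome, cfg, chrom, 0, taken, rep_index)
        if p is None:
            continue
        name, klass, elen = cfg.elements[rng.integers(len(cfg.elements))]
        ilen = elen if full else max(1_200, int(elen * rng.uniform(0.3, 0.85)))
        options = genome.element_copies[name]
        copy = options[rng.integers(len(options))]
        taken.append((chrom, p, p))
        manifest.events.append(PlantedEvent(
            TE_INSERTION, chrom, p, element=name, length=ilen,
            haplotypes=_sample_hapset(rng, cfg, chrom),
            source=GenomeInterval(copy.chrom, copy.start, copy.start + ilen)))

    add_span_event(LOCAL_DUPLICATION, *cfg.dup_len_range, autosomes,
                   cfg.n_duplications)
    add_span_event(DELETION, *cfg.del_len_range, autosomes, cfg.n_deletions)
    add_span_event(INVERSION, *cfg.inv_len_range, autosomes, cfg.n_inversions)

    if mito:
        for _ in range(cfg.n_mito_insertions):
            chrom = str(rng.choice(autosomes))
            p = _sample_locus(rng, genome, cfg, chrom, 0, taken, rep_index)
            if p is None:
                continue
            taken.append((chrom, p, p))
            manifest.events.append(PlantedEvent(
                MITO_INSERTION, chrom, p, length=cfg.mito_insert_len,
                haplotypes=_sample_hapset(rng, cfg, chrom),
                source=GenomeInterval(mito, 2_000,
                                      2_000 + cfg.mito_insert_len)))

    # build haplotype chromosomes
    haplotypes: dict[int, dict[str, HaplotypeChrom]] = {}
    for hap in (1, 2, 3, 4):
        plans: dict[str, list[tuple[str, int, int]]] = {}
        for chrom, L in genome.chrom_lengths.items():
            if hap not in cfg.haplotypes_of[chrom] and cfg.ploidy[chrom] > 1:
                continue
            plans[chrom] = [(chrom, 0, L)]
        for cA, pA, cB, pB, thaps in translocs:
            if hap not in thaps:
                continue
            LA, LB = genome.chrom_lengths[cA], genome.chrom_lengths[cB]
            if len(plans[cA]) > 1 or len(plans[cB]) > 1:
                raise ValueError("two translocations on one haplotype share "
                                 "a chromosome; reduce counts or carriers")
            plans[cA] = [(cA, 0, pA), (cB, pB, LB)]
            plans[cB] = [(cB, 0, pB), (cA, pA, LA)]
        haplotypes[hap] = {}
        for chrom, plan in plans.items():
            segments: list[Segment] = []
            for src, s, e in plan:
                segments.extend(_piece_segments(manifest, hap, src, s, e))
            haplotypes[hap][chrom] = HaplotypeChrom(
                f"{chrom}|h{hap}", hap, segments)
    return haplotypes, manifest


def _piece_segments(manifest: TruthManifest, hap: int, chrom: str,
                    lo: int, hi: int) -> list[Segment]:
    """Segments for reference span [lo,hi) with this haplotype's local events."""
    events = sorted(
        (e for e in manifest.events
         if e.chrom == chrom and hap in e.haplotypes
         and e.event_type in (TE_INSERTION, LOCAL_DUPLICATION, DELETION,
                              INVERSION, MITO_INSERTION)
         and lo <= e.pos and max(e.end, e.pos) <= hi),
        key=lambda e: e.pos)
    segs: list[Segment] = []
    cur = lo
    for e in events:
        if e.event_type in (TE_INSERTION, MITO_INSERTION):
            segs.append(Segment(chrom, cur, e.pos))
            segs.append(Segment(e.source.chrom, e.source.start, e.source.end))
            cur = e.pos
        elif e.event_type == LOCAL_DUPLICATION:
            segs.append(Segment(chrom, cur, e.end))
            segs.append(Segment(chrom, e.pos, e.end))
            cur = e.end
        elif e.event_type == DELETION:
            segs.append(Segment(chrom, cur, e.pos))
            cur = e.end
        elif e.event_type == INVERSION:
            segs.append(Segment(chrom, cur, e.pos))
            segs.append(Segment(chrom, e.pos, e.end, "-"))
            cur = e.end
    segs.append(Segment(chrom, cur, hi))
    return [s for s in segs if len(s) > 0]


# ---------------------------------------------------------------------------
# Long reads with analytic alignments
# ---------------------------------------------------------------------------

@dataclass
class SimulatedRead:
    read_id: str
    hap: int
    hap_chrom: HaplotypeChrom
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def simulate_long_reads(haplotypes: Mapping[int, Mapping[str, HaplotypeChrom]],
                        cfg: SimConfig
                        ) -> tuple[list[RefAlignment], list[AvaMapping],
                                   dict[str, int], list[SimulatedRead]]:
    """Sample reads per haplotype at the configured per-haplotype depth and
    emit exact reference alignments (split at planted breakpoints) and
    all-vs-all overlap mappings between same-haplotype reads."""
    rng = np.random.default_rng(cfg.seed + 2)
    mean_len = math.exp(cfg.read_len_log_mean
                        + cfg.read_len_log_sigma ** 2 / 2)
    reads: list[SimulatedRead] = []
    ref_alignments: list[RefAlignment] = []
    ava: list[AvaMapping] = []
    read_lengths: dict[str, int] = {}
    for hap in sorted(haplotypes):
        for chrom in sorted(haplotypes[hap]):
            hc = haplotypes[hap][chrom]
            L = hc.length
            n = max(1, int(round(cfg.per_haplotype_depth
                                 * (L + mean_len) / mean_len)))
            lens = np.maximum(cfg.min_read_len, np.rint(rng.lognormal(
                cfg.read_len_log_mean, cfg.read_len_log_sigma, n))).astype(int)
            starts = rng.integers(-lens + cfg.min_read_len,
                                  L - cfg.min_read_len, n)
            group: list[SimulatedRead] = []
            for i in range(n):
                s = max(0, int(starts[i]))
                e = min(L, int(starts[i]) + int(lens[i]))
                if e - s < cfg.min_read_len:
                    continue
                rid = f"r{hap}_{chrom}_{i}"
                read = SimulatedRead(rid, hap, hc, s, e)
                group.append(read)
                reads.append(read)
                read_lengths[rid] = e - s
                for (ha, hb, tchrom, rs, re_, orient) in hc.map_interval(s, e):
                    if hb - ha < 50:
                        continue
                    ref_alignments.append(RefAlignment(
                        read_id=rid, read_len=e - s,
                        read_start=ha - s, read_end=hb - s,
                        target=GenomeInterval(tchrom, rs, re_, orient),
                        strand=orient, matches=hb - ha, block_len=hb - ha))
            ava.extend(_ava_overlaps(group, cfg))
    return ref_alignments, ava, read_lengths, reads


def _ava_overlaps(group: list[SimulatedRead],
                  cfg: SimConfig) -> list[AvaMapping]:
    """All pairwise overlap mappings >= min_ava_overlap within one haplotype
    chromosome (reads there are sequence-identical over shared spans)."""
    out: list[AvaMapping] = []
    group = sorted(group, key=lambda r: r.start)
    active: list[SimulatedRead] = []
    for r in group:
        active = [a for a in active if a.end - r.start >= cfg.min_ava_overlap]
        for a in active:
            os_, oe = max(a.start, r.start), min(a.end, r.end)
            if oe - os_ < cfg.min_ava_overlap:
                continue
            q, t = (a, r) if a.length <= r.length else (r, a)
            out.append(AvaMapping(
                q.read_id, q.length, os_ - q.start, oe - q.start,
                t.read_id, t.length, os_ - t.start, oe - t.start,
                "+", oe - os_, oe - os_))
        active.append(r)
    return out


def read_sequence(read: SimulatedRead, genome: Genome) -> str:
    """Reconstruct a read's sequence from the reference (for FASTA export)."""
    comp = str.maketrans("ACGT", "TGCA")
    parts = []
    for (_, _, chrom, rs, re_, orient) in read.hap_chrom.map_interval(
            read.start, read.end):
        seq = genome.seqs[chrom][rs:re_]
        parts.append(seq if orient == "+" else seq.translate(comp)[::-1])
    return "".join(parts)


# ---------------------------------------------------------------------------
# Short read pairs
# ---------------------------------------------------------------------------

def simulate_pairs(haplotypes: Mapping[int, Mapping[str, HaplotypeChrom]],
                   genome: Genome, cfg: SimConfig) -> list[PairRecord]:
    """Innie paired-end reads mapped through the haplotype layout.

    Pairs straddling a planted tandem-duplication junction come out everted
    with separation close to the duplication length — the duplication
    signature. Mates crossing a breakpoint within the read are skipped
    (they would be clipped in real data)."""
    rng = np.random.default_rng(cfg.seed + 3)
    rep = genome.repeat_index()
    rl = cfg.pair_read_len
    pairs: list[PairRecord] = []
    for hap in sorted(haplotypes):
        for chrom in sorted(haplotypes[hap]):
            hc = haplotypes[hap][chrom]
            L = hc.length
            n = int(cfg.pair_depth_per_hap * L / (2 * rl))
            frags = np.maximum(3 * rl, np.rint(rng.normal(
                cfg.pair_insert_mean, cfg.pair_insert_sd, n))).astype(int)
            starts = rng.integers(0, np.maximum(1, L - frags), n)
            for i in range(n):
                s, flen = int(starts[i]), int(frags[i])
                m1 = hc.map_interval(s, s + rl)
                m2 = hc.map_interval(s + flen - rl, s + flen)
                if len(m1) != 1 or len(m2) != 1:
                    continue
                mates = []
                for pieces, fwd in ((m1, True), (m2, False)):
                    _, _, tchrom, rs, re_, orient = pieces[0]
                    strand = orient if fwd else ("-" if orient == "+" else "+")
                    mates.append(MateAlignment(
                        tchrom, rs, re_, strand, 1.0,
                        rep.fraction(tchrom, rs, re_), rl))
                pairs.append(PairRecord(mates[0], mates[1]))
    return pairs


# ---------------------------------------------------------------------------
# Convenience bundle + truth scoring
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    genome: Genome
    haplotypes: dict[int, dict[str, HaplotypeChrom]]
    manifest: TruthManifest
    ref_alignments: list[RefAlignment]
    ava: list[AvaMapping]
    read_lengths: dict[str, int]
    reads: list[SimulatedRead]

    @property
    def repeat_index(self) -> RepeatIndex:
        return self.genome.repeat_index()


def simulate_dataset(cfg: SimConfig | None = None) -> SimulatedDataset:
    cfg = cfg or SimConfig()
    genome = generate_genome(cfg)
    haplotypes, manifest = plant_events(genome, cfg)
    ref_aln, ava, read_lengths, reads = simulate_long_reads(haplotypes, cfg)
    return SimulatedDataset(genome, haplotypes, manifest, ref_aln, ava,
                            read_lengths, reads)


def match_insertions_to_truth(calls: Sequence, manifest: TruthManifest,
                              window: int = 500) -> dict[int, object]:
    """Map manifest insertion events to the nearest insertion call within
    the window (by call midpoint); value None when unmatched."""
    out: dict[int, object] = {}
    for idx, ev in enumerate(manifest.events):
        if ev.event_type not in (TE_INSERTION, MITO_INSERTION):
            continue
        best, best_d = None, window + 1
        for c in calls:
            if c.call_type != "insertion" or c.chrom1 != ev.chrom:
                continue
            d = abs(c.midpoint - ev.pos)
            if d < best_d:
                best, best_d = c, d
        out[idx] = best
    return out


def insertion_recall(calls: Sequence, manifest: TruthManifest,
                     min_len: int = 1_000, min_freq: int = 2,
                     window: int = 500) -> float:
    """Recall of planted TE insertions >= min_len on >= min_freq haplotypes."""
    matched = match_insertions_to_truth(calls, manifest, window)
    hits = total = 0
    for idx, call in matched.items():
        ev = manifest.events[idx]
        if ev.event_type != TE_INSERTION:
            continue
        if ev.length < min_len or ev.expected_frequency < min_freq:
            continue
        total += 1
        hits += call is not None
    return hits / total if total else float("nan")
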