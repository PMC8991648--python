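"""Readers, writers and domain types shared across the toolkit.

Every coordinate inside the package is 0-based half-open; conversion from
1-based formats (RepeatMasker .out, GFF3, VCF) happens here and only here.
PAF is the canonical alignment interchange format; SAM/BAM is accepted
through an adapter that reconstructs read coordinates from the CIGAR string
(hard clips count toward read length).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import yaml


# ---------------------------------------------------------------------------
# Threshold configuration
# ---------------------------------------------------------------------------

@dataclass
class ThresholdConfig:
    """Every numeric constant of the calling, haplotyping and comparative logic.

    Defaults reproduce the published analysis of the tetraploid S2-DRSC
    cell-line genome; all lengths are in bp.
    """

    # read containment
    containment_end_margin: int = 750
    # read layout
    min_distributed_aln: int = 100
    repetitive_fraction: float = 0.5
    anchor_min_len: int = 1000
    ac_gap: int = 5000
    ac_mask_omit_max: int = 25000
    ac_min_span: int = 3000
    # call clustering / filtering
    call_cluster_window: int = 500
    min_informative_reads: int = 2    # strict >
    min_read_support: int = 3         # strict >
    support_span_margin: int = 1
    element_purity: float = 0.9
    # genome graph
    large_sv_distance: int = 100000
    ref_edge_min_reads: int = 3
    # haplotyping
    per_haplotype_support: float = 44.0
    tetraploid_low: float = 0.875
    tetraploid_high: float = 1.125
    tetraploid_window: int = 3000
    te_match_window: int = 250
    # coverage / genes
    cn_bin: int = 50
    disruption_min_reads: int = 10
    zero_cov_min_run: int = 10
    gene_cn_repeat_omit: float = 0.30
    gene_flank_window: int = 100
    gene_upstream: int = 1000
    # short-read duplication signatures
    pair_sep_min: int = 5000
    pair_sep_max: int = 50000
    pair_match_fraction: float = 0.95
    pair_repeat_max: float = 0.70
    pair_cluster_window: int = 3000
    pair_aln_fraction: float = 0.80
    pair_span_similarity: float = 0.80
    dup_min_pairs: int = 4
    # bin matrices / copy gain
    binmat_bin: int = 1000
    cn_gain_fraction: float = 1.5
    snp_min_support: int = 3
    snp_repeat_max: float = 0.10
    snp_presence_fraction: float = 0.50
    # density / coverage profile
    density_window: int = 100000
    density_repeat_fraction: float = 0.70
    density_min_len: int = 1000
    profile_step: int = 1000
    profile_window: int = 10000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ThresholdConfig":
        """Load overrides from a YAML mapping; unknown keys are rejected."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)

    def replace(self, **kw) -> "ThresholdConfig":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeInterval:
    """A 0-based half-open reference interval, optionally stranded."""

    chrom: str
    start: int
    end: int
    strand: str | None = None

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("empty chromosome name")
        if not (0 <= self.start <= self.end):
            raise ValueError(f"bad interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomeInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class RefAlignment:
    """One alignment of a long read to the reference genome."""

    read_id: str
    read_len: int
    read_start: int
    read_end: int
    target: GenomeInterval
    strand: str
    matches: int
    block_len: int
    score: float = 0.0

    def __post_init__(self):
        if not (0 <= self.read_start < self.read_end <= self.read_len):
            raise ValueError(
                f"{self.read_id}: read span [{self.read_start},{self.read_end}) "
                f"outside read of length {self.read_len}")
        if self.score == 0.0:
            self.score = float(self.matches)


@dataclass(slots=True)
class AvaMapping:
    """One all-versus-all mapping between two long reads."""

    query_id: str
    query_len: int
    query_start: int
    query_end: int
    target_id: str
    target_len: int
    target_start: int
    target_end: int
    strand: str
    matches: int
    block_len: int


@dataclass(frozen=True)
class RepeatAnnotation:
    """A repeat-masked reference interval with its element identity."""

    interval: GenomeInterval
    element_name: str
    element_class: str = ""
    element_full_length: int | None = None

    def __post_init__(self):
        if not self.element_name:
            raise ValueError("empty element name")


@dataclass
class SNPRecord:
    """A SNP with its alternate-allele read-support fraction."""

    chrom: str
    pos: int
    support_fraction: float
    depth: int = 0
    alt_support: int = 0
    repeat_fraction: float = 0.0


@dataclass
class GeneModel:
    """A protein-coding gene: transcript bounds plus CDS intervals."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    cds: list[tuple[int, int]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# PAF
# ---------------------------------------------------------------------------

def _parse_paf_line(line: str, lineno: int):
    cols = line.rstrip("\n").split("\t")
    if len(cols) < 12:
        raise ValueError(f"PAF parse error at line {lineno}: "
                         f"expected >=12 columns, got {len(cols)}")
    try:
        qlen, qs, qe = int(cols[1]), int(cols[2]), int(cols[3])
        tlen, ts, te = int(cols[6]), int(cols[7]), int(cols[8])
        matches, blen = int(cols[9]), int(cols[10])
    except ValueError as exc:
        raise ValueError(f"PAF parse error at line {lineno}: {exc}") from None
    strand = cols[4]
    score = None
    for tag in cols[12:]:
        if tag.startswith("AS:i:"):
            score = float(tag[5:])
    return cols[0], qlen, qs, qe, strand, cols[5], tlen, ts, te, matches, blen, score


def read_paf(path: str | Path, mode: str) -> list:
    """Parse a PAF file into RefAlignment (mode='ref') or AvaMapping (mode='ava').

    The AS:i alignment-score tag is honoured when present; otherwise the
    score defaults to the matches column.
    """
    if mode not in ("ref", "ava"):
        raise ValueError(f"unknown PAF mode {mode!r}")
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            (qid, qlen, qs, qe, strand, tid, tlen, ts, te,
             matches, blen, score) = _parse_paf_line(line, lineno)
            if mode == "ref":
                out.append(RefAlignment(
                    read_id=qid, read_len=qlen, read_start=qs, read_end=qe,
                    target=GenomeInterval(tid, ts, te, strand), strand=strand,
                    matches=matches, block_len=blen,
                    score=score if score is not None else float(matches)))
            else:
                out.append(AvaMapping(qid, qlen, qs, qe, tid, tlen, ts, te,
                                      strand, matches, blen))
    return out


def write_paf(records: Iterable[RefAlignment | AvaMapping], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            if isinstance(r, RefAlignment):
                fields = [r.read_id, r.read_len, r.read_start, r.read_end,
                          r.strand, r.target.chrom, 0, r.target.start,
                          r.target.end, r.matches, r.block_len, 60,
                          f"AS:i:{int(r.score)}"]
            else:
                fields = [r.query_id, r.query_len, r.query_start, r.query_end,
                          r.strand, r.target_id, r.target_len, r.target_start,
                          r.target_end, r.matches, r.block_len, 60]
            fh.write("\t".join(str(f) for f in fields) + "\n")


def read_sam(path: str | Path, primary_only: bool = False) -> list[RefAlignment]:
    """SAM/BAM adapter: read coordinates reconstructed from CIGAR.

    Hard-clipped bases count toward read length and read coordinates so the
    result matches what the aligner's PAF output would report.
    """
    import pysam

    out = []
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for rec in af:
            if rec.is_unmapped:
                continue
            if primary_only and (rec.is_secondary or rec.is_supplementary):
                continue
            cig = rec.cigartuples or []
            # leading/trailing clips (S=4, H=5) in read orientation
            lead = sum(n for op, n in _take_clips(cig))
            tail = sum(n for op, n in _take_clips(reversed(cig)))
            qaln = sum(n for op, n in cig if op in (0, 1, 7, 8))  # M,I,=,X
            read_len = lead + qaln + tail
            if rec.is_reverse:
                read_start, read_end = tail, tail + qaln
            else:
                read_start, read_end = lead, lead + qaln
            matches = sum(n for op, n in cig if op in (0, 7))
            strand = "-" if rec.is_reverse else "+"
            try:
                score = float(rec.get_tag("AS"))
            except KeyError:
                score = float(matches)
            out.append(RefAlignment(
                read_id=rec.query_name, read_len=read_len,
                read_start=read_start, read_end=read_end,
                target=GenomeInterval(rec.reference_name,
                                      rec.reference_start, rec.reference_end,
                                      strand),
                strand=strand, matches=matches,
                block_len=rec.reference_end - rec.reference_start,
                score=score))
    return out


def _take_clips(cig) -> Iterator[tuple[int, int]]:
    for op, n in cig:
        if op in (4, 5):
            yield op, n
        else:
            return


# ---------------------------------------------------------------------------
# Repeat annotations
# ---------------------------------------------------------------------------

def read_repeats(path: str | Path, dialect: str) -> list[RepeatAnnotation]:
    """Parse RepeatMasker .out (1-based inclusive) or BED4 repeat annotations."""
    if dialect == "repeatmasker_out":
        return _read_rm_out(path)
    if dialect == "bed":
        return _read_repeat_bed(path)
    raise ValueError(f"unknown repeat dialect {dialect!r}")


def _read_rm_out(path) -> list[RepeatAnnotation]:
    out = []
    with open(path) as fh:
        lines = fh.readlines()
    body = lines[3:] if len(lines) >= 3 and not lines[0].strip()[:1].isdigit() else lines
    for line in body:
        cols = line.split()
        if len(cols) < 11:
            continue
        chrom, begin, end = cols[4], int(cols[5]), int(cols[6])
        name, klass = cols[9], cols[10]
        out.append(RepeatAnnotation(
            GenomeInterval(chrom, begin - 1, end), name, klass))
    return out


def _read_repeat_bed(path) -> list[RepeatAnnotation]:
    out = []
    with open(path) as fh:
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 4 or line.startswith(("#", "track")):
                continue
            name = cols[3]
            klass = cols[6] if len(cols) > 6 else (name.split("/")[0] if "/" in name else name)
            full_len = int(cols[7]) if len(cols) > 7 and cols[7] not in (".", "") else None
            out.append(RepeatAnnotation(
                GenomeInterval(cols[0], int(cols[1]), int(cols[2])),
                name, klass, full_len))
    return out


def write_repeats_bed(repeats: Iterable[RepeatAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in repeats:
            cols = [r.interval.chrom, r.interval.start, r.interval.end,
                    r.element_name, 0, ".", r.element_class,
                    r.element_full_length if r.element_full_length else "."]
            fh.write("\t".join(str(c) for c in cols) + "\n")


# ---------------------------------------------------------------------------
# GFF3 gene models (gene + CDS features; the schema the simulator emits)
# ---------------------------------------------------------------------------

def read_gff_genes(path: str | Path) -> list[GeneModel]:
    genes: dict[str, GeneModel] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                continue
            chrom, _, ftype, start, end, _, strand, _, attrs = cols[:9]
            adict = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if ftype == "gene":
                gid = adict.get("ID", adict.get("gene_id", ""))
                genes[gid] = GeneModel(gid, chrom, int(start) - 1, int(end),
                                       strand)
            elif ftype == "CDS":
                gid = adict.get("Parent", "").split(".")[0]
                if gid in genes:
                    genes[gid].cds.append((int(start) - 1, int(end)))
    return list(genes.values())


def write_gff_genes(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write("\t".join(map(str, [
                g.chrom, "polysv", "gene", g.start + 1, g.end, ".",
                g.strand, ".", f"ID={g.gene_id}"])) + "\n")
            for i, (cs, ce) in enumerate(g.cds):
                fh.write("\t".join(map(str, [
                    g.chrom, "polysv", "CDS", cs + 1, ce, ".",
                    g.strand, "0", f"ID={g.gene_id}.cds{i};Parent={g.gene_id}"]))
                    + "\n")


# ---------------------------------------------------------------------------
# VCF SNPs
# ---------------------------------------------------------------------------

def read_vcf_snps(path: str | Path) -> list[SNPRecord]:
    """Read SNPs from a VCF; support fraction from AO/DP, AD, or AF."""
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            depth = rec.info.get("DP", 0)
            ao = rec.info.get("AO", None)
            if isinstance(ao, tuple):
                ao = ao[0]
            if ao is None and rec.samples:
                smp = rec.samples[0]
                ad = smp.get("AD")
                if ad is not None and len(ad) >= 2:
                    ao = ad[1]
                    depth = depth or sum(a for a in ad if a is not None)
            if ao is not None and depth:
                frac = ao / depth
            else:
                af = rec.info.get("AF", None)
                if isinstance(af, tuple):
                    af = af[0]
                frac = float(af) if af is not None else 0.0
                ao = int(round(frac * depth)) if depth else 0
            out.append(SNPRecord(rec.chrom, rec.pos - 1, float(frac),
                                 int(depth or 0), int(ao or 0)))
    return out


# ---------------------------------------------------------------------------
# bedgraph
# ---------------------------------------------------------------------------

def write_bedgraph(entries: Iterable[tuple[str, int, int, float]],
                   path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in entries:
            v = int(value) if float(value).is_integer() else value
            fh.write(f"{chrom}\t{start}\t{end}\t{v}\n")


def read_bedgraph(path: str | Path) -> list[tuple[str, int, int, float]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "#")) or not line.strip():
                continue
            chrom, start, end, value = line.split()[:4]
            out.append((chrom, int(start), int(end), float(value)))
    return out


# ---------------------------------------------------------------------------
# GFA 1.0
# ---------------------------------------------------------------------------

def write_gfa(segments: Sequence[tuple[str, int]],
              links: Sequence[tuple[str, str, str, str]],
              path: str | Path) -> None:
    """Write segments (name, length) and links (from, from_orient, to, to_orient)."""
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for name, length in segments:
            fh.write(f"S\t{name}\t*\tLN:i:{length}\n")
        for a, ao, b, bo in links:
            fh.write(f"L\t{a}\t{ao}\t{b}\t{bo}\t0M\n")


def read_gfa(path: str | Path):
    """Parse S and L lines back; used for round-trip checks."""
    segments, links = [], []
    with open(path) as fh:
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            if cols[0] == "S":
                length = None
                for tag in cols[3:]:
                    if tag.startswith("LN:i:"):
                        length = int(tag[5:])
                segments.append((cols[1], length))
            elif cols[0] == "L":
                links.append((cols[1], cols[2], cols[3], cols[4]))
    return segments, links


# ---------------------------------------------------------------------------
# relaxed PHYLIP (binary matrices)
# ---------------------------------------------------------------------------

def write_phylip(matrix, path: str | Path) -> None:
    """Write a samples x bins binary DataFrame as relaxed PHYLIP."""
    with open(path, "w") as fh:
        fh.write(f"{matrix.shape[0]} {matrix.shape[1]}\n")
        for name, row in matrix.iterrows():
            fh.write(f"{name}  {''.join(str(int(v)) for v in row)}\n")


def read_phylip(path: str | Path):
    import numpy as np
    import pandas as pd

    with open(path) as fh:
        n, m = map(int, fh.readline().split())
        names, rows = [], []
        for _ in range(n):
            name, seq = fh.readline().split()
            names.append(name)
            rows.append([int(c) for c in seq])
    return pd.DataFrame(np.array(rows), index=names)


# ---------------------------------------------------------------------------
# FASTA (thin wrappers; sequences are plain strings internally)
# ---------------------------------------------------------------------------

def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            elif name is not None:
                seqs[name].append(line)
    return {k: "".join(v) for k, v in seqs.items()}


# ---------------------------------------------------------------------------
# simple TSV tables
# ---------------------------------------------------------------------------

def read_lengths_tsv(path: str | Path) -> dict[str, int]:
    out = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            rid, length = line.split()[:2]
            out[rid] = int(length)
    return out
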