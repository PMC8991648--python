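# Methods

## The calling model

The caller is read-centered: each informative long read is treated as a
local assembly whose ordered reference alignments describe the structure
of the haplotype it was sampled from. All reasoning happens in three
coordinate systems — the read, the reference, and (for all-vs-all
evidence) other reads — and all intervals are 0-based half-open
internally; 1-based formats are converted at I/O boundaries only.

**Containment.** A read adds no structural information if a longer read
covers it entirely. From all-vs-all mappings, a read is contained when its
unaligned head and tail are each ≤ `containment_end_margin` (750 bp, which
absorbs alignment fraying at read ends). Equal-length mutual containment is
broken lexicographically (the smaller read id stays informative), chains
are allowed (a container may itself be contained), and either mapping
orientation may witness containment. Contained reads are excluded from
calling but counted toward breakpoint support, which is what makes the
support scale with haplotype copy number.

**Layout.** One read's alignments are placed greedily in descending score
order (score = the aligner's AS tag when present, else matches). An
alignment overlapping already-occupied read territory keeps each free
sub-interval ≥ `min_distributed_aln` (100 bp); its target coordinates are
rescaled linearly to the kept read fraction. Linear rescaling is exact for
the simulator's gap-free alignments and approximate within the indel
content otherwise. Score ties break by longer alignment, then lower read
start, then target order, making layouts deterministic. Pieces are
classified repetitive (> 50 % of the target span repeat-masked — checked
first), anchor (> 1 kbp), or junction material.

**Adjacent clusters.** Read-consecutive anchors extend an AC while they
stay on one chromosome and strand with an effective reference gap ≤
`ac_gap` (5 kbp), where the effective gap subtracts repeat-masked bases in
the gap up to `ac_mask_omit_max` (25 kbp). Reference overlap between
consecutive members (gap ≤ 0) also joins — that is the duplication
pattern. A strand or chromosome change always ends the AC; the change
surfaces as a called rearrangement rather than being absorbed.

**Calls.** Insertions come from junctions whose flanks share an AC, with
`insertion_len` equal to the read gap between the flanking anchors and the
junction's composition aggregated from its members' repeat annotations
plus unaligned bases. Duplications come from reference-overlapping AC
members; the merged `duplicated_interval` is the union of the per-read
overlaps, because each read's overlap is a (possibly end-truncated)
sub-interval of the true duplicated span. Rearrangements join consecutive
ACs when both span > `ac_min_span` (3 kbp). Breakpoint pairs are
canonicalised to genome order; when the order swap reverses the junction's
traversal direction both strands flip, so reads crossing one junction in
opposite orientations produce identical calls — this is essential for both
clustering and for keeping the two junctions of a reciprocal translocation
distinct. Clustering is single-linkage (both breakpoints within
`call_cluster_window` = 500 bp, strands equal at both ends), iterated to a
fixed point so the operation is idempotent; merged breakpoints are
support-weighted medians. Support counts the cluster's informative reads
plus distinct contained reads whose mapping spans the breakpoint position
on a source read with ≥ `support_span_margin` (1 bp) on each side. The
low-frequency filter keeps calls with > 2 informative reads and > 3
support (both strict).

**Taxonomy.** Insertions are binned by length (< 1, 1–10, 10–100,
> 100 kbp), repeat fraction (25 % bins), and breakpoint distance
(trans-chromosomal, < 1 kbp, 1–10, 10–100 kbp, 100 kbp–1 Mbp, > 1 Mbp).
An insertion is labelled with an element when one element covers > 90 % of
the inserted sequence; the four most abundant element classes are kept and
the rest pooled as "Other"; the full-length flag requires 90–110 % of the
element's library length. Maintained-strand intra-chromosomal
rearrangements whose skipped reference is > 50 % repetitive are classed
with repetitive indels; everything else structural is "unclassified"
(nested events, large duplications, non-repetitive deletions, inversions).

## Coverage, ploidy and genes

Coverage is binned at `cn_bin` = 50 bp; bin copy number is depth divided
by the arm per-copy depth (arm mean / arm basal ploidy: 4 autosomal, 2 for
X, configurable). The stated normalisation "division by arm average
coverage" is read on the per-copy scale — dividing by the arm mean itself
would put every gene near 1 and contradict the "> 4 / > 2" gain rule. A
locus is tetraploid when the mean depth of a 3 kbp window centered on it
lies within 87.5–112.5 % of the autosome average; the interval is closed
on both ends (a dash range is printed, and the permissive reading is fixed
for determinism) with a 1e-9 relative guard against float accumulation.
SNP haplotype classes partition the support fraction (0, 1) into
(0, 0.125], (0.125, 0.375], (0.375, 0.625], (0.625, 0.875], (0.875, 1)
for < 1, 1, 2, 3, > 3 haplotypes; a fraction of exactly 1 is excluded
(indistinguishable from a progenitor/reference difference). Genes are
disrupted by a ≥ 10-read breakpoint or a > 10 bp zero-coverage run in the
transcription start/stop windows (100 bp, configurable — the sources do
not state a width), coding regions, or the 1 kbp upstream region; copy
number omits 50 bp bins ≥ 30 % repeat-annotated; gains are undisrupted
genes above arm ploidy.

## Haplotype frequency

The per-haplotype support constant *d* is the spacing of the peaks of the
insertion support distribution (a mixture with modes near *d*, 2*d*, 3*d*,
4*d*). The estimator histograms supports into 256 bins spanning the data
range, smooths with a Gaussian kernel of 2.5 % of the range (both scale
with the data, making the estimate scale-equivariant), locates peaks
(zero-padded so boundary modes are detected; unimodal inputs fall back to
the single mode with a warning), assigns each peak the nearest integer
multiple of the first, and regresses peak positions on multipliers through
the origin. Frequencies are `round(support / d)` with half rounded away
from zero (66/44 → 2), clamped to [1, arm ploidy]; only local insertions
(breakpoint distance < 1 kbp) in tetraploid windows enter spectra. The
estimator assumes the single-haplotype peak is present. Cross-validation
against short-read TE tables marks a call cell-line specific when it
matches the S2-DRSC table within ± 250 bp, is absent from both sibling
lines, and a sibling read spans the matched breakpoint; matched calls
failing the latter two rules are progenitor ("all"), unmatched calls stay
unresolved.

## Genome graph

Split points are breakpoints of calls > 100 kbp apart or
trans-chromosomal; split points within 500 bp merge into their median
(clustered calls share fuzzy breakpoints, and this prevents sliver
segments). Each large call becomes an edge between the facing segment
sides given its strands ('+' at the first breakpoint attaches the segment
ending there; '−' the segment starting there, and symmetrically at the
second). A reference edge re-joins adjacent segments when ≥ 3 distinct
reads hold a single AC across the split; 1–2 spanning reads leave the
connection absent rather than low-confidence. Mitochondrial insertions
need no special casing — their junction alignments to the mitochondrial
contig are long and non-repetitive, so they anchor, call trans
rearrangements, and surface as edges to the mitochondrial segments.

## Short-read comparative layer

A duplication-signature pair must (1) map 5–50 kbp apart (closed interval,
outermost mate coordinates — the geometry of junction-straddling pairs),
(2) be > 95 % matched, (3) be < 70 % repeat-annotated, (4) be everted:
a forward first mate expects its partner reverse-mapped upstream, a
reverse first mate forward-mapped downstream. Pairs cluster single-linkage
when their spans start within 3 kbp, both mates are > 80 % aligned, and
separations are > 80 % similar (min/max ratio — the spans are compared,
as mate separation is what the junction determines); clusters need ≥ 4
pairs. A Discussion passage elsewhere gives 3–50 kbp for the separation
range; the Methods value (5 kbp) is authoritative here. Basal arm ploidy
is the median of copy-number calls in [1, 8]; gains are calls ≥ 150 % of
basal. Bin matrices binarise per-sample events into 1 kbp bins (SNPs:
≥ 3 supporting reads in any sample, < 10 % repeat, present where the
sample's support fraction exceeds 50 %; TE calls: ≥ 2 supporting reads);
bins with no events are not emitted, and the matrix exports as relaxed
PHYLIP for external tree inference.

## The simulator and what it shows

The generator emulates the study system at desk scale: two 2 Mb tetraploid
autosomes, a 1 Mb diploid X and a 19 kb mitochondrial contig; five
annotated LTR/LINE/DNA element families with ancestral full-length and
truncated copies (including a 7,469 bp Gypsy-like element); 60 TE
insertions (half full-length, by quota so the manifest matches the
configured fraction exactly), 10 tandem duplications, 4 deletions,
2 inversions, 2 reciprocal translocations, and one 10 kb mitochondrial
insertion, at haplotype frequencies 1–4 (1–2 on X). Per-haplotype read
depth defaults to 44× so breakpoint support per carrier haplotype matches
the study's constant. Translocations are carried by two haplotypes by
default, mirroring the observation that translocation breakpoints sit at
coverage above baseline; this also gives each derivative junction a
comfortable informative-read count against the > 2 filter.

Reads follow a log-normal length distribution (median 20 kb, σ = 0.5,
minimum 1 kb) with uniform starts hanging over the ends so interior
coverage is flat. Alignments are emitted analytically from the event
layout: haplotypes are segment lists over the reference, inserted sequence
points at its ancestral source copy (so junctions map to repeat-annotated
loci and mitochondrial inserts to the mitochondrial contig), and a read's
alignment records are exactly its segment pieces ≥ 50 bp. All-vs-all
mappings are overlaps ≥ 2 kb between reads of the same haplotype — within
a haplotype reads are sequence-identical by construction, and
cross-haplotype mappings are unnecessary for support semantics because
each carrier haplotype's spanning reads are already counted through its
own informative and contained reads. Reads are emitted in the haplotype's
forward orientation (inverted segments map to the minus strand); the
pipeline itself is orientation-symmetric, which the reverse-read tests
exercise directly. Short pairs are innies (insert 600 ± 50 bp, 150 bp
mates); mates crossing a breakpoint inside the read are skipped, as they
would be clipped in real data.

What passing these fixtures does **not** show: tolerance to base-level
sequencing error, chimeric reads, mapping ambiguity in genuinely
repetitive reference (the simulator's repeat copies are identical, but
junction alignments are forced to the true source copy), reference bias,
or coverage waviness — real-data performance depends on the upstream
aligner handling those. Event counts and genome sizes were chosen so the
full suite runs in well under a minute of simulation time on one CPU; the
study-scale fixture uses ~37,000 reads and ~1.5 M all-vs-all mappings.

## Numerical choices and degenerate inputs

- Strict inequalities follow the printed wording everywhere (“> 2
  informative reads”, “> 3 support”, “> 1 kbp” anchors, “> 50 %”
  repetitive, “> 3 kbp” AC spans, “at least three reads” for reference
  edges, ≥ 150 % gains, ≥ 4 pairs).
- Insertion breakpoints are the facing anchor reference ends; a merged
  call's position is the support-weighted median; its representative point
  (for matching and windows) is the breakpoint midpoint.
- Empty inputs return empty outputs; malformed PAF names the line number;
  mappings referencing unknown reads, fractions outside [0, 1], window
  positions off-chromosome, and breakpoints past chromosome ends raise.
  Genes without CDS or fully repeat-masked genes are skipped with a
  warning; truncated tetraploid windows at chromosome ends warn.
- With minimap2-style input, supplementary alignments are used by default;
  `read_sam(primary_only=True)` restricts to primaries (whether the
  original analysis used supplementaries is not stated).
- A zero support-fraction SNP is excluded rather than classed — the < 1
  class is the half-open interval (0, 0.125].
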