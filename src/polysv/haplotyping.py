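"""Haplotype frequency of insertion calls and short-read TE cross-validation.

In a tetraploid genome, the number of haplotypes carrying a local insertion
is read support divided by the per-haplotype support constant, rounded to
the nearest integer (the published dataset's constant is 44 reads, the
spacing of the peaks of the insertion read-support distribution). Only
local insertions (breakpoints < 1 kbp apart) in tetraploid-coverage regions
enter frequency spectra. Cross-validation against short-read TE calls from
the two sibling cell lines separates insertions that arose in the cell line
from those present in the progenitor fly.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .coverage_ploidy import CoverageTrack, is_tetraploid_window
from .formats_io import ThresholdConfig
from .sv_calls import INSERTION, SVCall

PROVENANCE_ALL = "all"
PROVENANCE_CELLLINE = "cellline_specific"
PROVENANCE_UNRESOLVED = "unresolved"


@dataclass
class HaplotypeCall:
    call: SVCall
    support: int
    per_haplotype_support: float
    frequency: int
    tetraploid: bool
    provenance: str = PROVENANCE_UNRESOLVED


@dataclass
class TECall:
    chrom: str
    pos: int
    element: str = ""
    support: int = 0
    spanning: int = 0


@dataclass
class TECallTable:
    sample: str
    calls: list[TECall] = field(default_factory=list)

    def near(self, chrom: str, pos: int, window: int) -> list[TECall]:
        return [c for c in self.calls
                if c.chrom == chrom and abs(c.pos - pos) <= window]


def read_te_table(path, sample: str = "") -> TECallTable:
    """Neutral TSV schema: chrom, pos, element, support, spanning."""
    table = TECallTable(sample)
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if cols[0].lower() in ("chrom", "chromosome"):
                continue
            table.calls.append(TECall(
                cols[0], int(cols[1]),
                cols[2] if len(cols) > 2 else "",
                int(cols[3]) if len(cols) > 3 else 0,
                int(cols[4]) if len(cols) > 4 else 0))
    return table


def read_teflon_table(path, sample: str = "") -> TECallTable:
    """Column-mapping preset for TEFLoN genotype output.

    TEFLoN rows carry breakpoint coordinates in columns 2/3, the TE name in
    column 4, presence reads in column 10 and absence reads in column 11
    (0-based), per its documented output format.
    """
    table = TECallTable(sample)
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            bp = cols[1] if cols[1] != "-" else cols[2]
            table.calls.append(TECall(cols[0], int(bp), cols[3],
                                      int(cols[9]), int(cols[10])))
    return table


# ---------------------------------------------------------------------------
# Per-haplotype support estimation
# ---------------------------------------------------------------------------

def estimate_per_haplotype_support(supports: Sequence[int],
                                   n_bins: int = 256,
                                   smooth_fraction: float = 0.025) -> float:
    """Spacing of the read-support distribution peaks.

    The support histogram of insertions in a tetraploid genome is a mixture
    with modes near d, 2d, 3d, 4d where d is the read support contributed by
    one haplotype. The histogram is kernel-smoothed, peaks are located, each
    peak is assigned its nearest multiplier of the first peak, and the
    spacing is the least-squares regression of peak positions on multipliers
    through the origin. Binning and smoothing scale with the data, so the
    estimate is scale-equivariant.
    """
    from scipy.ndimage import gaussian_filter1d
    from scipy.signal import find_peaks

    supports = np.asarray(list(supports), dtype=float)
    if len(supports) < 50:
        warnings.warn("fewer than 50 support values; estimate may be unstable")
    if len(supports) == 0:
        raise ValueError("no support values")
    hi = float(supports.max())
    if hi <= 0:
        raise ValueError("support values must be positive")
    width = hi / n_bins
    edges = np.arange(0, hi + 2 * width, width)
    hist, _ = np.histogram(supports, bins=edges)
    # kernel width scales with the data range, so the estimate is
    # scale-equivariant and intra-peak sampling noise is smoothed out
    sigma = max(1.0, smooth_fraction * n_bins)
    smooth = gaussian_filter1d(hist.astype(float), sigma)
    # zero-pad so modes at the histogram boundaries are still peaks
    pad = int(4 * sigma) + 1
    padded = np.concatenate([np.zeros(pad), smooth, np.zeros(pad)])
    peaks, _ = find_peaks(padded, height=smooth.max() * 0.1)
    peaks = np.clip(peaks - pad, 0, len(hist) - 1)
    centers = np.unique((edges[peaks] + edges[peaks + 1]) / 2.0)
    if len(centers) == 0:
        # fully degenerate histogram (all mass in one bin)
        return float(np.median(supports))
    if len(centers) == 1:
        warnings.warn("unimodal support distribution; falling back to the "
                      "single mode")
        return float(centers[0])
    d0 = centers[0]
    ks = np.maximum(1, np.rint(centers / d0))
    return float((centers * ks).sum() / (ks * ks).sum())


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def insertion_haplotype_frequency(call: SVCall, track: CoverageTrack,
                                  cfg: ThresholdConfig | None = None,
                                  per_haplotype_support: float | None = None
                                  ) -> HaplotypeCall:
    """Frequency = round(support / per-haplotype support), clamped to
    [1, arm ploidy]; non-tetraploid or non-local calls keep tetraploid=False
    and are excluded from frequency spectra."""
    cfg = cfg or ThresholdConfig()
    d = per_haplotype_support or cfg.per_haplotype_support
    if call.support <= 0:
        raise ValueError("call has zero support; filter should have removed it")
    dist = call.breakpoint_distance
    local = (call.call_type == INSERTION and dist is not None
             and dist < 1_000)
    tetra = bool(local and call.chrom1 in track.depth
                 and is_tetraploid_window(track, call.chrom1, call.midpoint,
                                          cfg))
    ploidy = track.ploidy.get(call.chrom1, 4)
    freq = min(max(1, _round_half_away(call.support / d)), ploidy)
    return HaplotypeCall(call, call.support, d, freq, tetra)


def frequency_spectrum(hapcalls: Iterable[HaplotypeCall]) -> Counter:
    """Counts per haplotype frequency among tetraploid local insertions."""
    return Counter(h.frequency for h in hapcalls if h.tetraploid)


# ---------------------------------------------------------------------------
# Short-read TE cross-validation
# ---------------------------------------------------------------------------

def crossvalidate_te_calls(hapcalls: Sequence[HaplotypeCall],
                           tables: Mapping[str, TECallTable],
                           cfg: ThresholdConfig | None = None
                           ) -> list[HaplotypeCall]:
    """Assign provenance to long-read insertion calls.

    A call is cell-line specific iff it (1) overlaps an S2-DRSC short-read
    call within 250 bp, (2) is not called in S1 or S3, and (3) has a read
    spanning the matched short-read breakpoint in S1 or S3. Calls matching
    S2-DRSC but failing (2) or (3) were present in the progenitor ('all');
    calls with no S2-DRSC match stay unresolved.
    """
    cfg = cfg or ThresholdConfig()
    win = cfg.te_match_window
    norm = {k.lower().split("-")[0]: v for k, v in tables.items()}
    s2 = norm.get("s2")
    if s2 is None:
        raise ValueError("tables must include an S2(-DRSC) table")
    siblings = [t for k, t in norm.items() if k in ("s1", "s3")]
    for h in hapcalls:
        c = h.call
        pos = c.midpoint
        matches = s2.near(c.chrom1, pos, win)
        if not matches:
            h.provenance = PROVENANCE_UNRESOLVED
            continue
        called_sibling = any(
            any(t.support > 0 for t in tab.near(c.chrom1, pos, win))
            for tab in siblings)
        m = min(matches, key=lambda t: abs(t.pos - pos))
        spanning_sibling = any(
            any(t.spanning > 0 for t in tab.near(c.chrom1, m.pos, win))
            for tab in siblings)
        if not called_sibling and spanning_sibling:
            h.provenance = PROVENANCE_CELLLINE
        else:
            h.provenance = PROVENANCE_ALL
    return list(hapcalls)


def write_haplotype_tsv(hapcalls: Sequence[HaplotypeCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\telement\tsupport\tfrequency\ttetraploid\t"
                 "provenance\n")
        for h in hapcalls:
            c = h.call
            fh.write(f"{c.chrom1}\t{c.midpoint}\t{c.element or '.'}\t"
                     f"{h.support}\t{h.frequency}\t"
                     f"{int(h.tetraploid)}\t{h.provenance}\n")
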