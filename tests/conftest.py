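"""Shared fixtures: seeded simulated datasets and pipeline results."""

from __future__ import annotations

import pytest

from polysv.coverage_ploidy import bin_coverage
from polysv.formats_io import GenomeInterval, RefAlignment
from polysv.simulate import SimConfig, simulate_dataset
from polysv.sv_calls import run_calling_pipeline


def make_ref_alignment(read_id="r1", read_len=30_000, read_start=0,
                       read_end=10_000, chrom="chr1", start=0, end=10_000,
                       strand="+", score=None):
    a = RefAlignment(read_id=read_id, read_len=read_len,
                     read_start=read_start, read_end=read_end,
                     target=GenomeInterval(chrom, start, end, strand),
                     strand=strand, matches=read_end - read_start,
                     block_len=end - start)
    if score is not None:
        a.score = score
    return a


@pytest.fixture(scope="session")
def study_dataset():
    """The study-scale fixture: 2 x 2 Mb tetraploid autosomes, 1 Mb diploid
    X, 19 kb mitochondrial contig; 60 TE insertions, 10 duplications,
    2 reciprocal translocations plus deletions/inversions/one mito
    insertion; per-haplotype depth 44x."""
    return simulate_dataset(SimConfig(seed=1))


@pytest.fixture(scope="session")
def study_pipeline(study_dataset):
    ds = study_dataset
    kept, clustered, cont, acs = run_calling_pipeline(
        ds.ref_alignments, ds.ava, ds.read_lengths, ds.repeat_index)
    return {"kept": kept, "clustered": clustered, "containment": cont,
            "acs": acs, "dataset": ds}


@pytest.fixture(scope="session")
def study_track(study_dataset):
    return bin_coverage(alignments=study_dataset.ref_alignments,
                        chrom_lengths=study_dataset.genome.chrom_lengths)


@pytest.fixture(scope="session")
def sv_free_dataset():
    """A smaller fixture with no planted events at full depth."""
    cfg = SimConfig(seed=2, n_te_insertions=0, n_duplications=0,
                    n_translocations=0, n_deletions=0, n_inversions=0,
                    n_mito_insertions=0,
                    chrom_lengths={"chr2": 500_000, "chrX": 300_000})
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_dataset():
    """A quick low-depth fixture for unit-level checks."""
    cfg = SimConfig(seed=3, chrom_lengths={"chr2": 400_000, "chr3": 400_000},
                    n_te_insertions=6, n_duplications=2, n_translocations=1,
                    n_deletions=1, n_inversions=1, n_mito_insertions=0,
                    per_haplotype_depth=12)
    return simulate_dataset(cfg)
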