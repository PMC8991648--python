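"""Classify long reads as informative or contained from all-vs-all mappings.

A read is redundant for variant calling when it maps fully inside a longer
read: its unaligned head and tail (on its own coordinates) must each be at
most the containment end margin (default 750 bp), which absorbs mapping
noise at read ends. Only informative (non-contained) reads emit calls;
contained reads still contribute to breakpoint read support.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .formats_io import AvaMapping, ThresholdConfig

INFORMATIVE = "informative"
CONTAINED = "contained"


@dataclass
class ContainmentResult:
    read_id: str
    status: str
    container_id: str | None = None
    mapping: AvaMapping | None = None


def _contains(inner_len: int, inner_start: int, inner_end: int,
              outer_len: int, inner_id: str, outer_id: str,
              margin: int) -> bool:
    """True if the inner read's span sits within `margin` of both its ends
    and the outer read is longer (equal length ties break lexicographically:
    the smaller id stays informative)."""
    if inner_start > margin or inner_len - inner_end > margin:
        return False
    if outer_len > inner_len:
        return True
    return outer_len == inner_len and outer_id < inner_id


def classify_reads(reads: Mapping[str, int],
                   ava: Iterable[AvaMapping],
                   cfg: ThresholdConfig | None = None) -> dict[str, ContainmentResult]:
    """Partition reads into informative and contained.

    Either orientation of a mapping may witness containment (query inside
    target or target inside query). Containment chains are allowed: a read
    contained in an already-contained read remains contained.
    """
    cfg = cfg or ThresholdConfig()
    margin = cfg.containment_end_margin
    results = {rid: ContainmentResult(rid, INFORMATIVE) for rid in reads}
    for m in ava:
        if m.query_id not in reads:
            raise ValueError(f"all-vs-all mapping references unknown read "
                             f"{m.query_id!r}")
        if m.target_id not in reads:
            raise ValueError(f"all-vs-all mapping references unknown read "
                             f"{m.target_id!r}")
        # query contained in target?
        if _contains(m.query_len, m.query_start, m.query_end,
                     m.target_len, m.query_id, m.target_id, margin):
            r = results[m.query_id]
            if r.status == INFORMATIVE:
                r.status, r.container_id, r.mapping = CONTAINED, m.target_id, m
        # target contained in query?
        if _contains(m.target_len, m.target_start, m.target_end,
                     m.query_len, m.target_id, m.query_id, margin):
            r = results[m.target_id]
            if r.status == INFORMATIVE:
                r.status, r.container_id, r.mapping = CONTAINED, m.query_id, m
    return results


def informative_ids(results: Mapping[str, ContainmentResult]) -> set[str]:
    return {rid for rid, r in results.items() if r.status == INFORMATIVE}


def write_containment_tsv(results: Mapping[str, ContainmentResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tstatus\tcontainer_id\n")
        for rid in sorted(results):
            r = results[rid]
            fh.write(f"{rid}\t{r.status}\t{r.container_id or '.'}\n")
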