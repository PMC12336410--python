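"""Half-open interval arithmetic on a single chromosome.

All coordinates in this package are 0-based half-open internally; conversion
to/from the 1-based closed GTF/SAF convention happens only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A strand-aware genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"interval start must be < end (got [{self.start}, {self.end}))"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals as a disjoint sorted list.

    Strand and chromosome are carried through from the first interval; all
    inputs must agree on both (per-gene usage).  Adjacent (bookended)
    intervals are merged.
    """
    ivs = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    if not ivs:
        return []
    chrom, strand = ivs[0].chrom, ivs[0].strand
    for iv in ivs:
        if iv.chrom != chrom or iv.strand != strand:
            raise ValueError("merge_intervals requires a single chrom/strand")
    merged: list[tuple[int, int]] = [(ivs[0].start, ivs[0].end)]
    for iv in ivs[1:]:
        lo, hi = merged[-1]
        if iv.start <= hi:
            merged[-1] = (lo, max(hi, iv.end))
        else:
            merged.append((iv.start, iv.end))
    return [GenomicInterval(chrom, lo, hi, strand) for lo, hi in merged]


def subtract_intervals(
    span: GenomicInterval, blocks: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """``span`` minus the union of ``blocks``, as disjoint sorted intervals."""
    gaps: list[GenomicInterval] = []
    cursor = span.start
    for blk in merge_intervals(blocks):
        if blk.end <= span.start or blk.start >= span.end:
            continue
        if blk.start > cursor:
            gaps.append(GenomicInterval(span.chrom, cursor, blk.start, span.strand))
        cursor = max(cursor, blk.end)
    if cursor < span.end:
        gaps.append(GenomicInterval(span.chrom, cursor, span.end, span.strand))
    return gaps


def total_width(intervals: Iterable[GenomicInterval]) -> int:
    return sum(iv.width for iv in intervals)
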