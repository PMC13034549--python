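"""Genomic interval primitives.

All coordinates in this package are 0-based half-open on the forward
genomic strand; GTF (1-based inclusive) and narrowPeak/BED (already
half-open) are converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

VALID_STRANDS = {"+", "-", "."}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval [start, end) on a named sequence.

    ``strand`` is ``+`` or ``-`` for stranded features and ``.`` for
    strandless ones (e.g. coverage peaks, which inherit a strand only
    once assigned to a gene).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start >= self.end:
            raise ValueError(f"require start < end, got [{self.start}, {self.end})")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def with_strand(self, strand: str) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start, self.end, strand)


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or abutting intervals into a disjoint sorted list.

    All intervals must share one chrom; strand of the result is taken
    from the first interval.
    """
    ivs = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    if not ivs:
        return []
    chrom = ivs[0].chrom
    strand = ivs[0].strand
    if any(iv.chrom != chrom for iv in ivs):
        raise ValueError("merge_intervals requires a single chrom")
    merged: list[tuple[int, int]] = [(ivs[0].start, ivs[0].end)]
    for iv in ivs[1:]:
        s, e = merged[-1]
        if iv.start <= e:
            merged[-1] = (s, max(e, iv.end))
        else:
            merged.append((iv.start, iv.end))
    return [GenomicInterval(chrom, s, e, strand) for s, e in merged]


def intersect(
    query: GenomicInterval, targets: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Intersect ``query`` with a disjoint interval list; returns the fragments."""
    out = []
    for t in targets:
        if query.chrom != t.chrom:
            continue
        s = max(query.start, t.start)
        e = min(query.end, t.end)
        if s < e:
            out.append(GenomicInterval(query.chrom, s, e, t.strand))
    return sorted(out, key=lambda iv: iv.start)


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    return sum(iv.length for iv in intervals)
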