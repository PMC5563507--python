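"""Core genomic record types and interval algebra.

Coordinates follow the BED convention throughout: 0-based, half-open
``[start, end)``.  A peak summit is a single absolute base position and
must lie inside its peak interval.  Chromosome names are opaque strings;
no ``chr`` prefix normalization is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "GenomicInterval",
    "Peak",
    "GeneModel",
    "overlaps",
    "merge_overlapping",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be a nonempty string")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class Peak:
    """A called ChIP-seq binding interval with its summit coordinate.

    ``score`` carries the peak caller's significance measure (narrowPeak
    column 9, a -log10 q-value); ``source`` labels the TF/condition the
    peak set came from.
    """

    interval: GenomicInterval
    summit: int
    score: float = 0.0
    source: str = ""
    peak_id: str = ""

    def __post_init__(self) -> None:
        if not self.interval.contains(self.summit):
            raise ValueError(
                f"summit {self.summit} outside peak interval "
                f"{self.interval.chrom}:{self.interval.start}-{self.interval.end}"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass(frozen=True)
class GeneModel:
    """A gene body (transcription start to end) with strand.

    The body is the anchoring window for peak-to-gene association;
    window arithmetic is strand-symmetric, so strand is carried only
    as an annotation.
    """

    gene_id: str
    symbol: str
    body: GenomicInterval
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.gene_id:
            raise ValueError("gene_id must be nonempty")


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two intervals share at least one base."""
    return a.chrom == b.chrom and max(a.start, b.start) < min(a.end, b.end)


def merge_overlapping(
    intervals: Iterable[GenomicInterval],
) -> list[GenomicInterval]:
    """Collapse transitively overlapping intervals into their unions.

    Returns disjoint intervals sorted by (chrom, start, end).  Adjacent
    but non-overlapping intervals (half-open: ``a.end == b.start``) are
    NOT merged: merging requires >= 1 shared base.
    """
    ivs = sorted(intervals)
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start < merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(iv)
    return merged
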