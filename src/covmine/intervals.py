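"""Strand-aware genomic intervals and minimally-attributed aligned reads.

All coordinates are 0-based, half-open ``[start, end)`` throughout the
package.  1-based inclusive conventions (SAM, GTF/GFF3, the read TSV dump)
are converted at the I/O boundary and nowhere else.

A read carries only chromosome, start, end and strand: no sequence, no
qualities, no CIGAR.  This minimal attribute set is what makes the toolbox
independent of the sequencing platform and of mapper settings — any read
that the mapper accepted is a half-open interval, nothing more.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

from .errors import DomainError

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic range ``[start, end)`` on one strand.

    ``strand`` is ``"+"``, ``"-"`` or ``"."`` (unstranded).  ``start`` is
    0-based inclusive, ``end`` exclusive; the interval always spans at least
    one nucleotide.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise DomainError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise DomainError(
                f"empty interval: start={self.start} >= end={self.end}"
            )
        if self.strand not in STRANDS:
            raise DomainError(f"strand must be one of {STRANDS}: {self.strand!r}")

    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 nucleotide (strand ignored)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def intersection(self, other: "GenomicInterval") -> "GenomicInterval":
        if not self.overlaps(other):
            raise DomainError(f"intervals do not overlap: {self} / {other}")
        return GenomicInterval(
            self.chrom,
            max(self.start, other.start),
            min(self.end, other.end),
            self.strand,
        )

    def shifted(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(
            self.chrom, self.start + offset, self.end + offset, self.strand
        )

    def strand_matches(self, strand: str) -> bool:
        """Strand compatibility: ``"."`` on either side matches everything."""
        return self.strand == "." or strand == "." or self.strand == strand

    def __str__(self) -> str:  # chrN:start-end(strand), BED-like half-open
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"


@dataclass(frozen=True)
class AlignedRead:
    """One mapped read reduced to its genomic footprint."""

    interval: GenomicInterval
    sample_id: str = ""

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


class ReadSet:
    """Reads of one sample restricted to a region.

    Reads are stored sorted by (start, end); every read overlaps the region
    by at least one nucleotide.  Reads may extend past the region boundary —
    the pileup clips them, it never drops them — so chunked scans of a
    chromosome stay exact.
    """

    def __init__(
        self,
        region: GenomicInterval,
        reads: Iterable[AlignedRead] = (),
        sample_id: str = "",
    ):
        self.region = region
        self.sample_id = sample_id
        reads = sorted(reads, key=lambda r: (r.start, r.end))
        for r in reads:
            if not r.interval.overlaps(region):
                raise DomainError(
                    f"read {r.interval} does not overlap region {region}"
                )
        self.reads: Sequence[AlignedRead] = tuple(reads)

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self) -> Iterator[AlignedRead]:
        return iter(self.reads)

    def subset(self, interval: GenomicInterval) -> "ReadSet":
        """Reads overlapping ``interval`` (same chromosome), as a new ReadSet."""
        if interval.chrom != self.region.chrom:
            raise DomainError(
                f"chromosome mismatch: {interval.chrom} vs {self.region.chrom}"
            )
        return ReadSet(
            interval,
            (r for r in self.reads if r.interval.overlaps(interval)),
            self.sample_id,
        )


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals on one chromosome, as sorted disjoint intervals.

    Adjacent (touching) intervals are merged.  Strand of each output interval
    is taken from the first interval of its merged run.
    """
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(
                    last.chrom, last.start, iv.end, last.strand
                )
        else:
            merged.append(iv)
    return merged
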