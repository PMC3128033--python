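"""Per-nucleotide coverage tracks and the pileup that builds them.

The coverage function — number of reads overlapping each nucleotide — is
the central object of the toolbox: every downstream transformation
(smoothing, fold change, splicing index, region-based coverage) is a map
from one ``CoverageTrack`` to another, and region mining consumes a track.
"""

from __future__ import annotations

import enum
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import BoundsError, ConfigurationError, DomainError, SampleLookupError
from .intervals import GenomicInterval, ReadSet


class TrackKind(enum.Enum):
    """What the values of a track mean."""

    COUNTS = "counts"
    NORMALIZED = "normalized"
    SMOOTHED = "smoothed"
    FOLD_CHANGE = "fold_change"
    SPLICING_INDEX = "splicing_index"
    REGION_BASED = "region_based"


class StrandMode(enum.Enum):
    """Whether the pileup respects strand.

    ``SAME_STRAND`` counts reads whose strand equals the region's strand
    (plus unstranded "." reads, which are protocol-agnostic and counted in
    every mode).  ``IGNORE_STRAND`` counts everything.
    """

    SAME_STRAND = "same_strand"
    IGNORE_STRAND = "ignore_strand"


class CountingRule(enum.Enum):
    ANY_OVERLAP = "any_overlap"
    CONTAINED = "contained"


class CoverageTrack:
    """Per-nucleotide values over one region for one or more samples.

    ``values`` has shape ``(n_samples, region.length())``; row order follows
    ``samples``.
    """

    def __init__(
        self,
        region: GenomicInterval,
        samples: Sequence[str],
        values: np.ndarray,
        kind: TrackKind = TrackKind.COUNTS,
    ):
        values = np.atleast_2d(np.asarray(values))
        if values.shape != (len(samples), region.length()):
            raise DomainError(
                f"values shape {values.shape} != "
                f"({len(samples)}, {region.length()})"
            )
        if kind is TrackKind.COUNTS:
            if np.any(values < 0) or not np.all(np.equal(np.mod(values, 1), 0)):
                raise DomainError("COUNTS tracks must hold non-negative integers")
        self.region = region
        self.samples = list(samples)
        self.values = values
        self.kind = kind

    def sample_values(self, sample: str) -> np.ndarray:
        try:
            idx = self.samples.index(sample)
        except ValueError:
            raise SampleLookupError(
                f"sample {sample!r} not in track ({self.samples})"
            ) from None
        return self.values[idx]

    def with_values(self, values: np.ndarray, kind: TrackKind) -> "CoverageTrack":
        return CoverageTrack(self.region, self.samples, values, kind)

    def __len__(self) -> int:
        return self.region.length()


def pileup_coverage(
    readset: ReadSet,
    strand_mode: StrandMode = StrandMode.IGNORE_STRAND,
) -> CoverageTrack:
    """Build the coverage function of a read set over its region.

    Value at position p = number of reads whose interval contains p.  Reads
    extending past the region contribute only their overlapping part.  In
    ``SAME_STRAND`` mode only reads on the region's strand (or unstranded
    "." reads) are counted; the region must then be stranded.
    """
    region = readset.region
    if strand_mode is StrandMode.SAME_STRAND and region.strand == ".":
        raise ConfigurationError(
            "SAME_STRAND pileup requires a stranded region (+ or -)"
        )
    n = region.length()
    # difference-array pileup: +1 at each clipped start, -1 past each end
    diff = np.zeros(n + 1, dtype=np.int64)
    for read in readset:
        if strand_mode is StrandMode.SAME_STRAND and not read.interval.strand_matches(
            region.strand
        ):
            continue
        s = max(read.start, region.start) - region.start
        e = min(read.end, region.end) - region.start
        if s < e:
            diff[s] += 1
            diff[e] -= 1
    values = np.cumsum(diff[:-1])
    return CoverageTrack(region, [readset.sample_id], values[None, :], TrackKind.COUNTS)


def region_count(
    readset: ReadSet,
    interval: GenomicInterval,
    rule: CountingRule = CountingRule.ANY_OVERLAP,
) -> int:
    """Number of reads overlapping (or fully contained in) an interval.

    Strand-matched against ``interval.strand`` unless the interval is
    unstranded; "." reads always count.  This is the read-count denominator
    used by the splicing index and the entry of an exported count table.
    """
    if interval.chrom != readset.region.chrom:
        raise DomainError(
            f"chromosome mismatch: {interval.chrom} vs {readset.region.chrom}"
        )
    n = 0
    for read in readset:
        if not read.interval.strand_matches(interval.strand):
            continue
        if rule is CountingRule.ANY_OVERLAP:
            hit = read.interval.overlaps(interval)
        else:
            hit = interval.contains(read.interval)
        if hit:
            n += 1
    return n


def slice_track(track: CoverageTrack, sub: GenomicInterval) -> CoverageTrack:
    """Restrict a track to a sub-interval of its region; kind is preserved."""
    region = track.region
    if sub.chrom != region.chrom or sub.start < region.start or sub.end > region.end:
        raise BoundsError(f"{sub} is not inside {region}")
    lo = sub.start - region.start
    hi = sub.end - region.start
    return CoverageTrack(sub, track.samples, track.values[:, lo:hi], track.kind)


def stack_tracks(tracks: Iterable[CoverageTrack]) -> CoverageTrack:
    """Combine single-sample tracks over the same region into one track."""
    tracks = list(tracks)
    if not tracks:
        raise DomainError("no tracks to stack")
    region = tracks[0].region
    kind = tracks[0].kind
    samples: list[str] = []
    rows = []
    for t in tracks:
        if t.region != region:
            raise DomainError(f"region mismatch: {t.region} vs {region}")
        if t.kind is not kind:
            raise DomainError("cannot stack tracks of different kinds")
        samples.extend(t.samples)
        rows.append(t.values)
    return CoverageTrack(region, samples, np.vstack(rows), kind)


def pileup_samples(
    readsets: Mapping[str, ReadSet],
    strand_mode: StrandMode = StrandMode.IGNORE_STRAND,
) -> CoverageTrack:
    """Pile up several samples over the same region into one multi-row track."""
    return stack_tracks(
        pileup_coverage(rs, strand_mode) for rs in readsets.values()
    )
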