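"""Annotation-free discovery: region categories, chunked scans, count tables.

The pipeline dissects each chromosome into gene regions, flank-extended
gene regions and intergenic spaces, piles up coverage per region and per
sample (in bounded-memory chunks where regions are long), mines irreducible
regions, keeps loci supported by enough samples, and exports read counts in
genes and in the surviving novel regions for downstream count-based
differential-expression tools.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import AnnotationSet
from .coverage import (
    CountingRule,
    CoverageTrack,
    StrandMode,
    pileup_coverage,
    region_count,
)
from .errors import ConfigurationError
from .intervals import GenomicInterval, ReadSet, merge_intervals
from .mining import (
    IrreducibleRegion,
    MiningParams,
    find_irreducible_regions,
    maximal_irreducible_intervals,
    support_count,
)
from .transforms import SmoothingParams, lowess_smooth

#: a source of reads: called with an interval, returns that sample's ReadSet
ReadSource = Callable[[GenomicInterval], ReadSet]


class Category(enum.Enum):
    GENIC = "genic"
    EXTENDED = "extended"
    INTERGENIC = "intergenic"


DEFAULT_FLANK = 1_000
DEFAULT_CHUNK_SIZE = 2_000_000
DEFAULT_CHUNK_OVERLAP = 10_000


# ---------------------------------------------------------------------------
# region categories


def gene_regions(ann: AnnotationSet, chrom: str, strand: str = ".") -> list[GenomicInterval]:
    """Gene intervals on (chrom, strand), sorted by start."""
    return [g.interval for g in ann.genes_on(chrom, strand)]


def extended_gene_regions(ann: AnnotationSet, flank: int = DEFAULT_FLANK) -> list[GenomicInterval]:
    """Every gene widened by ``flank`` nt both sides, clamped to the
    chromosome — the scan that finds expression running past annotated
    boundaries."""
    if flank < 0:
        raise ConfigurationError(f"flank must be >= 0: {flank}")
    out = []
    for g in sorted(ann.genes, key=lambda g: (g.interval.chrom, g.interval.start)):
        iv = g.interval
        length = ann.chrom_lengths[iv.chrom]
        out.append(
            GenomicInterval(
                iv.chrom,
                max(0, iv.start - flank),
                min(length, iv.end + flank),
                iv.strand,
            )
        )
    return out


def intergenic_regions(ann: AnnotationSet, chrom: str, strand: str = ".") -> list[GenomicInterval]:
    """Complement of the (merged) gene union on (chrom, strand) within
    [0, chrom_length): the search space for novel transcribed regions."""
    length = ann.require_chrom(chrom)
    merged = merge_intervals(gene_regions(ann, chrom, strand))
    out: list[GenomicInterval] = []
    pos = 0
    for iv in merged:
        if iv.start > pos:
            out.append(GenomicInterval(chrom, pos, iv.start, strand))
        pos = max(pos, iv.end)
    if pos < length:
        out.append(GenomicInterval(chrom, pos, length, strand))
    return out


def chunk_iterator(
    interval: GenomicInterval, chunk_size: int, overlap: int
) -> Iterator[GenomicInterval]:
    """Slice a long interval into overlapping chunks of bounded size.

    Consecutive chunks share exactly ``overlap`` nucleotides, so any mined
    region no longer than the overlap lies wholly inside at least one
    chunk; the caller deduplicates by canonical coordinates.
    """
    if overlap < 0 or chunk_size <= 2 * overlap:
        raise ConfigurationError(
            f"need chunk_size > 2*overlap, got {chunk_size} <= 2*{overlap}"
        )
    step = chunk_size - overlap
    pos = interval.start
    while True:
        end = min(pos + chunk_size, interval.end)
        yield GenomicInterval(interval.chrom, pos, end, interval.strand)
        if end >= interval.end:
            return
        pos += step


# ---------------------------------------------------------------------------
# count tables


@dataclass
class CountTable:
    """Read counts for labelled regions x samples, exportable as the input
    table of count-based differential-expression tools."""

    labels: list[str]
    samples: list[str]
    counts: np.ndarray  # (n_regions, n_samples) non-negative ints
    intervals: list[GenomicInterval] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.labels), len(self.samples)):
            raise ConfigurationError(
                f"counts shape {self.counts.shape} != "
                f"({len(self.labels)}, {len(self.samples)})"
            )
        if np.any(self.counts < 0):
            raise ConfigurationError("counts must be non-negative")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=pd.Index(self.labels, name="region"), columns=self.samples
        )


def build_count_table(
    read_sources: Mapping[str, ReadSource],
    regions: Sequence[tuple[str, GenomicInterval]],
    rule: CountingRule = CountingRule.ANY_OVERLAP,
) -> CountTable:
    """Count reads per labelled region per sample."""
    if not read_sources or not regions:
        raise ConfigurationError("need at least one sample and one region")
    samples = list(read_sources)
    counts = np.zeros((len(regions), len(samples)), dtype=np.int64)
    for i, (_label, iv) in enumerate(regions):
        for j, sample in enumerate(samples):
            counts[i, j] = region_count(read_sources[sample](iv), iv, rule)
    return CountTable(
        [label for label, _ in regions], samples, counts, [iv for _, iv in regions]
    )


# ---------------------------------------------------------------------------
# chunked mining


def _dedup_chunked(regions: list[IrreducibleRegion]) -> list[IrreducibleRegion]:
    """Canonicalise regions mined from overlapping chunks: drop duplicates
    and any region contained in a longer one (a chunk-boundary fragment of
    a region that another chunk saw whole)."""
    regions = sorted(
        regions, key=lambda r: (r.interval.start, -r.interval.length())
    )
    out: list[IrreducibleRegion] = []
    for r in regions:
        if out and out[-1].interval.contains(r.interval):
            continue
        out.append(r)
    return out


def mine_region_chunked(
    source: ReadSource,
    region: GenomicInterval,
    params: MiningParams,
    strand_mode: StrandMode = StrandMode.IGNORE_STRAND,
    smoothing: SmoothingParams | None = None,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
    chunk_overlap: int = DEFAULT_CHUNK_OVERLAP,
) -> list[IrreducibleRegion]:
    """Pile up and mine one (possibly chromosome-sized) region in chunks.

    Maximality is resolved across chunk boundaries before the width filter:
    each chunk is mined without the filter, fragments contained in a longer
    region from a neighbouring chunk are dropped, and ``minsup`` is applied
    to the surviving canonical regions.  Results equal an unchunked run
    whenever every true region is shorter than the chunk overlap.
    """
    no_filter = MiningParams(params.mu, 1, params.strict)
    collected: list[IrreducibleRegion] = []
    for chunk in chunk_iterator(region, chunk_size, chunk_overlap):
        track = pileup_coverage(source(chunk), strand_mode)
        if smoothing is not None and chunk.length() >= 10:
            track = lowess_smooth(track, smoothing)
        collected.extend(find_irreducible_regions(track, track.samples[0], no_filter))
    return [
        IrreducibleRegion(r.interval, r.mean_value, params)
        for r in _dedup_chunked(collected)
        if r.interval.length() >= params.minsup
    ]


# ---------------------------------------------------------------------------
# the discovery pipeline


@dataclass(frozen=True)
class DiscoveredRegion:
    """One locus surviving the cross-sample support filter."""

    interval: GenomicInterval
    category: Category
    label: str
    n_samples: int  # samples contributing a mined region to this locus


@dataclass
class DiscoveryResult:
    regions: list[DiscoveredRegion]
    counts: CountTable
    support: pd.DataFrame  # rows (mu, minsup), columns X = 1..n_samples
    per_gene_support: dict[str, int] = field(default_factory=dict)


def _strands_for(mode: StrandMode) -> tuple[str, ...]:
    return ("+", "-") if mode is StrandMode.SAME_STRAND else (".",)


def _group_loci(
    per_sample: Mapping[str, list[IrreducibleRegion]], min_samples: int
) -> list[tuple[GenomicInterval, int]]:
    """Merge per-sample regions into loci; keep loci with >= min_samples
    contributing samples."""
    all_ivs = [r.interval for regions in per_sample.values() for r in regions]
    loci = merge_intervals(all_ivs)
    out = []
    for locus in loci:
        n = support_count(per_sample, locus)
        if n >= min_samples:
            out.append((locus, n))
    return out


def discover(
    read_sources: Mapping[str, ReadSource],
    ann: AnnotationSet,
    params: MiningParams,
    categories: Iterable[Category] = (Category.GENIC,),
    min_samples: int = 1,
    strand_mode: StrandMode = StrandMode.SAME_STRAND,
    smoothing: SmoothingParams | None = None,
    flank: int = DEFAULT_FLANK,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
    chunk_overlap: int = DEFAULT_CHUNK_OVERLAP,
    rule: CountingRule = CountingRule.ANY_OVERLAP,
) -> DiscoveryResult:
    """Run the full discovery pipeline over every chromosome.

    For each requested category the regions are scanned per (chromosome,
    strand), mined per sample, and loci supported by at least
    ``min_samples`` samples are kept.  A discovered locus overlapping any
    annotated gene is labelled GENIC regardless of the scan that found it.
    The count table reports every annotated gene plus every surviving
    novel (EXTENDED/INTERGENIC) locus; the support summary counts genes
    containing irreducible regions in >= X of N samples for the given
    parameters.
    """
    if not read_sources:
        raise ConfigurationError("at least one sample back-end is required")
    categories = set(categories)
    n_samples = len(read_sources)

    def mine_all_samples(region: GenomicInterval) -> dict[str, list[IrreducibleRegion]]:
        return {
            sample: mine_region_chunked(
                source, region, params, strand_mode, smoothing, chunk_size, chunk_overlap
            )
            for sample, source in read_sources.items()
        }

    discovered: list[DiscoveredRegion] = []
    per_gene_support: dict[str, int] = {}
    gene_union = merge_intervals(
        [g.interval for g in ann.genes]
    )  # strand-blind, for category labelling

    def overlaps_gene(iv: GenomicInterval) -> bool:
        return any(iv.overlaps(g) for g in gene_union)

    for chrom in sorted(ann.chrom_lengths):
        for strand in _strands_for(strand_mode):
            genes = ann.genes_on(chrom, strand) if strand != "." else ann.genes_on(chrom)
            genes = [g for g in genes if g.interval.chrom == chrom]
            if Category.GENIC in categories or Category.EXTENDED in categories:
                for g in genes:
                    scan_iv = g.interval
                    if Category.EXTENDED in categories:
                        length = ann.chrom_lengths[chrom]
                        scan_iv = GenomicInterval(
                            chrom,
                            max(0, g.interval.start - flank),
                            min(length, g.interval.end + flank),
                            g.interval.strand,
                        )
                    if strand == ".":
                        scan_iv = GenomicInterval(
                            scan_iv.chrom, scan_iv.start, scan_iv.end, "."
                        )
                    per_sample = mine_all_samples(scan_iv)
                    per_gene_support[g.gene_id] = support_count(per_sample, g.interval)
                    for locus, n in _group_loci(per_sample, min_samples):
                        cat = (
                            Category.GENIC
                            if overlaps_gene(locus)
                            else Category.EXTENDED
                        )
                        if cat is Category.GENIC and Category.GENIC not in categories:
                            continue
                        label = (
                            g.gene_id
                            if cat is Category.GENIC
                            else f"{g.gene_id}_ext:{locus.start}-{locus.end}"
                        )
                        discovered.append(DiscoveredRegion(locus, cat, label, n))
            if Category.INTERGENIC in categories:
                for gap in intergenic_regions(ann, chrom, strand):
                    per_sample = mine_all_samples(gap)
                    for locus, n in _group_loci(per_sample, min_samples):
                        discovered.append(
                            DiscoveredRegion(
                                locus,
                                Category.INTERGENIC,
                                f"novel:{chrom}:{locus.start}-{locus.end}({strand})",
                                n,
                            )
                        )

    # count table: all annotated genes + surviving novel loci
    count_regions: list[tuple[str, GenomicInterval]] = [
        (g.gene_id, g.interval)
        for g in sorted(ann.genes, key=lambda g: (g.interval.chrom, g.interval.start))
    ]
    seen_labels = {label for label, _ in count_regions}
    for d in discovered:
        if d.category is not Category.GENIC and d.label not in seen_labels:
            count_regions.append((d.label, d.interval))
            seen_labels.add(d.label)
    counts = build_count_table(read_sources, count_regions, rule)

    support = pd.DataFrame(
        {
            X: [sum(1 for v in per_gene_support.values() if v >= X)]
            for X in range(1, n_samples + 1)
        },
        index=pd.MultiIndex.from_tuples(
            [(params.mu, params.minsup)], names=["mu", "minsup"]
        ),
    )
    discovered.sort(key=lambda d: (d.interval.chrom, d.interval.start, d.interval.end))
    return DiscoveryResult(discovered, counts, support, per_gene_support)


def support_summary(
    read_sources: Mapping[str, ReadSource],
    ann: AnnotationSet,
    mus: Sequence[float],
    minsups: Sequence[int],
    strand_mode: StrandMode = StrandMode.SAME_STRAND,
    smoothing: SmoothingParams | None = None,
) -> pd.DataFrame:
    """Genes containing irreducible regions in >= X of N samples, for a grid
    of (mu, minsup): rows (mu, minsup), columns X = 1..N.

    Counts are monotone non-increasing along X, along mu and along minsup.
    """
    n_samples = len(read_sources)
    rows = {}
    # pile up once per gene/sample and mine once per mu; the minsup filter
    # is applied to the cached maximal intervals, so the grid costs one
    # mining pass per (gene, sample, mu)
    widths: list[dict[str, dict[float, list[int]]]] = []
    for g in sorted(ann.genes, key=lambda g: (g.interval.chrom, g.interval.start)):
        per_sample: dict[str, dict[float, list[int]]] = {}
        for sample, source in read_sources.items():
            track = pileup_coverage(source(g.interval), strand_mode)
            if smoothing is not None and g.interval.length() >= 10:
                track = lowess_smooth(track, smoothing)
            values = track.sample_values(sample)
            per_sample[sample] = {
                mu: [e - s for s, e in maximal_irreducible_intervals(values, mu)]
                for mu in mus
            }
        widths.append(per_sample)
    for mu in mus:
        for minsup in minsups:
            support_counts = [
                sum(
                    1
                    for per_mu in per_sample.values()
                    if any(w >= minsup for w in per_mu[mu])
                )
                for per_sample in widths
            ]
            rows[(mu, minsup)] = [
                sum(1 for v in support_counts if v >= X)
                for X in range(1, n_samples + 1)
            ]
    return pd.DataFrame(
        rows.values(),
        index=pd.MultiIndex.from_tuples(rows.keys(), names=["mu", "minsup"]),
        columns=pd.Index(range(1, n_samples + 1), name="X"),
    )
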