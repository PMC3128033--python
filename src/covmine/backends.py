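"""Read-level back-ends: indexed BAM/SAM and the plain-text read table.

Both back-ends deliver the same thing — a ``ReadSet`` of minimally
attributed reads overlapping a query interval — so any pipeline result is
identical whichever storage the reads came from.  The read TSV is the kind
of table a one-line AWK script produces from SAM: chrom, start and end
1-based inclusive, strand, sample id.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pysam

from .errors import DomainError
from .intervals import AlignedRead, GenomicInterval, ReadSet
from .discovery import ReadSource


class BackEndFormat:
    BAM = "bam"
    READ_TSV = "read_tsv"


@dataclass(frozen=True)
class BackEndConfig:
    """One sample's read source.

    ``min_mapq`` and ``include_secondary`` control BAM filtering; defaults
    keep every primary mapped read, leaving mapper stringency to the user.
    """

    path: str
    format: str  # BackEndFormat.BAM or BackEndFormat.READ_TSV
    sample_id: str
    min_mapq: int = 0
    include_secondary: bool = False

    def __post_init__(self) -> None:
        if self.format not in (BackEndFormat.BAM, BackEndFormat.READ_TSV):
            raise DomainError(f"unknown back-end format: {self.format!r}")
        if self.min_mapq < 0:
            raise DomainError("min_mapq must be >= 0")

    def source(self) -> ReadSource:
        """As a callable interval -> ReadSet (the shape discovery expects)."""
        return lambda interval: fetch_reads(self, interval)


def backend_for(path: str | Path, sample_id: str, **kwargs) -> BackEndConfig:
    """Guess the back-end format from the file extension."""
    fmt = (
        BackEndFormat.BAM
        if str(path).endswith((".bam", ".sam", ".cram"))
        else BackEndFormat.READ_TSV
    )
    return BackEndConfig(str(path), fmt, sample_id, **kwargs)


def fetch_reads(cfg: BackEndConfig, interval: GenomicInterval) -> ReadSet:
    """Reads of one sample overlapping an interval, minimally attributed.

    Unmapped reads are always excluded; secondary/supplementary alignments
    unless ``include_secondary``; alignments below ``min_mapq``.  A query
    on a chromosome absent from the file returns an empty ReadSet — scans
    over sparse data should not crash on empty space.
    """
    if cfg.format == BackEndFormat.BAM:
        return _fetch_bam(cfg, interval)
    return read_read_tsv(cfg.path, interval, sample_id=cfg.sample_id)


def _fetch_bam(cfg: BackEndConfig, interval: GenomicInterval) -> ReadSet:
    mode = "r" if cfg.path.endswith(".sam") else "rb"
    with pysam.AlignmentFile(cfg.path, mode) as bam:
        if interval.chrom not in bam.references:
            return ReadSet(interval, (), cfg.sample_id)
        try:
            it = bam.fetch(interval.chrom, interval.start, interval.end)
            reads = []
            for aln in it:
                if aln.is_unmapped:
                    continue
                if (aln.is_secondary or aln.is_supplementary) and not cfg.include_secondary:
                    continue
                if aln.mapping_quality < cfg.min_mapq:
                    continue
                strand = "-" if aln.is_reverse else "+"
                reads.append(
                    AlignedRead(
                        GenomicInterval(
                            interval.chrom,
                            aln.reference_start,
                            aln.reference_end,
                            strand,
                        ),
                        cfg.sample_id,
                    )
                )
        except ValueError as exc:
            raise IOError(
                f"cannot fetch from {cfg.path}: {exc} "
                f"(is the file coordinate-sorted and indexed? "
                f"run `samtools sort` / `samtools index`)"
            ) from exc
    return ReadSet(interval, reads, cfg.sample_id)


READ_TSV_HEADER = "chrom\tstart\tend\tstrand\tsample_id"


def write_read_tsv(readset: ReadSet, path: str | Path) -> None:
    """Dump a ReadSet as the plain-text read table.

    Start and end are written 1-based inclusive (SAM-style), so a read
    stored internally as [10, 60) appears as start=11, end=60.
    """
    with open(path, "w") as fh:
        fh.write("# read table; start and end are 1-based inclusive\n")
        fh.write(READ_TSV_HEADER + "\n")
        for r in readset:
            iv = r.interval
            fh.write(
                f"{iv.chrom}\t{iv.start + 1}\t{iv.end}\t{iv.strand}\t"
                f"{r.sample_id or readset.sample_id}\n"
            )


def read_read_tsv(
    path: str | Path,
    interval: GenomicInterval,
    sample_id: str | None = None,
) -> ReadSet:
    """Load reads overlapping ``interval`` from a read table.

    When ``sample_id`` is given only that sample's rows are kept; otherwise
    it is taken from the rows (which must then agree).
    """
    reads = []
    seen_samples: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line == READ_TSV_HEADER:
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise DomainError(
                    f"{path}:{lineno}: expected 5 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, start1, end1, strand, sid = fields
            try:
                start = int(start1) - 1  # 1-based inclusive -> half-open
                end = int(end1)
            except ValueError:
                raise DomainError(f"{path}:{lineno}: non-integer coordinates") from None
            if chrom != interval.chrom:
                continue
            if sample_id is not None and sid != sample_id:
                continue
            iv = GenomicInterval(chrom, start, end, strand)
            if iv.overlaps(interval):
                reads.append(AlignedRead(iv, sid))
                seen_samples.add(sid)
    if sample_id is None:
        if len(seen_samples) > 1:
            raise DomainError(
                f"{path} holds several samples {sorted(seen_samples)}; "
                f"pass sample_id to select one"
            )
        sample_id = next(iter(seen_samples), "")
    return ReadSet(interval, reads, sample_id)
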