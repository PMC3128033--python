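"""Text writers: bedGraph for tracks, BED6 for mined regions, TSV for
count tables.  All outputs are tab-delimited, newline-terminated UTF-8 with
0-based half-open coordinates (the native BED/bedGraph convention)."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .coverage import CoverageTrack
from .discovery import CountTable
from .errors import DomainError
from .mining import IrreducibleRegion


def write_bedgraph(
    track: CoverageTrack,
    path: str | Path,
    sample: str | None = None,
    zero_suppress: bool = True,
    track_line: bool = True,
) -> None:
    """Write one sample of a track as bedGraph, merging runs of equal value.

    Zero runs are omitted by default (bedGraph convention for sparse
    coverage); pass ``zero_suppress=False`` to keep them.
    """
    if sample is None:
        if len(track.samples) != 1:
            raise DomainError("sample must be given for a multi-sample track")
        sample = track.samples[0]
    values = np.asarray(track.sample_values(sample))
    region = track.region
    with open(path, "w") as fh:
        if track_line:
            fh.write(
                f'track type=bedGraph name="{sample}:{track.kind.value}"\n'
            )
        if len(values) == 0:
            return
        breaks = np.nonzero(np.diff(values))[0] + 1
        starts = np.concatenate(([0], breaks))
        ends = np.concatenate((breaks, [len(values)]))
        for s, e in zip(starts, ends):
            v = values[s]
            if zero_suppress and v == 0:
                continue
            out = int(v) if float(v).is_integer() else float(v)
            fh.write(f"{region.chrom}\t{region.start + s}\t{region.start + e}\t{out}\n")


def read_bedgraph(path: str | Path) -> list[tuple[str, int, int, float]]:
    """Parse a bedGraph file back into (chrom, start, end, value) rows."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            chrom, start, end, value = line.split("\t")
            rows.append((chrom, int(start), int(end), float(value)))
    return rows


def write_bed(
    regions: Iterable[IrreducibleRegion],
    path: str | Path,
    sample: str = "",
) -> None:
    """Write mined regions as BED6.

    name = sample:mu:minsup, score = round(mean value) clipped to the BED
    0..1000 range, strand from the region.
    """
    with open(path, "w") as fh:
        for r in sorted(regions, key=lambda r: (r.interval.chrom, r.interval.start)):
            iv = r.interval
            name = f"{sample}:{r.params.mu:g}:{r.params.minsup}"
            score = int(min(1000, max(0, round(r.mean_value))))
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
            )


def read_bed(path: str | Path) -> list[tuple[str, int, int, str, int, str]]:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            f = line.split("\t")
            rows.append((f[0], int(f[1]), int(f[2]), f[3], int(f[4]), f[5]))
    return rows


def write_counts_tsv(table: CountTable, path: str | Path) -> None:
    """Count table as TSV: header row of sample ids, first column of region
    labels — directly loadable by count-based DE tools."""
    table.to_dataframe().to_csv(path, sep="\t")


def read_counts_tsv(path: str | Path) -> CountTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountTable(
        [str(i) for i in df.index],
        [str(c) for c in df.columns],
        df.to_numpy(dtype=np.int64),
    )


def write_discovered_bed(regions, path: str | Path) -> None:
    """Discovered loci (category-labelled) as BED6; score = supporting
    sample count, name = label|category."""
    with open(path, "w") as fh:
        for d in regions:
            iv = d.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{d.label}|{d.category.value}\t"
                f"{d.n_samples}\t{iv.strand}\n"
            )
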