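"""Seeded RNA-seq read simulator with a ground-truth manifest.

The generator emulates the statistical structure the analyses assume:
genes with exon/intron structure laid out on both strands of one
chromosome, per-exon read counts drawn from a negative binomial law
(RNA-seq counts are over-dispersed: variance = mean + dispersion * mean^2),
uniform read placement within exons, a thin uniform background of noise
reads, and occasional single-position stacks of duplicated reads imitating
PCR over-amplification towers.  It writes the same data through every
back-end format (coordinate-sorted indexed BAM and the read TSV), plus
GFF3 and gene-TSV annotations and a JSON manifest recording the planted
truth — exon intervals, per-sample per-exon counts, artifact positions —
so recovery can be scored exactly.

No junction reads are generated: reads never span introns, matching the
package's treatment of every alignment as a single block.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .annotation import AnnotationSet, GeneModel, write_gene_tsv, write_gff3
from .errors import ConfigurationError
from .intervals import AlignedRead, GenomicInterval, ReadSet
from .backends import write_read_tsv


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of a simulated experiment.

    Defaults give ~40x exon coverage (expression_mean reads of 50 bp on
    exons of 200-500 nt) against a ~0.1x background — the regime where
    expressed exons stand far above a detection threshold of 5 and the
    mining contract is meaningfully exercised.
    """

    seed: int = 0
    n_genes: int = 50
    n_samples: int = 6
    chrom: str = "chrSim"
    chrom_length: int = 4_000_000
    read_length: int = 50
    exons_per_gene: tuple[int, int] = (2, 5)  # inclusive range
    exon_length: tuple[int, int] = (200, 500)
    # mammalian-scale introns, long enough that the miner's dip tolerance
    # does not bridge them at the default signal strength (see docs)
    intron_length: tuple[int, int] = (8_000, 15_000)
    expression_mean: float = 300.0  # mean reads per exon per sample
    dispersion: float = 0.2  # NB: variance = mean + dispersion * mean^2
    background_rate: float = 2.0  # noise reads per kb per sample
    artifact_peak_rate: float = 0.1  # per gene per sample
    artifact_stack: int = 30  # duplicated reads in one artifact tower

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_samples, self.chrom_length, self.read_length) <= 0:
            raise ConfigurationError("all counts must be positive")
        if self.exon_length[0] <= self.read_length:
            raise ConfigurationError(
                "exons must be longer than a read so reads fit inside them"
            )
        if self.dispersion < 0 or self.expression_mean <= 0:
            raise ConfigurationError("expression_mean > 0 and dispersion >= 0 required")


@dataclass
class SimulatedGene:
    gene_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval]


@dataclass
class Manifest:
    """Planted truth of one simulation."""

    config: SimulationConfig
    genes: list[SimulatedGene]
    samples: list[str]
    # per sample -> per gene -> per-exon expression read counts
    exon_counts: dict[str, dict[str, list[int]]]
    # per sample -> per gene -> exact ANY_OVERLAP read count over each exon,
    # including background and artifact reads that happen to overlap it
    exon_total_counts: dict[str, dict[str, list[int]]]
    artifacts: dict[str, list[int]] = field(default_factory=dict)
    files: dict[str, dict[str, str]] = field(default_factory=dict)

    def annotation(self) -> AnnotationSet:
        return AnnotationSet(
            [GeneModel(g.gene_id, g.interval) for g in self.genes],
            {self.config.chrom: self.config.chrom_length},
        )

    def to_json(self) -> str:
        def enc(o):
            if isinstance(o, GenomicInterval):
                return {
                    "chrom": o.chrom,
                    "start": o.start,
                    "end": o.end,
                    "strand": o.strand,
                }
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(type(o))

        return json.dumps(dataclasses.asdict(self), default=enc, indent=1, sort_keys=True)


def _nb_counts(rng: np.random.Generator, mean: float, dispersion: float, size: int) -> np.ndarray:
    """Negative binomial in (mean, dispersion) parameterisation."""
    if dispersion == 0:
        return rng.poisson(mean, size)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size)


def _place_genes(cfg: SimulationConfig, rng: np.random.Generator) -> list[SimulatedGene]:
    genes: list[SimulatedGene] = []
    pos = int(rng.integers(1_000, 5_000))
    for i in range(cfg.n_genes):
        n_exons = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        cursor = pos
        for k in range(n_exons):
            if k > 0:
                cursor += int(rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1))
            ex_len = int(rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1))
            exons.append(GenomicInterval(cfg.chrom, cursor, cursor + ex_len, strand))
            cursor = cursor + ex_len
        interval = GenomicInterval(cfg.chrom, pos, cursor, strand)
        if cursor + 5_000 > cfg.chrom_length:
            raise ConfigurationError(
                f"chrom_length {cfg.chrom_length} too small for {cfg.n_genes} genes "
                f"(ran out of space at gene {i + 1})"
            )
        genes.append(SimulatedGene(f"gene{i + 1:03d}", interval, exons))
        # intergenic gaps wide enough that even a strongly expressed
        # terminal exon cannot drag an irreducible region across to the
        # next gene's first exon
        pos = cursor + int(rng.integers(20_000, 40_001))
    return genes


def simulate(cfg: SimulationConfig, outdir: str | Path) -> Manifest:
    """Generate the dataset and write every output format.

    Writes per sample a coordinate-sorted indexed BAM and a read TSV, plus
    ``genes.tsv``, ``genes.gff3`` and ``manifest.json`` in ``outdir``.
    Identical seeds give byte-identical outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    genes = _place_genes(cfg, rng)
    samples = [f"sample{j + 1:02d}" for j in range(cfg.n_samples)]
    rl = cfg.read_length

    exon_counts: dict[str, dict[str, list[int]]] = {}
    artifacts: dict[str, list[int]] = {}
    all_reads: dict[str, list[tuple[int, str]]] = {}  # sample -> (start, strand)

    for sample in samples:
        reads: list[tuple[int, str]] = []
        counts_for_sample: dict[str, list[int]] = {}
        for gene in genes:
            counts = _nb_counts(
                rng, cfg.expression_mean, cfg.dispersion, len(gene.exons)
            )
            counts_for_sample[gene.gene_id] = [int(c) for c in counts]
            for exon, count in zip(gene.exons, counts):
                starts = rng.integers(exon.start, exon.end - rl + 1, int(count))
                reads.extend((int(s), exon.strand) for s in starts)
        # uniform background noise on both strands
        n_bg = rng.poisson(cfg.background_rate * cfg.chrom_length / 1_000)
        bg_starts = rng.integers(0, cfg.chrom_length - rl + 1, n_bg)
        bg_strands = rng.random(n_bg) < 0.5
        reads.extend(
            (int(s), "+" if plus else "-") for s, plus in zip(bg_starts, bg_strands)
        )
        # artifact towers: duplicated reads stacked on one exonic position
        # (over-amplification duplicates fragments of the sequenced library,
        # so towers sit on transcribed sequence)
        art_positions: list[int] = []
        for gene in genes:
            if rng.random() < cfg.artifact_peak_rate:
                exon = gene.exons[int(rng.integers(len(gene.exons)))]
                p = int(rng.integers(exon.start, exon.end - rl + 1))
                reads.extend([(p, gene.interval.strand)] * cfg.artifact_stack)
                art_positions.append(p)
        reads.sort()
        all_reads[sample] = reads
        exon_counts[sample] = counts_for_sample
        artifacts[sample] = art_positions

    # exact ANY_OVERLAP totals per exon (expression + background + artifacts)
    exon_total_counts: dict[str, dict[str, list[int]]] = {}
    for sample in samples:
        starts = np.array([s for s, _ in all_reads[sample]], dtype=np.int64)
        strands = np.array([st for _, st in all_reads[sample]])
        totals: dict[str, list[int]] = {}
        for gene in genes:
            per_exon = []
            for exon in gene.exons:
                hit = (starts < exon.end) & (starts + rl > exon.start)
                if exon.strand != ".":
                    hit &= strands == exon.strand
                per_exon.append(int(np.count_nonzero(hit)))
            totals[gene.gene_id] = per_exon
        exon_total_counts[sample] = totals

    ann = AnnotationSet(
        [GeneModel(g.gene_id, g.interval) for g in genes],
        {cfg.chrom: cfg.chrom_length},
    )
    write_gene_tsv(ann, outdir / "genes.tsv")
    write_gff3(ann, outdir / "genes.gff3", {g.gene_id: g.exons for g in genes})

    files: dict[str, dict[str, str]] = {}
    whole = GenomicInterval(cfg.chrom, 0, cfg.chrom_length, ".")
    for sample in samples:
        bam_path = outdir / f"{sample}.bam"
        _write_bam(cfg, all_reads[sample], bam_path)
        tsv_path = outdir / f"{sample}.reads.tsv"
        readset = ReadSet(
            whole,
            (
                AlignedRead(
                    GenomicInterval(cfg.chrom, s, s + rl, strand), sample
                )
                for s, strand in all_reads[sample]
            ),
            sample,
        )
        write_read_tsv(readset, tsv_path)
        files[sample] = {"bam": str(bam_path), "read_tsv": str(tsv_path)}

    manifest = Manifest(
        cfg, genes, samples, exon_counts, exon_total_counts, artifacts, files
    )
    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest


def _write_bam(cfg: SimulationConfig, reads: list[tuple[int, str]], path: Path) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": cfg.chrom, "LN": cfg.chrom_length}],
    }
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for i, (start, strand) in enumerate(reads):
            a = pysam.AlignedSegment()
            a.query_name = f"r{i:08d}"
            a.flag = 16 if strand == "-" else 0
            a.reference_id = 0
            a.reference_start = start
            a.mapping_quality = 60
            a.cigartuples = ((0, cfg.read_length),)
            bam.write(a)
    pysam.index(str(path))
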