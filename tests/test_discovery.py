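"""Region categories, chunked iteration, count tables and the discovery
pipeline on simulated data."""

import numpy as np
import pytest

from covmine import (
    AnnotationSet,
    Category,
    ChromosomeLookupError,
    ConfigurationError,
    GeneModel,
    GenomicInterval,
    MiningParams,
    StrandMode,
    build_count_table,
    chunk_iterator,
    discover,
    extended_gene_regions,
    gene_regions,
    intergenic_regions,
    mine_region_chunked,
    read_read_tsv,
    support_summary,
    write_read_tsv,
)
from covmine.coverage import CountingRule


def _ann(genes, length=1000, chrom="chr1"):
    return AnnotationSet(
        [GeneModel(f"g{i}", GenomicInterval(chrom, s, e, st)) for i, (s, e, st) in enumerate(genes)],
        {chrom: length},
    )


class TestGeneRegions:
    def test_empty_annotation(self):
        assert gene_regions(_ann([]), "chr1", "+") == []

    def test_strand_filter_and_sort(self):
        ann = _ann([(500, 600, "+"), (100, 200, "+"), (300, 400, "-"),
                    (700, 800, "+"), (10, 20, "-")])
        plus = gene_regions(ann, "chr1", "+")
        assert [(iv.start, iv.end) for iv in plus] == [(100, 200), (500, 600), (700, 800)]
        assert len(gene_regions(ann, "chr1", "-")) == 2

    def test_unknown_chromosome(self):
        with pytest.raises(ChromosomeLookupError):
            gene_regions(_ann([]), "chrX", "+")

    def test_simulated_annotation_matches_manifest(self, sim, sim_annotation):
        truth = sorted(
            (g.interval.start, g.interval.end) for g in sim.genes
        )
        got = sorted(
            (iv.start, iv.end)
            for iv in gene_regions(sim_annotation, sim.config.chrom)
        )
        assert got == truth


class TestExtendedGeneRegions:
    def test_zero_flank_is_identity(self):
        ann = _ann([(100, 200, "+"), (500, 600, "-")])
        assert extended_gene_regions(ann, 0) == [g.interval for g in ann.genes]

    def test_flank_clamped_to_chromosome(self):
        ann = _ann([(100, 200, "+")], length=10_000)
        (ext,) = extended_gene_regions(ann, 1000)
        assert (ext.start, ext.end) == (0, 1200)

    def test_every_extension_contains_its_gene_and_stays_in_bounds(self):
        rng = np.random.default_rng(12)
        genes = []
        pos = 0
        for _ in range(20):
            pos += int(rng.integers(10, 300))
            end = pos + int(rng.integers(1, 400))
            genes.append((pos, end, "+"))
            pos = end
        ann = _ann(genes, length=pos + 500)
        for g, ext in zip(ann.genes, extended_gene_regions(ann, 250)):
            assert ext.contains(g.interval)
            assert 0 <= ext.start and ext.end <= pos + 500


class TestIntergenicRegions:
    def test_no_genes_gives_whole_chromosome(self):
        (iv,) = intergenic_regions(_ann([]), "chr1", "+")
        assert (iv.start, iv.end) == (0, 1000)

    def test_complement_of_two_genes(self):
        ann = _ann([(100, 200, "+"), (500, 600, "+")])
        gaps = intergenic_regions(ann, "chr1", "+")
        assert [(g.start, g.end) for g in gaps] == [(0, 100), (200, 500), (600, 1000)]

    def test_overlapping_genes_merged_before_complement(self):
        ann = _ann([(100, 300, "+"), (250, 400, "+")])
        gaps = intergenic_regions(ann, "chr1", "+")
        assert [(g.start, g.end) for g in gaps] == [(0, 100), (400, 1000)]

    def test_partition_with_gene_union(self):
        """genic union + intergenic complement tile [0, L) exactly once."""
        rng = np.random.default_rng(3)
        genes = []
        pos = 0
        for _ in range(15):
            pos += int(rng.integers(1, 100))
            end = pos + int(rng.integers(1, 150))
            genes.append((pos, min(end, 2000), "+"))
            pos = end
            if pos >= 1990:
                break
        ann = _ann(genes, length=2000)
        membership = np.zeros(2000, dtype=int)
        for s, e, _ in genes:
            membership[s:e] = 1
        covered = np.zeros(2000, dtype=int)
        for gap in intergenic_regions(ann, "chr1", "+"):
            covered[gap.start : gap.end] += 1
        # intergenic covers exactly the non-genic positions, once
        assert np.array_equal(covered, 1 - membership)


class TestChunkIterator:
    def test_short_interval_is_single_chunk(self):
        iv = GenomicInterval("chr1", 10, 60, "+")
        assert list(chunk_iterator(iv, 100, 10)) == [iv]

    def test_worked_chunking(self):
        iv = GenomicInterval("chr1", 0, 250, "+")
        chunks = [(c.start, c.end) for c in chunk_iterator(iv, 100, 10)]
        assert chunks == [(0, 100), (90, 190), (180, 250)]

    def test_consecutive_chunks_share_exact_overlap(self):
        iv = GenomicInterval("chr1", 0, 5000, "+")
        chunks = list(chunk_iterator(iv, 512, 32))
        for a, b in zip(chunks, chunks[1:]):
            assert a.end - b.start == 32
        assert chunks[0].start == 0 and chunks[-1].end == 5000

    def test_invalid_sizes_rejected(self):
        iv = GenomicInterval("chr1", 0, 100, "+")
        with pytest.raises(ConfigurationError):
            list(chunk_iterator(iv, 20, 10))


class TestCountTable:
    def test_all_zero_table(self, tmp_path):
        region = GenomicInterval("chr1", 0, 100, "+")
        tsv = tmp_path / "empty.tsv"
        write_read_tsv(_empty_readset(region), tsv)
        source = lambda iv: read_read_tsv(tsv, iv)
        table = build_count_table({"s1": source}, [("g", region)])
        assert table.counts.tolist() == [[0]]

    def test_counts_match_simulator_manifest(self, sim, sim_bam_sources):
        gene = sim.genes[0]
        regions = [
            (f"{gene.gene_id}.ex{k}", exon) for k, exon in enumerate(gene.exons)
        ]
        table = build_count_table(sim_bam_sources, regions)
        for j, sample in enumerate(table.samples):
            truth = sim.exon_total_counts[sample][gene.gene_id]
            assert table.counts[:, j].tolist() == truth

    def test_needs_samples_and_regions(self):
        with pytest.raises(ConfigurationError):
            build_count_table({}, [])


def _empty_readset(region):
    from covmine import ReadSet

    return ReadSet(region, (), "s1")


class TestDiscover:
    def test_fully_expressed_genes_all_reach_full_support(
        self, sim, sim_annotation, sim_bam_sources
    ):
        res = discover(
            sim_bam_sources,
            sim_annotation,
            MiningParams(mu=5, minsup=51),
            categories=[Category.GENIC],
            min_samples=len(sim.samples),
        )
        n = len(sim.samples)
        # every simulated gene is strongly expressed in every sample
        assert res.support.loc[(5, 51), n] == len(sim.genes)
        assert all(v == n for v in res.per_gene_support.values())
        assert all(d.category is Category.GENIC for d in res.regions)
        # counts cover all genes
        assert set(res.counts.labels) >= {g.gene_id for g in sim.genes}

    def test_single_expressed_sample_fails_min_samples_two(self, tmp_path):
        from covmine import AlignedRead, ReadSet

        region = GenomicInterval("chr1", 0, 2000, "+")
        gene = GenomicInterval("chr1", 500, 1000, "+")
        reads = [
            AlignedRead(GenomicInterval("chr1", s, s + 50, "+"))
            for s in range(500, 950, 2)
        ]
        expressed = tmp_path / "expressed.tsv"
        silent = tmp_path / "silent.tsv"
        write_read_tsv(ReadSet(region, reads, "s1"), expressed)
        write_read_tsv(ReadSet(region, (), "s2"), silent)
        ann = AnnotationSet([GeneModel("g", gene)], {"chr1": 2000})
        sources = {
            "s1": lambda iv: read_read_tsv(expressed, iv, sample_id="s1"),
            "s2": lambda iv: read_read_tsv(silent, iv, sample_id="s2"),
        }
        res = discover(sources, ann, MiningParams(5, 10), min_samples=2)
        assert res.regions == []
        res1 = discover(sources, ann, MiningParams(5, 10), min_samples=1)
        assert len(res1.regions) == 1

    def test_planted_intergenic_transcript_is_recovered(
        self, sim, sim_bam_sources
    ):
        # hide one simulated gene from the annotation: its expression must
        # resurface through the INTERGENIC scan at the planted locus
        hidden = sim.genes[3]
        ann = AnnotationSet(
            [
                GeneModel(g.gene_id, g.interval)
                for g in sim.genes
                if g.gene_id != hidden.gene_id
            ],
            {sim.config.chrom: sim.config.chrom_length},
        )
        res = discover(
            sim_bam_sources,
            ann,
            MiningParams(mu=5, minsup=51),
            categories=[Category.INTERGENIC],
            min_samples=len(sim.samples),
        )
        novel = [d for d in res.regions if d.category is Category.INTERGENIC]
        rl = sim.config.read_length
        assert novel
        for exon in hidden.exons:
            assert any(d.interval.overlaps(exon) for d in novel), (
                f"exon {exon} not recovered"
            )
        # everything reported lies inside the hidden gene body (regions may
        # bridge introns when the running mean stays above mu), and the
        # outermost boundaries land within a read length of the true ones
        for d in novel:
            assert hidden.interval.start <= d.interval.start
            assert d.interval.end <= hidden.interval.end
        assert min(d.interval.start for d in novel) - hidden.interval.start <= rl
        assert hidden.interval.end - max(d.interval.end for d in novel) <= rl

    def test_chunked_and_unchunked_mining_agree(self, sim, sim_bam_sources):
        source = sim_bam_sources[sim.samples[0]]
        whole = GenomicInterval(sim.config.chrom, 0, sim.config.chrom_length, "+")
        params = MiningParams(mu=5, minsup=51)
        unchunked = mine_region_chunked(
            source, whole, params, chunk_size=sim.config.chrom_length + 1,
            chunk_overlap=0,
        )
        # overlap chosen above the longest mined region so each region is
        # seen whole by at least one chunk
        chunked = mine_region_chunked(
            source, whole, params, chunk_size=50_000, chunk_overlap=20_000,
        )
        key = lambda rs: [(r.interval.start, r.interval.end) for r in rs]
        assert key(chunked) == key(unchunked)

    def test_no_samples_is_configuration_error(self, sim_annotation):
        with pytest.raises(ConfigurationError):
            discover({}, sim_annotation, MiningParams(5, 51))


class TestSupportSummary:
    def test_monotone_in_every_direction(self, sim, sim_annotation, sim_bam_sources):
        mus = [5.0, 10.0, 20.0]
        minsups = [1, 51, 150]
        table = support_summary(sim_bam_sources, sim_annotation, mus, minsups)
        # columns: non-increasing in X
        arr = table.to_numpy()
        assert (np.diff(arr, axis=1) <= 0).all()
        # non-increasing in mu at fixed minsup, and in minsup at fixed mu
        for ms in minsups:
            sub = table.loc[[(m, ms) for m in mus]].to_numpy()
            assert (np.diff(sub, axis=0) <= 0).all()
        for m in mus:
            sub = table.loc[[(m, ms) for ms in minsups]].to_numpy()
            assert (np.diff(sub, axis=0) <= 0).all()
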