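"""Gene annotations: in-memory model and GTF/GFF3/TSV readers.

Only gene-level boundaries are used — discovery scans whole gene bodies,
their flanks and the intergenic complement; exon structure is something the
miner infers from coverage, not something it trusts from the annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gffutils

from .errors import ChromosomeLookupError, DomainError
from .intervals import GenomicInterval


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    interval: GenomicInterval


@dataclass
class AnnotationSet:
    """A set of genes plus chromosome lengths.

    Gene ids are unique; every gene lies within its chromosome.
    """

    genes: list[GeneModel] = field(default_factory=list)
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise DomainError(f"duplicate gene_id: {g.gene_id}")
            seen.add(g.gene_id)
            length = self.chrom_lengths.get(g.interval.chrom)
            if length is None:
                raise DomainError(
                    f"gene {g.gene_id} on unknown chromosome {g.interval.chrom}"
                )
            if g.interval.end > length:
                raise DomainError(
                    f"gene {g.gene_id} extends past chromosome end "
                    f"({g.interval.end} > {length})"
                )

    def require_chrom(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[chrom]
        except KeyError:
            raise ChromosomeLookupError(
                f"unknown chromosome {chrom!r}; known: {sorted(self.chrom_lengths)}"
            ) from None

    def genes_on(self, chrom: str, strand: str = ".") -> list[GeneModel]:
        """Genes on (chrom, strand), sorted by start.  Strand "." matches all."""
        self.require_chrom(chrom)
        return sorted(
            (
                g
                for g in self.genes
                if g.interval.chrom == chrom and g.interval.strand_matches(strand)
            ),
            key=lambda g: (g.interval.start, g.interval.end),
        )

    def get(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


def read_gene_tsv(
    path: str | Path, chrom_lengths: Mapping[str, int] | None = None
) -> AnnotationSet:
    """Read the simple gene table: gene_id, chrom, start (1-based inclusive),
    end (inclusive), strand.  Lines starting with '#' are comments.

    If ``chrom_lengths`` is not given, each chromosome's length is inferred
    as the largest gene end seen on it (sufficient for gene/extended scans;
    pass real lengths for intergenic discovery).
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise DomainError(
                    f"{path}:{lineno}: expected 5 tab-separated fields, "
                    f"got {len(fields)}"
                )
            gene_id, chrom, start1, end1, strand = fields
            try:
                start = int(start1) - 1
                end = int(end1)
            except ValueError:
                raise DomainError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from None
            genes.append(GeneModel(gene_id, GenomicInterval(chrom, start, end, strand)))
    if chrom_lengths is None:
        chrom_lengths = {}
        for g in genes:
            c = g.interval.chrom
            chrom_lengths[c] = max(chrom_lengths.get(c, 0), g.interval.end)
    return AnnotationSet(genes, dict(chrom_lengths))


def write_gene_tsv(ann: AnnotationSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# gene_id\tchrom\tstart_1based\tend\tstrand\n")
        for g in sorted(ann.genes, key=lambda g: (g.interval.chrom, g.interval.start)):
            iv = g.interval
            fh.write(
                f"{g.gene_id}\t{iv.chrom}\t{iv.start + 1}\t{iv.end}\t{iv.strand}\n"
            )


def read_annotation(
    path: str | Path, chrom_lengths: Mapping[str, int] | None = None
) -> AnnotationSet:
    """Read gene annotations from GTF, GFF3 or the simple gene TSV.

    Format is chosen by extension (.gtf / .gff / .gff3, anything else is
    treated as gene TSV).  GTF/GFF coordinates (1-based inclusive) are
    converted to the internal 0-based half-open convention here and nowhere
    else.  For GFF3, ``##sequence-region`` pragmas supply chromosome
    lengths when ``chrom_lengths`` is not given.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix not in {".gtf", ".gff", ".gff3"}:
        return read_gene_tsv(path, chrom_lengths)

    lengths: dict[str, int] = dict(chrom_lengths or {})
    if not lengths:
        with open(path) as fh:
            for line in fh:
                if line.startswith("##sequence-region"):
                    _, chrom, _start, end = line.split()[:4]
                    lengths[chrom] = int(end)
                elif not line.startswith("#"):
                    break

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("gene_id", [feat.id])[0]
        iv = GenomicInterval(
            feat.seqid,
            feat.start - 1,  # GFF/GTF 1-based inclusive -> 0-based half-open
            feat.end,
            feat.strand if feat.strand in "+-" else ".",
        )
        genes.append(GeneModel(gene_id, iv))
        lengths.setdefault(feat.seqid, 0)
        lengths[feat.seqid] = max(lengths[feat.seqid], iv.end)
    return AnnotationSet(genes, lengths)


def write_gff3(
    ann: AnnotationSet,
    path: str | Path,
    exons: Mapping[str, Iterable[GenomicInterval]] | None = None,
) -> None:
    """Write genes (and optionally their exons) as GFF3 with
    ``##sequence-region`` pragmas carrying chromosome lengths."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in sorted(ann.chrom_lengths):
            fh.write(f"##sequence-region {chrom} 1 {ann.chrom_lengths[chrom]}\n")
        for g in sorted(ann.genes, key=lambda g: (g.interval.chrom, g.interval.start)):
            iv = g.interval
            fh.write(
                f"{iv.chrom}\tcovmine\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID={g.gene_id}\n"
            )
            for k, ex in enumerate(exons.get(g.gene_id, ()) if exons else ()):
                fh.write(
                    f"{ex.chrom}\tcovmine\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{ex.strand}\t.\tID={g.gene_id}.exon{k + 1};Parent={g.gene_id}\n"
                )
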