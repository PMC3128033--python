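# covmine

Exploratory analysis of RNA-seq expression at nucleotide resolution:
per-base coverage from minimally-attributed aligned reads, mining of
**irreducible regions** of expression, a nucleotide-level **splicing
index**, annotation-free **discovery** of transcribed regions, and count
tables ready for downstream differential-expression tools.

## Who this is for

Annotation-driven RNA-seq analysis counts reads in predefined genes and
hands the counts to a statistical test. That works until the transcript
does not follow the annotation: expression running past a gene boundary, a
novel transcript in an intergenic gap, an exon included in one condition
and skipped in another. `covmine` approaches the data from the other side —
it treats the per-nucleotide coverage function as the primary object,
determines expressed-region boundaries from the data itself, and only then
produces region×sample count tables for tools such as DESeq2 or edgeR.
Reads are reduced to (chromosome, start, end, strand), so any mapper and
any platform can feed it; reads come from indexed BAM/SAM or from a plain
read table, and long regions are processed in bounded-memory chunks.

## The core algorithm

Let `v₁…vₙ` be the coverage of a genomic window and `μ` a detection
threshold (a common choice is 5). An interval is **irreducible at μ** when
every split into two parts leaves both parts with mean coverage ≥ μ
(a single position is irreducible iff its value ≥ μ). Equivalently: every
prefix mean and every suffix mean is ≥ μ. Irreducible regions

* tolerate short interior dips below μ (an exon whose coverage sags over a
  GC-poor stretch stays one region),
* provably start and end with a value ≥ μ, so boundaries sit only where
  expression is genuinely high, and
* merge whenever they overlap or touch, so the *maximal* irreducible
  regions are pairwise disjoint.

`covmine` mines the maximal irreducible regions with an `O(n log n)`
prefix-sum algorithm (with `S = cumsum(v − μ)`, an interval `[a,b)` is
irreducible iff `S[a] = min S[a..b]` and `S[b] = max S[a..b]`), and ships a
brute-force enumeration oracle against which the fast implementation is
verified element-wise on thousands of randomized inputs. A minimum region
width `minsup` (default: read length + 1) is applied after maximality and
suppresses single stacks of duplicated reads.

Around the miner sit the standard transforms — reads-per-million
normalisation, lowess smoothing (span `f = 0.1`) for artifact damping,
per-nucleotide log2 fold change — and the nucleotide-level splicing index
between two conditions

```
SI_n = log2( ((E1_n + p) / G1) / ((E2_n + p) / G2) )
```

where `E1_n`, `E2_n` are coverages at nucleotide *n*, `G1`, `G2` the read
counts of the enclosing gene and `p` a pseudocount: gene-level
normalisation cancels overall expression differences, so |SI| ≥ 1 marks a
two-fold or larger *relative inclusion* change. Mining |SI| localises the
differential exons.

## A worked example

`examples/01_pileup_and_mine.py` builds a 1200-nt window containing a
strong exon-like block, a weak block hovering at the threshold, and a
30-read PCR duplicate tower, then piles up and mines it:

```
coverage: length 1200, max 30, total read-nucleotides 5000

mu=5, minsup=1:
  chr1:103-290(+)  mean coverage 15.9
  chr1:784-835(+)  mean coverage 8.2
  chr1:1000-1050(+)  mean coverage 30.0

mu=5, minsup=51:
  chr1:103-290(+)  mean coverage 15.9
  chr1:784-835(+)  mean coverage 8.2
```

The two expressed blocks are recovered with boundaries where coverage
first reaches μ = 5; the duplicate tower — 50 nt of coverage 30 — is the
highest signal in the window yet disappears once `minsup` exceeds the read
length, because an isolated stack can never be wider than one read.

`examples/04_discovery_pipeline.py` runs the full pipeline on simulated
data with one gene hidden from the annotation:

```
simulated 6 genes; annotation hides gene003 (chrSim:155921-182788(-))

support summary (genes with regions in >= X of N samples):
           1  2  3
mu minsup
5  51      5  5  5

3 novel intergenic loci (the hidden gene has 3 exons):
  chrSim:155925-156410(-)  supported by 3 samples
  chrSim:171306-171772(-)  supported by 3 samples
  chrSim:182372-182777(-)  supported by 3 samples
```

Every annotated gene contains irreducible regions in all 3 samples, and
the hidden gene's three exons resurface as novel intergenic loci within a
few nucleotides of their true boundaries — the count table then carries
both the genes and the novel loci.

The other examples cover smoothing + region-based coverage (`02`), the
splicing index (`03`) and count-table export (`05`). Each is a short
self-contained script: `python examples/03_splicing_index.py`.

## Command line

A thin CLI wraps the library for shell use:

```bash
covmine simulate --seed 1 --outdir sim/
covmine mine --backend s1=sim/sample01.bam --region chrSim:0-4000000:+ \
        --mu 5 --out regions.bed
covmine discover --backend s1=sim/sample01.bam --backend s2=sim/sample02.bam \
        --annotation sim/genes.gff3 --categories genic,intergenic \
        --outdir out/
```

Subcommands: `coverage`, `mine`, `splice-index`, `counts`, `discover`,
`simulate`, `plot`. Every run logs the exact parameters (μ, minsup,
strandedness, pseudocount, f) and input checksums; `discover` also accepts
a flat key=value config file (`--config run.cfg`) that round-trips
byte-identically.

## Layout

| module | contents |
|---|---|
| `covmine.intervals` / `covmine.coverage` | half-open strand-aware intervals, read sets, pileup, region counts |
| `covmine.mining` | irreducible-region miner, brute-force oracle, region-based coverage, support filter |
| `covmine.transforms` | normalisation, lowess, fold change, splicing index |
| `covmine.annotation` / `covmine.discovery` | GTF/GFF3/TSV annotations, genic/extended/intergenic scans, chunking, count tables |
| `covmine.backends` / `covmine.writers` | BAM/SAM and read-TSV back-ends; bedGraph/BED6/TSV writers |
| `covmine.simulate` | seeded read simulator with ground-truth manifest |
| `covmine.cli` / `covmine.plotting` / `covmine.config` | CLI, static region plots, run configs |

See `docs/methods.md` for the model, parameter defaults and limitations.
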