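# Methods

## The coverage model

All analyses operate on the *coverage function*: for a genomic window and
one sample, the number of reads overlapping each nucleotide. Reads enter
the system reduced to (chromosome, start, end, strand) — no sequence,
qualities or CIGAR — which makes the toolbox independent of sequencing
platform and mapper configuration; mapper stringency (mismatches,
multi-mapping) is decided upstream. Spliced alignments are treated as a
single `[start, end)` block: there is no junction modelling anywhere in
the package, and exon/intron structure is inferred from coverage alone.
Coordinates are 0-based half-open internally on every type; the 1-based
inclusive conventions of SAM, GTF/GFF3 and the read-TSV dump are converted
exactly once, at the I/O boundary. Reads crossing a window boundary
contribute their overlapping part to the pileup (clipping, never
exclusion), which is what makes chunked whole-chromosome scans exact.

Strand handling: `SAME_STRAND` pileup counts reads on the region's strand
plus unstranded ("." ) reads — the protocol-agnostic default for reads
whose protocol lost strand information; `IGNORE_STRAND` counts everything.
Region read-counting (`region_count`) defaults to *any overlap* (one
shared nucleotide suffices), matching the denominator convention where
every mapped read in a locus contributes; fully-contained counting is
available as an option.

## Irreducible-region mining

**Definition.** For coverage values `v₁…vₙ` and threshold μ ≥ 0, an
interval is *irreducible* when every split into two parts leaves both
parts with mean ≥ μ; a single position is irreducible iff its value ≥ μ.
Equivalent formulation (the one computed): every prefix mean and every
suffix mean is ≥ μ. Two consequences used throughout: an irreducible
interval starts and ends with a value ≥ μ, and two irreducible intervals
that overlap or touch merge into a larger irreducible interval — hence
maximal irreducible intervals are pairwise disjoint, and the minimum-width
filter (`minsup`) can be applied *after* maximality without ambiguity.

**Comparisons are non-strict (≥) by default.** Coverage is integer-valued
and equality with an integer μ is common; the single-position base case
(value ≥ μ) forces the non-strict convention for consistency. A `strict`
flag switches every comparison to `>` for parity experiments; both the
fast miner and the oracle honour it.

**Algorithm.** With `w = v − μ` and prefix sums `S` (`S[0] = 0`), interval
`[a, b)` is irreducible iff `S[a] = min S[a..b]` and `S[b] = max S[a..b]`.
For each start `a` the longest irreducible interval ends at the rightmost
argmax of `S` strictly between `a` and the first position where `S` drops
below `S[a]` ("next smaller", leftmost-tie/strict variants in strict
mode). By the merge property, the maximal intervals are exactly the
connected runs of the union of these per-start longest intervals. The
implementation computes next-smaller positions with a monotone stack and
range argmaxes with a sparse table — `O(n log n)` time, `O(n log n)`
memory — and is specified by contract: its output must equal the
exhaustive `O(n³)`-style enumeration oracle (`brute_force_regions`,
guarded to n ≤ 10 000). The equivalence is asserted element-wise on
thousands of randomized Poisson/negative-binomial/gamma vectors across a
(μ, minsup, strict) grid in the test suite and re-measured by the
acceptance script.

**Numerical note.** Both routes compute the same float64 prefix-sum array,
so their comparisons agree bit-for-bit; on integer coverage with rational
μ all quantities are exact. Mining accepts any non-negative real signal
(smoothed tracks are fractional); negative inputs are a domain error —
signed signals such as the splicing index are mined via |SI|.

**Defaults.** μ = 5, the conventional "detection threshold" for expressed
coverage; `minsup` = read length + 1, the smallest width that an isolated
stack of duplicated reads (a PCR/over-amplification tower, exactly one
read wide) cannot reach. Adaptive thresholds are available as μ-resolvers
— fixed value, fraction of the slice maximum, fraction of the slice
minimum — evaluated on the current track slice; fixed is the default.

**Region-based coverage** mines at an ascending ladder of μ values and
assigns each position the highest μ at which it lies inside a region of
width ≥ minsup (0 where none). Output values are always drawn from the
ladder ∪ {0}, and removing ladder levels can only lower values pointwise.

## Transforms

* **Library-size normalisation**: values × 10⁶ / total mapped reads
  (reads-per-million). Between-sample quantile/TMM normalisation is out of
  scope — count-based DE tools apply their own.
* **Lowess smoothing** (span `f`, default 0.1; 3 robustness iterations;
  positions as x): recommended before mining to stabilise boundaries —
  it flattens duplicate towers and fills small non-expressed gaps.
  Fitting is delegated to statsmodels' lowess with one guard: when the
  median absolute residual of the unweighted fit is (near) zero, the
  robustness weights degenerate and every local fit collapses onto the
  raw data, so the unweighted fit is kept — the same early exit R's
  `lowess` takes; the test suite cross-checks the output against R's
  implementation to < 10⁻⁶. Negative fitted values are clipped to 0 so a
  smoothed track remains a valid mining input. Regions shorter than 10 nt
  are rejected (too few points for a local fit). Smoothing trades a little
  boundary precision for stability.
* **Fold change**: per position `log2((v₁ + p)/(v₂ + p))`, pseudocount
  p = 1 by default.
* **Splicing index**: per position
  `SI_n = log2(((E1_n + p)/G1) / ((E2_n + p)/G2))` with `G1`, `G2` the
  gene/region read counts of the two conditions and p = 1 by default. The
  formula follows the exon-array splicing-index convention — gene-level
  normalisation isolates relative-inclusion changes from expression-level
  changes — with an additive pseudocount so zero-coverage positions stay
  finite; this concrete functional form, including the pseudocount, is a
  design choice of this package. `G1`/`G2` are per-region scalars: one
  count for the enclosing gene, not a per-nucleotide quantity. A zero gene
  count is a domain error (an unexpressed gene has no meaningful relative
  inclusion; filter such genes first). Significant SI regions are mined on
  |SI| with threshold `mu_si` (default 1.0 ≙ two-fold relative change);
  each region is reported with the sign of its mean SI.

## Discovery

Each chromosome is dissected per strand into three scan categories:
**genic** (annotated gene bodies), **extended** (gene bodies widened by a
fixed flank, default 1000 nt, clamped to the chromosome — expression
running past annotated boundaries), and **intergenic** (the complement of
the merged gene union — novel transcription). Overlapping genes are merged
per strand before taking the complement, and a discovered locus
overlapping any annotated gene is labelled genic regardless of which scan
found it, so category assignment is unambiguous. A fixed flank was chosen
over adaptively growing boundaries until coverage falls below μ; adaptive
extension would be a natural variant.

Long regions are scanned in overlapping chunks (default 2 Mb with 10 kb
overlap) so memory stays bounded: chunks are mined without the width
filter, fragments contained in a longer region found by a neighbouring
chunk are dropped, and `minsup` is applied to the surviving canonical
regions. The chunked result equals an unchunked run whenever every true
region is shorter than the chunk overlap — the reason the default overlap
(10 kb) far exceeds plausible exon/region lengths.

Per locus, the **support filter** counts the samples contributing at least
one mined region (a gene counts once per sample however many regions it
contains) and keeps loci reaching `min_samples`. The **support summary**
tabulates, for a grid of (μ, minsup), how many genes contain irreducible
regions in ≥ X of N samples; the counts are monotone non-increasing in X,
in μ and in minsup, which the tests assert on simulated data. The exported
**count table** (regions × samples, any-overlap counts by default) covers
every annotated gene plus every surviving novel locus and is written as a
TSV directly loadable by count-based DE tools; significance testing itself
is deliberately downstream.

## The simulator

The generator emulates the statistical structure the analyses assume, on
one synthetic chromosome (default 4 Mb):

* **Genes**: 50 genes by default, non-overlapping by construction (overlap
  handling is tested separately with hand-built annotations), random
  strand, 2–5 exons of 200–500 nt separated by introns of 8–15 kb,
  intergenic gaps of 20–40 kb.
* **Expression**: per exon and sample, a negative-binomial read count with
  mean 300 and dispersion 0.2 (variance = mean + 0.2·mean², the
  over-dispersion regime of RNA-seq counts); 50-bp reads placed uniformly
  inside the exon, on the gene's strand. No junction reads — introns
  receive zero signal reads, consistent with the package's no-junction
  scope.
* **Background**: uniform noise reads on both strands at 2 reads/kb
  (≈ 0.1× coverage).
* **Artifacts**: with probability 0.1 per gene and sample, one exonic
  position receives a tower of 30 duplicated reads (over-amplification
  duplicates fragments of the sequenced library, hence towers sit on
  transcribed sequence).

The defaults realise the regime the recovery guarantee is stated for:
exon plateau coverage ≈ 300·50/350 ≈ 43× (≥ 4μ at μ = 5) against ≈ 0.1×
background (≤ μ/4), with margin for the linear coverage ramp a read length
wide at exon edges. The geometry is deliberately conservative in two
places: introns and intergenic gaps are long enough that the miner's dip
tolerance cannot carry a region across them even for strongly expressed
flanking exons (bridging requires flanking read mass ≥ μ × gap length),
which keeps exon-level planted truth well-defined. On real data, closely
spaced exons *will* merge across short introns — that is the documented
dip-tolerance behaviour, not an error.

Outputs are written through every back-end format — coordinate-sorted
indexed BAM and read TSV per sample, GFF3 (with `##sequence-region`
pragmas) and gene TSV annotations — plus a JSON manifest recording the
planted truth: exon intervals, per-sample per-exon expression counts,
exact any-overlap totals per exon (including background/artifact reads),
and artifact positions. A fixed seed gives byte-identical outputs.

**What passing tests on this generator do and do not show.** They show the
mining contract, the support logic, back-end equivalence and recovery
behave exactly as specified under NB expression with uniform read
placement. They do not probe positional coverage bias (GC, fragmentation,
3′ bias), junction-spanning reads, overlapping or nested genes, or
mapping ambiguity; boundary-recovery accuracy on real data will be
dominated by such effects rather than by the miner.

**Recovery guarantees, precisely.** At the default conditions, per-sample
mining at (μ = 5, minsup = 51) over the whole chromosome recovers planted
exon bases at ≥ 95% sensitivity and precision. Boundary error ≤ read
length is guaranteed for exons whose *realised* coverage (NB draw × read
length / exon length) meets the ≥ 4μ condition — an exon whose draw left
it near μ has no well-defined recoverable boundary, and the miner reports
whatever fragment stays above threshold.

## Numerical and degenerate-input choices

* Empty vectors, empty read sets over a region, and queries on
  chromosomes absent from a BAM return empty-but-valid results; unknown
  chromosomes in *annotations* are lookup errors (a typo should not
  silently scan nothing).
* COUNTS tracks enforce non-negative integers; transforms tag their
  outputs (`NORMALIZED`, `SMOOTHED`, `FOLD_CHANGE`, `SPLICING_INDEX`,
  `REGION_BASED`) so pipelines can assert what they are consuming.
* BED scores clip mined means to the 0–1000 BED range; bedGraph output
  merges equal-value runs and suppresses zero runs by default.
* The brute-force oracle refuses vectors above 10 000 positions: it
  exists to check the miner, not to replace it.
* `chunk_size > 2 × overlap` is enforced; chunk boundaries never lose
  reads because pileup clips rather than drops boundary-crossing reads.

## Known limitations

* No junction reads and no isoform assembly: a skipped exon is visible in
  the splicing index, but the connecting structure is not modelled.
* Mining is per-sample; cross-sample evidence enters only through the
  support filter, not through joint segmentation.
* No significance attached to mined regions — region lists and count
  tables are inputs to count-based DE tools, which own the statistics.
* The lowess pass is `O(n · f · n)` per window and is intended for
  gene-scale windows, not whole chromosomes at once.
* Support-summary monotonicity in minsup holds at fixed μ on the same
  track; it is not guaranteed across different smoothing settings.
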