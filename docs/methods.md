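# Methods

## Scope and model

circseek models the computational arm of a circRNA tumour-marker study:
junction-level discovery of circRNAs from rRNA-depleted strand-specific
RNA-seq, abundance quantification by junction read counting, host-gene
annotation, paired tumour/normal differential expression, miRNA seed-site
scanning on the circular transcript, and the clinical statistics applied
to the resulting expression marker. Wet-lab assays, a full spliced aligner
and Cox regression are out of scope; the linear mapper is a deliberate
annotation-guided stand-in whose only job is to partition reads so that
back-splice-crossing reads end up in the unmapped pool.

Coordinates are 0-based half-open everywhere in memory. GTF output is
1-based inclusive; BED output 0-based half-open; human-readable locus
strings ("chr1:5097–5852") are 1-based inclusive.

## Back-splice detection

Unmapped reads of length L contribute two terminal anchors of 20 nt
(configurable; reads shorter than 2 × anchor length are skipped). Anchors
must match the genome exactly and uniquely across both strands; reads with
ambiguous anchors are discarded so that repeats cannot fabricate
junctions. With unique hits in head-to-tail orientation, every breakpoint
b ∈ [20, L − 20] is scored: read[:b] must extend the prefix anchor
colinearly so that its last base abuts the donor, read[b:] must extend the
suffix anchor starting at the acceptor, with at most `max_mismatch` (2)
substitutions in total, and the implied interval [start, end) must carry
the splice signature. The accepted b minimizes mismatches among
signature-passing breakpoints; ties break to the smallest b, making output
deterministic.

Strand is inferred from the flank signature itself: on the plus-strand
genome, AG…GT brackets a + circle and AC…CT (the reverse-complemented
signals) a − circle. This makes detection symmetric in read orientation —
a sense read of a − strand circle and the antisense mate of a + strand
circle both collapse onto the correct junction record — without consulting
library strandedness. In the degenerate case where both signatures match,
+ wins deterministically. Non-canonical (non-GT/AG) junctions are a
non-goal.

Evidence aggregation groups junctions by (chrom, start, end, strand). A
fragment votes at most once, and support is the number of distinct
supporting read *sequences* (exact PCR duplicates collapse); counting
distinct breakpoint offsets instead is available via
`unique_by="breakpoint"`. The default support threshold is 2 unique
back-spliced reads. Raising the threshold can only remove candidates
(monotonicity, property-tested).

## Linear mapper

Seed-and-verify with exact 20-mer seeds at both read ends, verified
against the genome and against spliced transcript sequences (which is how
reads crossing annotated exon–exon junctions map, flagged `spliced`).
Ties for the best location are routed to the unmapped pool flagged
multimapped. Indels and gapped alignment outside annotated introns are not
modelled. With error-free reads this mapper has no false negatives on
linear templates, which the truth-tagged simulations assert; with the
optional substitution-error model, reads carrying an error in both seed
regions can be lost to the unmapped pool, which is conservative for
detection (they lack exact anchors and are then discarded there too).

## Annotation

Genic means ≥ 1 bp overlap with any gene on either strand (interval-tree
lookup). Host assignment follows the exact-boundary longest-fragment rule:
among same-strand transcripts, every run of consecutive exons whose first
exon start and last exon end equal the circle boundaries is a candidate
fragment; the largest summed exon length wins, ties break on transcript
id. Both circle ends must match the same transcript's fragment; one-ended
matches are not accepted. Genic candidates without an exact fragment get
status `overlap` with the maximum-overlap gene as host — a fallback
convention, since only the exact case is well defined.

## Differential expression

Normalization is junction reads per million linearly mapped reads (JRPM);
junction reads themselves are excluded from the library size, which makes
the denominators stable when circRNA content differs between conditions.
The test is a paired two-sided t-test on log2(JRPM + 1) across
tumour/normal pairs (≥ 2 pairs required); the screen is FC ≥ 2 or
≤ 1/2 (inclusive) and P < 0.05 (strict), uncorrected. Which test the
screening convention implies is genuinely open; the paired t-test on
logs was chosen as the simplest test respecting the paired design, and
Benjamini–Hochberg correction is available but off by default to mirror
raw-p screening. Degenerate limits are defined explicitly: all-zero paired
differences give P = 1 (no evidence), constant nonzero differences give
P = 0 (the zero-variance limit of the t statistic). With a pseudocount of
1 on JRPM values in the thousands, a planted effect of exactly 2-fold
lands marginally below the inclusive FC bound; recovery guarantees are
therefore stated for effects of at least 4-fold, the planted default.

Row ordering for heatmaps uses hierarchical agglomerative clustering with
distance 1 − Pearson r and average linkage; constant rows are assigned
r = 0 against everything rather than NaN. Leaf order comes from scipy's
deterministic dendrogram traversal.

## Sponge scanning

Seed-site taxonomy follows the canonical target-prediction conventions:
seed core = reverse complement of miRNA positions 2–7; an m8 match
(position 8) and/or an A opposite position 1 upgrade the site to 7mer-m8,
7mer-A1 or 8mer, with longest-match priority. Only seed pairing is
modelled — no context scores, conservation or free energy. U ≡ T on
input. Circular targets are scanned on the doubled sequence keeping sites
whose core starts in the first copy; this yields rotation-invariant
counts (property-tested) and finds junction-spanning sites, which exist
only on the circular topology. Overlapping sites are all reported; an
optional greedy collapse (longest type first) is available.

## Clinical statistics

Expression is dichotomized at the cohort median with ties going to the
low group by default (`tie_rule="high"` flips this). Note that under the
default rule the high group of an even cohort can never exceed n/2;
uneven splits arise only through ties at the median. 2×2 contingency
tables use Pearson X² with the Yates continuity correction
(|O−E| → max(|O−E|−0.5, 0) per cell); larger tables use the uncorrected
statistic; the statistic is computed from the margins in-package and the
tail probability comes from scipy, with scipy's `chi2_contingency` kept
as an independent cross-check in the tests. Zero margins raise, naming
the degenerate level. Survival uses the lifelines product-limit estimator
(median = earliest time with S(t) ≤ 0.5, infinity if never reached) and
the standard two-group log-rank test, validated against hand product-limit
arithmetic and a permutation null. Pearson correlation reports the
two-sided Student-t p-value on n − 2 df. The xenograft volume formula is
the ellipsoid approximation length × width² / 2 (mm³).

## Synthetic data

The generator emulates the emulated study design: a single-chromosome
random genome (default 1 Mb) with 20 non-overlapping genes of 4–8 exons
(100–300 bp) and introns (200–800 bp) whose splice dinucleotides are
written into the sequence; 15 exonic circles re-using whole internal exon
runs (so boundaries coincide with annotated exons and flanks inherit the
intron signals) and 5 intergenic circles with signals written into gene
deserts; ten tumour/normal library pairs of 100-bp paired-end reads
(dUTP convention: read 2 carries transcript sense); and Phred+33 qualities.
Linear fragments (N(250, 25²)) are sampled uniformly per transcript at 20
pairs per transcript per library. Junction pairs are forced: read 2
crosses the junction at an offset b drawn without replacement from
[20, L−20], so with dispersion 0 the truth-tagged junction-pair count per
library equals the configured abundance exactly and all supporting
sequences are distinct. Junction abundance defaults to 5–15 pairs per
circle; with the planted 4-fold effects this keeps counts within the 61
distinct breakpoint offsets of a 100-nt read, so PCR-duplicate collapse
cannot saturate them. Planted tumour/normal effects (default
log2FC = +2, +2, +2, −2, −2 on the first five circles) scale the
negative-binomial mean; dispersion 0 means deterministic counts.
Sequencing errors are off by default (uniform substitution rate
available). Read names carry truth tags (template, library, junction flag,
breakpoint offset).

The clinical-table generator draws log-normal expression for 120 patients
and exponential survival whose median is 16 months above the expression
median and 45 months below it, censored uniformly on (1, 85) months —
numbers chosen to emulate a poor-prognosis marker over a typical
follow-up window — plus an independent sex covariate and a T-stage
covariate enriched in the high-expression group.

What the simulations do *not* model: sequencing-quality error profiles,
rRNA carry-over, indels, multi-isoform genes (isoform competition in host
assignment is covered by constructed unit tests instead), GC or coverage
bias, PCR duplicates beyond exact-sequence identity, and non-canonical
splice signals. Passing recovery tests therefore demonstrates
correctness of the algorithms under clean, uniquely-mappable conditions,
not performance on real tissue libraries.

## Problem sizes and determinism

Default validation runs use: a 1-Mb genome with 20 planted circles for
detection recovery (single tumour/normal pair), a 250-kb genome with 8
genes and 5 pairs for DE recovery, 5-kb genomes for exhaustive-oracle
equivalence, 2 000–4 000 label permutations for the log-rank null, and
200 replicates for correlation recovery — sizes at which every check runs
comfortably on a laptop. All randomness flows through numpy Generators
seeded from a single configured seed per stage, so identical configs give
byte-identical FASTA/GTF/FASTQ outputs and manifest checksums.

## Known limitations

- The mapper is annotation-guided; novel linear splice junctions would be
  routed to the unmapped pool and could in principle reach the detector
  (they are then rejected by the head-to-tail geometry test).
- Reads from circles shorter than the read length (multi-wrap reads) are
  not modelled or detected.
- The `overlap` host fallback and the breakpoint-uniqueness counting mode
  are conventions exposed for sensitivity analysis, not validated against
  an external truth.
- Fusion (inter-chromosomal) and non-GT/AG junctions are out of scope.
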