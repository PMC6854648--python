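# circseek

Desk-scale discovery and analysis of circular RNAs (circRNAs) from
rRNA-depleted, strand-specific paired-end RNA-seq, together with the
clinical statistics used when a circRNA is evaluated as a tumour marker.
It is aimed at computational biologists who want a fully testable,
self-contained model of a circRNA study: every stage — from read
simulation to survival analysis — runs on synthetic data with known ground
truth, so detection, annotation, differential expression and sponge-site
scanning can all be validated by parameter recovery.

## What it computes

**Back-splice detection.** circRNAs arise by back-splicing: a downstream
splice donor joins an upstream acceptor, producing a covalently closed
circle. A read that crosses the back-splice junction cannot be aligned
colinearly, so detection starts from the reads a linear mapper rejects.
Each unmapped read is reduced to two 20-nt terminal anchors which are
aligned exactly to the genome. Anchors landing in *head-to-tail*
orientation (the 5′ anchor downstream of the 3′ anchor) are the junction
signature; the breakpoint b inside the read is then refined so that both
read segments extend their anchors colinearly with at most 2 mismatches
and the junction is flanked by canonical splice dinucleotides — AG
immediately 5′ of the circle start and GT immediately 3′ of its end
(reverse-complemented on the − strand). Candidates with ≥ 2 unique
back-spliced reads (exact duplicates collapsed) are reported; the junction
read count is the abundance measure.

**Annotation.** A candidate is genic if it overlaps any gene; its host
gene is the gene of the longest run of consecutive exons of a same-strand
transcript whose outer boundaries exactly equal the circle's ends (e.g. a
circle looped by exons 10–11 of a 12-exon transcript).

**Differential expression.** Counts are normalized to junction reads per
million linearly mapped reads; fold change FC = (mean_T + 1)/(mean_N + 1);
a paired two-sided t-test on log2(JRPM + 1) across tumour/normal pairs
gives P; the screen keeps |FC| ≥ 2 and P < 0.05. Heatmap row order comes
from average-linkage clustering under the 1 − Pearson-r distance.

**Sponge scanning.** The mature circle sequence (exons joined, strand
corrected, circular topology) is scanned for miRNA seed sites — 8mer,
7mer-m8, 7mer-A1, 6mer with longest-match priority — including sites that
span the back-splice junction, which only exist on the circular form.

**Clinical statistics.** Median dichotomization of marker expression,
Yates-corrected chi-square for 2×2 contingency tables (plain Pearson X²
for r×c), Kaplan–Meier curves with log-rank comparison, Pearson
correlation, and the xenograft volume formula length × width²/2.

## Worked example

```bash
circseek all --seed 13 --outdir run/
```

simulates a 1-Mb genome with 20 genes and 20 planted circRNAs (15 exonic,
5 intergenic), writes ten paired tumour/normal 100-bp libraries, maps
them, detects junctions and prints the stage summary (abridged):

```json
{
  "detect": {"N1": 20, "T1": 19, "N2": 20, "T2": 19, "...": "..."},
  "diffexp": {"tested": 20, "up": 3, "down": 2},
  "simulate": {"n_circs": 20, "n_genes": 20, "n_libraries": 20}
}
```

Normal libraries recover all 20 planted circles with exact coordinates;
tumour libraries recover 19 because one circle planted with a 4-fold
*down* effect falls below the 2-read support floor there — which is the
point: the 3 up + 2 down differential calls are exactly the five circles
planted with 4-fold effects. `run/circ_annotated.tsv` lists each
candidate with its host gene and exon range, e.g.

```
locus            strand  class  status  host_gene  transcript  exon_range  junction_reads
chr1:7523–9643   +       genic  exact   gene1      gene1.t1    4-7         61
```

Individual stages are available as `circseek
{simulate,map,detect,annotate,sponge,clinstats}`; the library API mirrors
the same steps (`circseek.detect.detect_library`,
`circseek.clinstats.chi_square`, ...).

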