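"""Synthetic rRNA-depleted RNA-seq data with planted circRNAs.

Emulates the study design this package targets: a multi-gene genome with
canonical GT/AG introns, exonic and intergenic circRNAs, paired
tumour/normal strand-specific 100-bp paired-end libraries with planted
fold changes, and a clinical table with group-dependent survival. Every
read is truth-tagged with its template of origin so downstream stages have
an exact recovery oracle.

Splice-signal conventions (plus-strand genome view):
  + strand intron:  GT ... AG      + strand circ flanks:  AG [circ) GT
  − strand intron:  CT ... AC      − strand circ flanks:  AC [circ) CT
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AnnotationSet, Exon, Gene, ReferenceGenome, Transcript, revcomp

log = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimSizingError(ValueError):
    """The requested genes/circRNAs do not fit the configured genome."""


class PlantingError(ValueError):
    """No eligible exon run or intergenic window for a requested circRNA."""


@dataclass
class SimConfig:
    """Study-condition knobs for the simulator.

    Defaults mirror the emulated design: ten paired tumour/normal libraries,
    100-bp paired-end strand-specific reads (dUTP protocol: read 2 carries
    the transcript sense), and twenty planted circRNAs on a 1-Mb genome.
    """

    genome_length: int = 1_000_000
    chrom_name: str = "chr1"
    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (4, 8)
    exon_len: tuple[int, int] = (100, 300)
    intron_len: tuple[int, int] = (200, 800)
    intergenic_gap: tuple[int, int] = (3_000, 8_000)
    n_circ_exonic: int = 15
    n_circ_intergenic: int = 5
    read_len: int = 100
    frag_len_mean: float = 250.0
    frag_len_sd: float = 25.0
    depth_linear: int = 20          # read pairs per transcript per library
    junction_reads_per_circ: tuple[int, int] = (5, 15)
    n_pairs: int = 10               # tumour/normal sample pairs
    planted_log2fc: tuple[float, ...] = (2.0, 2.0, 2.0, -2.0, -2.0)
    noise_dispersion: float = 0.0   # NB dispersion; 0 = deterministic counts
    error_rate: float = 0.0         # uniform substitution rate, off by default
    anchor_len: int = 20            # junction reads keep this margin on both sides
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("exons_per_gene", "exon_len", "intron_len",
                     "intergenic_gap", "junction_reads_per_circ",
                     "planted_log2fc"):
            setattr(self, name, tuple(getattr(self, name)))

    def validate(self) -> None:
        if self.read_len < 2 * self.anchor_len:
            raise ValueError(
                f"read_len={self.read_len} must be ≥ 2 × anchor_len={self.anchor_len}"
            )
        for name in ("exon_len", "intron_len"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} range ({lo}, {hi}) must be positive and ordered")
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if self.n_pairs < 1:
            raise ValueError("need at least one tumour/normal pair")

    def min_mature_len(self) -> int:
        """Shortest circle the fragment model can cover without skipping."""
        return int(self.frag_len_mean + 4 * self.frag_len_sd)


@dataclass
class SimulatedCircRNA:
    """Ground truth for one planted circRNA."""

    circ_id: str
    chrom: str
    start: int                      # 0-based half-open genomic interval
    end: int
    strand: str
    circ_class: str                 # "exonic" | "intergenic"
    gene_id: str | None = None
    transcript_id: str | None = None
    exon_indices: tuple[int, int] | None = None  # 1-based, transcript order
    mature_len: int = 0
    base_reads: int = 0             # mean junction read pairs in normal libraries
    log2fc: float = 0.0             # tumour-vs-normal planted effect

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.strand)


@dataclass
class Library:
    lib_id: str
    condition: str                  # "tumour" | "normal"
    pair_id: int
    r1: Path
    r2: Path
    n_pairs: int = 0


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([stage, config.rng_seed])


# ---------------------------------------------------------------------------
# genome + annotation


def generate_genome(config: SimConfig) -> tuple[ReferenceGenome, AnnotationSet]:
    """Random genome with non-overlapping genes whose introns carry GT/AG.

    Genes alternate placement left-to-right with random intergenic gaps;
    a gene that does not fit raises :class:`SimSizingError` naming the
    constraint. Splice-site dinucleotides are written into the genome so
    every intron starts with GT and ends with AG in transcript orientation.
    """
    config.validate()
    rng = _rng(config, 0)
    seq = bytearray(_BASES[rng.integers(0, 4, config.genome_length)].tobytes())

    genes: list[Gene] = []
    cursor = int(rng.integers(*config.intergenic_gap))
    for gi in range(config.n_genes):
        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exon_lens = rng.integers(config.exon_len[0], config.exon_len[1] + 1, n_ex)
        intron_lens = rng.integers(config.intron_len[0], config.intron_len[1] + 1, n_ex - 1)
        glen = int(exon_lens.sum() + intron_lens.sum())
        if cursor + glen > config.genome_length:
            raise SimSizingError(
                f"gene {gi + 1}/{config.n_genes} (span {glen} bp) does not fit: "
                f"cursor {cursor} + span exceeds genome_length {config.genome_length}"
            )
        strand = "+" if rng.random() < 0.5 else "-"
        exons: list[Exon] = []
        pos = cursor
        for i in range(n_ex):
            exons.append(Exon(pos, pos + int(exon_lens[i])))
            pos += int(exon_lens[i])
            if i < n_ex - 1:
                istart, iend = pos, pos + int(intron_lens[i])
                if strand == "+":
                    seq[istart:istart + 2] = b"GT"
                    seq[iend - 2:iend] = b"AG"
                else:
                    seq[istart:istart + 2] = b"CT"
                    seq[iend - 2:iend] = b"AC"
                pos = iend
        gene_id = f"gene{gi + 1}"
        tx = Transcript(f"{gene_id}.t1", gene_id, config.chrom_name, strand, exons)
        genes.append(Gene(gene_id, config.chrom_name, strand, [tx]))
        cursor = pos + int(rng.integers(*config.intergenic_gap))

    genome = ReferenceGenome({config.chrom_name: seq.decode("ascii")})
    return genome, AnnotationSet(genes)


# ---------------------------------------------------------------------------
# circRNA planting


def _exonic_runs(tx: Transcript, min_mature: int, min_span: int) -> list[tuple[int, int]]:
    """Internal consecutive-exon runs (transcript order, 0-based inclusive)
    long enough for the fragment model. First and last exons are excluded so
    both circle ends face an intron and inherit its splice signal."""
    exons = tx.exons_transcript_order()
    runs = []
    n = len(exons)
    for i in range(1, n - 1):
        for j in range(i, n - 1):
            run = exons[i:j + 1]
            mature = sum(len(e) for e in run)
            start = min(e.start for e in run)
            end = max(e.end for e in run)
            if mature >= min_mature and end - start >= min_span:
                runs.append((i, j))
    return runs


def plant_circrnas(
    genome: ReferenceGenome,
    annotation: AnnotationSet,
    config: SimConfig,
    truth_path: str | Path | None = None,
) -> list[SimulatedCircRNA]:
    """Plant exonic and intergenic circRNAs with valid splice-signal flanks.

    Exonic circles reuse whole internal exon runs of one transcript, so their
    boundaries coincide exactly with annotated exon boundaries and their
    flanking intron dinucleotides already satisfy the GT/AG rule. Intergenic
    circles are placed in gene deserts and have AG/GT (strand-appropriate)
    flanks written into the genome sequence. Mutates ``genome`` in place for
    the intergenic flanks; returns ground truth and optionally writes it as
    TSV.
    """
    config.validate()
    if config.n_circ_exonic > 0 and len(annotation) == 0:
        raise PlantingError("exonic circRNAs requested but the annotation is empty")
    rng = _rng(config, 1)
    min_mature = max(config.min_mature_len(), config.read_len)
    circs: list[SimulatedCircRNA] = []

    eligible = []
    for gene in annotation.genes:
        for tx in gene.transcripts:
            runs = _exonic_runs(tx, min_mature, config.read_len)
            if runs:
                eligible.append((gene, tx, runs))
    if config.n_circ_exonic > len(eligible):
        short = [g.gene_id for g in annotation.genes
                 if all(e[0] is not g for e in eligible)]
        raise PlantingError(
            f"requested {config.n_circ_exonic} exonic circRNAs but only "
            f"{len(eligible)} transcripts have an internal exon run ≥ "
            f"{min_mature} nt (ineligible genes: {', '.join(short) or 'none'})"
        )
    order = rng.permutation(len(eligible))[:config.n_circ_exonic]
    for ci, idx in enumerate(order, start=1):
        gene, tx, runs = eligible[idx]
        i, j = runs[int(rng.integers(len(runs)))]
        run = tx.exons_transcript_order()[i:j + 1]
        start = min(e.start for e in run)
        end = max(e.end for e in run)
        circs.append(SimulatedCircRNA(
            circ_id=f"circ{ci}",
            chrom=tx.chrom, start=start, end=end, strand=tx.strand,
            circ_class="exonic", gene_id=gene.gene_id, transcript_id=tx.transcript_id,
            exon_indices=(i + 1, j + 1),
            mature_len=sum(len(e) for e in run),
        ))

    # intergenic: windows clear of all genes (with a margin) and of each other
    chrom = config.chrom_name
    occupied = [(g.start - 50, g.end + 50) for g in annotation.genes_on(chrom)]
    seq = bytearray(genome[chrom], "ascii")
    glen = len(seq)
    placed = 0
    attempts = 0
    while placed < config.n_circ_intergenic:
        attempts += 1
        if attempts > 200 * max(config.n_circ_intergenic, 1):
            raise PlantingError(
                f"could not place intergenic circRNA {placed + 1}/"
                f"{config.n_circ_intergenic}: no free window of "
                f"{min_mature} bp outside genes"
            )
        span = int(rng.integers(min_mature, min_mature + 400))
        start = int(rng.integers(10, glen - span - 10))
        end = start + span
        if any(s < end + 10 and start - 10 < e for s, e in occupied):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            seq[start - 2:start] = b"AG"
            seq[end:end + 2] = b"GT"
        else:
            seq[start - 2:start] = b"AC"
            seq[end:end + 2] = b"CT"
        occupied.append((start - 10, end + 10))
        placed += 1
        circs.append(SimulatedCircRNA(
            circ_id=f"circ{len(circs) + 1}",
            chrom=chrom, start=start, end=end, strand=strand,
            circ_class="intergenic", mature_len=span,
        ))
    genome.sequences[chrom] = seq.decode("ascii")

    # abundance and planted effects: the configured log2FCs go to the first
    # circles in planting order, the rest are null
    for k, circ in enumerate(circs):
        circ.base_reads = int(rng.integers(config.junction_reads_per_circ[0],
                                           config.junction_reads_per_circ[1] + 1))
        circ.log2fc = config.planted_log2fc[k] if k < len(config.planted_log2fc) else 0.0

    if truth_path is not None:
        truth_table(circs).to_csv(truth_path, sep="\t", index=False)
    return circs


def truth_table(circs: list[SimulatedCircRNA]) -> pd.DataFrame:
    rows = []
    for c in circs:
        d = asdict(c)
        d["exon_indices"] = (
            f"{c.exon_indices[0]}-{c.exon_indices[1]}" if c.exon_indices else ""
        )
        rows.append(d)
    cols = ["circ_id", "chrom", "start", "end", "strand", "circ_class", "gene_id",
            "transcript_id", "exon_indices", "mature_len", "base_reads", "log2fc"]
    return pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)


def mature_circ_sequence(genome: ReferenceGenome, annotation: AnnotationSet,
                         circ: SimulatedCircRNA) -> str:
    """Mature (exon-joined, strand-corrected) circle sequence.

    Position 0 is the circle 5' end, i.e. the base just after the
    back-splice acceptor; the junction sits between the last and first base.
    """
    if circ.circ_class == "exonic":
        tx = next(t for t in annotation.transcripts()
                  if t.transcript_id == circ.transcript_id)
        i, j = circ.exon_indices
        run = tx.exons_transcript_order()[i - 1:j]
        parts = [genome.fetch(circ.chrom, e.start, e.end) for e in run]
        if tx.strand == "-":
            return "".join(revcomp(p) for p in parts)
        return "".join(parts)
    seq = genome.fetch(circ.chrom, circ.start, circ.end)
    return seq if circ.strand == "+" else revcomp(seq)


# ---------------------------------------------------------------------------
# read simulation


def _nb_count(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if mean <= 0:
        return 0
    if dispersion <= 0:
        return int(round(mean))
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return int(rng.poisson(lam))


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = bytearray(seq, "ascii")
    for i in range(len(arr)):
        if rng.random() < rate:
            cur = arr[i]
            repl = _BASES[int(rng.integers(0, 4))]
            while repl == cur:
                repl = _BASES[int(rng.integers(0, 4))]
            arr[i] = repl
    return arr.decode("ascii")


def _mate_pair(fragment: str, read_len: int) -> tuple[str, str]:
    """dUTP first-strand convention: read 2 = transcript sense, read 1 =
    antisense of the fragment's other end."""
    r2 = fragment[:read_len]
    r1 = revcomp(fragment[-read_len:])
    return r1, r2


def simulate_reads(
    genome: ReferenceGenome,
    annotation: AnnotationSet,
    circs: list[SimulatedCircRNA],
    config: SimConfig,
    outdir: str | Path,
) -> tuple[list[Library], pd.DataFrame]:
    """Write per-library paired FASTQ files and return truth counts.

    Linear read pairs are sampled uniformly from each spliced transcript at
    ``depth_linear`` pairs per transcript. Back-splice pairs are sampled
    from the circular mature sequence with read 2 forced to cross the
    junction at an offset ``b`` ∈ [anchor_len, read_len − anchor_len], drawn
    without replacement so supporting sequences are distinct. Tumour
    libraries scale each circle's junction abundance by 2**log2fc; with
    dispersion 0 counts are deterministic. Read names carry truth tags
    (template of origin, junction flag, breakpoint offset).
    """
    config.validate()
    rng = _rng(config, 2)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    L = config.read_len

    tx_seqs = [(tx, tx.spliced_sequence(genome)) for tx in annotation.transcripts()]
    circ_seqs = [(c, mature_circ_sequence(genome, annotation, c)) for c in circs]
    b_choices = np.arange(config.anchor_len, L - config.anchor_len + 1)

    libraries: list[Library] = []
    count_rows = []
    for pair in range(1, config.n_pairs + 1):
        for condition in ("tumour", "normal"):
            lib_id = ("T" if condition == "tumour" else "N") + str(pair)
            r1_path = outdir / f"{lib_id}_R1.fastq"
            r2_path = outdir / f"{lib_id}_R2.fastq"
            n_written = 0
            with open(r1_path, "w") as f1, open(r2_path, "w") as f2:

                def emit(name: str, r1: str, r2: str):
                    nonlocal n_written
                    r1 = _apply_errors(rng, r1, config.error_rate)
                    r2 = _apply_errors(rng, r2, config.error_rate)
                    q = "I" * len(r1)
                    f1.write(f"@{name}\n{r1}\n+\n{q}\n")
                    f2.write(f"@{name}\n{r2}\n+\n{'I' * len(r2)}\n")
                    n_written += 1

                for tx, seq in tx_seqs:
                    if len(seq) < L:
                        log.warning("transcript %s shorter than read length; skipped",
                                    tx.transcript_id)
                        continue
                    for _ in range(config.depth_linear):
                        frag = int(np.clip(round(rng.normal(config.frag_len_mean,
                                                            config.frag_len_sd)),
                                           L, len(seq)))
                        start = int(rng.integers(0, len(seq) - frag + 1))
                        r1, r2 = _mate_pair(seq[start:start + frag], L)
                        emit(f"sim|{lib_id}|{n_written}|tx={tx.transcript_id}|junc=0",
                             r1, r2)

                for circ, cseq in circ_seqs:
                    M = len(cseq)
                    mean = circ.base_reads * (2.0 ** circ.log2fc
                                              if condition == "tumour" else 1.0)
                    count = _nb_count(rng, mean, config.noise_dispersion)
                    if count == 0:
                        count_rows.append((circ.circ_id, lib_id, 0))
                        continue
                    if M < config.frag_len_mean:
                        log.warning("fragment model exceeds circle %s (len %d); "
                                    "template skipped", circ.circ_id, M)
                        count_rows.append((circ.circ_id, lib_id, 0))
                        continue
                    if count <= len(b_choices):
                        bs = rng.choice(b_choices, size=count, replace=False)
                    else:
                        bs = rng.choice(b_choices, size=count, replace=True)
                    for b in np.sort(bs):
                        b = int(b)
                        frag = int(np.clip(round(rng.normal(config.frag_len_mean,
                                                            config.frag_len_sd)),
                                           L, M))
                        doubled = cseq + cseq
                        fragment = doubled[M - b:M - b + frag]
                        r1, r2 = _mate_pair(fragment, L)
                        emit(f"sim|{lib_id}|{n_written}|circ={circ.circ_id}"
                             f"|junc=1|b={b}", r1, r2)
                    count_rows.append((circ.circ_id, lib_id, count))

            libraries.append(Library(lib_id, condition, pair, r1_path, r2_path,
                                     n_written))

    counts = pd.DataFrame(count_rows, columns=["circ_id", "lib_id", "junction_pairs"])
    counts = (counts.pivot(index="circ_id", columns="lib_id", values="junction_pairs")
              .fillna(0).astype(int)
              if len(counts) else pd.DataFrame())
    return libraries, counts


# ---------------------------------------------------------------------------
# clinical table


def generate_clinical_table(
    n_patients: int = 120,
    median_survival_high: float = 16.0,
    median_survival_low: float = 45.0,
    follow_up_max: float = 85.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic patient cohort with expression-dependent survival.

    Expression is log-normal; patients above the cohort median ("high")
    draw exponential survival with the shorter median. Follow-up is
    administratively censored uniformly on (1, ``follow_up_max``) months.
    Categorical covariates: sex (independent) and T stage (enriched in the
    high-expression group), mirroring the kind of contingency structure
    clinical tables report.
    """
    rng = np.random.default_rng([3, seed])
    expr = np.exp(rng.normal(0.0, 1.0, n_patients))
    median = np.median(expr)
    high = expr > median
    scale = np.where(high,
                     median_survival_high / np.log(2),
                     median_survival_low / np.log(2))
    death = rng.exponential(scale)
    censor = rng.uniform(1.0, follow_up_max, n_patients)
    time = np.minimum(death, censor)
    event = (death <= censor).astype(int)
    sex = rng.choice(["male", "female"], n_patients)
    t4_prob = np.where(high, 0.6, 0.3)
    t_stage = np.where(rng.random(n_patients) < t4_prob, "T4", "T1-T3")
    return pd.DataFrame({
        "patient_id": [f"P{i + 1}" for i in range(n_patients)],
        "expression": expr,
        "survival_months": np.round(time, 1),
        "event": event,
        "sex": sex,
        "t_stage": t_stage,
    })
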