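"""Host-gene assignment and genic/intergenic classification of circRNA
candidates.

A candidate is *genic* when its genomic interval overlaps any gene by at
least one base on either strand, else *intergenic*. The host gene of an
exonic circRNA is found by the exact-boundary longest-fragment rule: among
all transcripts on the circle's strand, consider every run of consecutive
exons whose first exon starts at the circle start and whose last exon ends
at the circle end; the run with the greatest summed exon length wins (ties
break by transcript id) and its gene is the host. Genic candidates with no
exact-boundary fragment fall back to the maximum-overlap gene with status
``overlap``.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

from intervaltree import IntervalTree

from .core import AnnotationSet, Transcript
from .detect import CircCandidate


class AnnotationError(KeyError):
    pass


@dataclass
class HostAssignment:
    circ_key: tuple[str, int, int, str]
    status: str                       # "exact" | "overlap" | "intergenic"
    gene_id: str | None = None
    transcript_id: str | None = None
    exon_range: tuple[int, int] | None = None   # 1-based, transcript order
    fragment_len: int = 0             # summed exon length of the matched run


class GeneIndex:
    """Interval index of gene spans per chromosome."""

    def __init__(self, annotation: AnnotationSet):
        self.annotation = annotation
        self.trees: dict[str, IntervalTree] = {}
        self.chroms = {g.chrom for g in annotation.genes}
        for gene in annotation.genes:
            self.trees.setdefault(gene.chrom, IntervalTree()).addi(
                gene.start, gene.end, gene)

    def overlapping(self, chrom: str, start: int, end: int):
        tree = self.trees.get(chrom)
        return [iv.data for iv in tree.overlap(start, end)] if tree else []


def classify_genic(circ: CircCandidate, index: GeneIndex) -> str:
    """"genic" iff the candidate overlaps ≥ 1 base of any gene (either strand)."""
    if index.annotation.genes and circ.chrom not in index.chroms:
        raise AnnotationError(
            f"chromosome {circ.chrom!r} absent from the annotation")
    return "genic" if index.overlapping(circ.chrom, circ.start, circ.end) else "intergenic"


def _exact_fragments(circ: CircCandidate, tx: Transcript):
    """Consecutive-exon runs of ``tx`` whose outer boundaries equal the
    circle's; yields (fragment_len, first_idx, last_idx) in transcript order."""
    exons = tx.exons_transcript_order()
    n = len(exons)
    for i in range(n):
        for j in range(i, n):
            run = exons[i:j + 1]
            if (min(e.start for e in run) == circ.start
                    and max(e.end for e in run) == circ.end):
                yield sum(len(e) for e in run), i + 1, j + 1


def assign_host_gene(circ: CircCandidate, index: GeneIndex) -> HostAssignment:
    """Exact-boundary longest-fragment host assignment (see module docs)."""
    overlapping = index.overlapping(circ.chrom, circ.start, circ.end)
    if not overlapping:
        if index.annotation.genes and circ.chrom not in index.chroms:
            raise AnnotationError(
                f"chromosome {circ.chrom!r} absent from the annotation")
        return HostAssignment(circ.key, "intergenic")

    best: tuple[int, str] | None = None      # (−fragment_len, transcript_id)
    best_assign: HostAssignment | None = None
    for gene in overlapping:
        if gene.strand != circ.strand:
            continue
        for tx in gene.transcripts:
            for frag_len, i, j in _exact_fragments(circ, tx):
                rank = (-frag_len, tx.transcript_id)
                if best is None or rank < best:
                    best = rank
                    best_assign = HostAssignment(
                        circ.key, "exact", gene.gene_id, tx.transcript_id,
                        (i, j), frag_len)
    if best_assign is not None:
        return best_assign

    # no exact-boundary fragment: host = gene with maximum base overlap
    def overlap_len(gene):
        return min(circ.end, gene.end) - max(circ.start, gene.start)

    host = max(overlapping, key=lambda g: (overlap_len(g), g.gene_id))
    return HostAssignment(circ.key, "overlap", host.gene_id)


_LOCUS_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)[–-](?P<end>\d+)$")


def format_locus(chrom: str, start: int, end: int) -> str:
    """Human-readable 1-based inclusive locus string, e.g. chr7:98190727–98194572.

    Internal coordinates stay 0-based half-open; only the text form shifts.
    """
    return f"{chrom}:{start + 1}–{end}"


def parse_locus(text: str) -> tuple[str, int, int]:
    """Inverse of :func:`format_locus` (accepts en-dash or hyphen)."""
    m = _LOCUS_RE.match(text.strip().replace(",", ""))
    if not m:
        raise ValueError(f"unparseable locus string: {text!r}")
    return m["chrom"], int(m["start"]) - 1, int(m["end"])


def annotate_candidates(
    candidates: list[CircCandidate],
    annotation: AnnotationSet,
    path: str | Path | None = None,
) -> list[HostAssignment]:
    """Assign every candidate and optionally write the annotated TSV."""
    index = GeneIndex(annotation)
    assignments = [assign_host_gene(c, index) for c in candidates]
    if path is not None:
        with open(path, "w") as fh:
            fh.write("locus\tstrand\tclass\tstatus\thost_gene\ttranscript\t"
                     "exon_range\tjunction_reads\n")
            for circ, a in zip(candidates, assignments):
                cls = "intergenic" if a.status == "intergenic" else "genic"
                exon_range = f"{a.exon_range[0]}-{a.exon_range[1]}" if a.exon_range else ""
                fh.write(f"{format_locus(circ.chrom, circ.start, circ.end)}\t"
                         f"{circ.strand}\t{cls}\t{a.status}\t{a.gene_id or ''}\t"
                         f"{a.transcript_id or ''}\t{exon_range}\t"
                         f"{circ.junction_read_count}\n")
    return assignments
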