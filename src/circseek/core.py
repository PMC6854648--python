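"""Core containers: reference genome and exon-level gene annotation.

Coordinates are 0-based half-open throughout the library. GTF output is
1-based inclusive per the GTF2.2 standard; BED output is 0-based half-open.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved, N passed through)."""
    return seq.translate(_COMPLEMENT)[::-1]


class ReferenceGenome:
    """A set of named chromosome sequences with FASTA round-trip support."""

    def __init__(self, sequences: dict[str, str] | None = None):
        self.sequences: dict[str, str] = dict(sequences or {})

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Subsequence [start, end), clipped to chromosome bounds."""
        seq = self.sequences[chrom]
        return seq[max(start, 0):min(end, len(seq))]

    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.sequences.items()
        ]
        with open(path, "w") as fh:
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
            writer.write_file(records)

    @classmethod
    def read_fasta(cls, path: str | Path) -> "ReferenceGenome":
        return cls({rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")})


@dataclass(frozen=True)
class Exon:
    start: int
    end: int

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"empty exon [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[Exon] = field(default_factory=list)
    """Exons in genomic (coordinate) order."""

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    def exons_transcript_order(self) -> list[Exon]:
        """Exons in 5'→3' transcript order (reversed for − strand)."""
        return self.exons if self.strand == "+" else self.exons[::-1]

    def introns(self) -> list[tuple[int, int]]:
        """Genomic intron intervals between consecutive exons."""
        return [
            (self.exons[i].end, self.exons[i + 1].start)
            for i in range(len(self.exons) - 1)
        ]

    def spliced_sequence(self, genome: ReferenceGenome) -> str:
        """Mature transcript sequence, 5'→3' (reverse-complemented on −)."""
        s = "".join(genome.fetch(self.chrom, e.start, e.end) for e in self.exons)
        return s if self.strand == "+" else revcomp(s)


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)


class AnnotationSet:
    """Gene → transcript → exon hierarchy with GTF round-trip support."""

    def __init__(self, genes: list[Gene] | None = None):
        self.genes: list[Gene] = list(genes or [])

    def __len__(self) -> int:
        return len(self.genes)

    def transcripts(self) -> Iterator[Transcript]:
        for gene in self.genes:
            yield from gene.transcripts

    def n_exons(self) -> int:
        return sum(len(t.exons) for t in self.transcripts())

    def genes_on(self, chrom: str) -> list[Gene]:
        return [g for g in self.genes if g.chrom == chrom]

    def write_gtf(self, path: str | Path, source: str = "circseek") -> None:
        """Write GTF2.2 (1-based inclusive coordinates)."""
        with open(path, "w") as fh:
            for gene in self.genes:
                fh.write(
                    f"{gene.chrom}\t{source}\tgene\t{gene.start + 1}\t{gene.end}\t.\t"
                    f'{gene.strand}\t.\tgene_id "{gene.gene_id}";\n'
                )
                for tx in gene.transcripts:
                    attrs = f'gene_id "{gene.gene_id}"; transcript_id "{tx.transcript_id}";'
                    fh.write(
                        f"{tx.chrom}\t{source}\ttranscript\t{tx.start + 1}\t{tx.end}\t.\t"
                        f"{tx.strand}\t.\t{attrs}\n"
                    )
                    for i, exon in enumerate(tx.exons_transcript_order(), start=1):
                        fh.write(
                            f"{tx.chrom}\t{source}\texon\t{exon.start + 1}\t{exon.end}\t.\t"
                            f'{tx.strand}\t.\t{attrs} exon_number "{i}";\n'
                        )

    @classmethod
    def read_gtf(cls, path: str | Path) -> "AnnotationSet":
        import pyranges

        df = pyranges.read_gtf(str(path)).df  # pyranges converts to 0-based half-open
        genes: dict[str, Gene] = {}
        txs: dict[str, Transcript] = {}
        for row in df.itertuples(index=False):
            if row.Feature == "gene":
                genes[row.gene_id] = Gene(row.gene_id, str(row.Chromosome), row.Strand)
            elif row.Feature == "transcript":
                tx = Transcript(row.transcript_id, row.gene_id, str(row.Chromosome), row.Strand)
                txs[row.transcript_id] = tx
                genes[row.gene_id].transcripts.append(tx)
            elif row.Feature == "exon":
                txs[row.transcript_id].exons.append(Exon(int(row.Start), int(row.End)))
        for tx in txs.values():
            tx.exons.sort(key=lambda e: e.start)
        # pyranges groups rows by strand; restore coordinate order
        return cls(sorted(genes.values(),
                          key=lambda g: (g.chrom, g.start, g.gene_id)))
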