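"""Minimal annotation-guided linear read mapper.

Partitions reads into linearly mapped (genomic or spliced-transcript,
unique best location, ≤ max_mismatch substitutions) and unmapped — the
input pool for back-splice detection. Deliberately exact-match seeded and
annotation-guided: gapped alignment is only allowed across annotated
introns, via the spliced transcript sequences. Multimapped reads (ties for
the best location) are routed to the unmapped pool with a flag so repeats
cannot create junctions downstream.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from .core import AnnotationSet, ReferenceGenome, Transcript, revcomp

log = logging.getLogger(__name__)


class ParameterError(ValueError):
    pass


class FastqParseError(ValueError):
    pass


@dataclass
class LinearAlignment:
    read_id: str
    chrom: str
    start: int           # leftmost genomic base, 0-based
    strand: str
    mismatches: int
    spliced: bool = False


class KmerIndex:
    """Exact-match k-mer index over both strands.

    Internally only plus-strand k-mers are stored; a lookup also queries the
    reverse complement, reporting those hits on the − strand (a − hit at
    offset *o* means revcomp(seq[o:o+k]) equals the query). Lookups are
    case-insensitive; k-mers containing non-ACGT characters are not indexed.
    """

    def __init__(self, sequences: dict[str, str], k: int):
        if k < 1:
            raise ParameterError(f"k={k} out of range")
        self.k = k
        self._fwd: dict[str, list[tuple[str, int]]] = {}
        acgt = frozenset("ACGT")
        for name, seq in sequences.items():
            s = seq.upper()
            if len(s) < k:
                continue
            fwd = self._fwd
            if set(s) <= acgt:
                for off in range(len(s) - k + 1):
                    fwd.setdefault(s[off:off + k], []).append((name, off))
            else:
                # skip any window touching an ambiguous base
                last_bad = -1
                for off in range(len(s) - k + 1):
                    if s[off + k - 1] not in acgt:
                        last_bad = off + k - 1
                    if off == 0:
                        for i in range(k):
                            if s[i] not in acgt:
                                last_bad = i
                    if last_bad < off:
                        fwd.setdefault(s[off:off + k], []).append((name, off))

    @classmethod
    def from_genome(cls, genome: ReferenceGenome, k: int) -> "KmerIndex":
        if any(k > len(s) for s in genome.sequences.values() if s):
            log.debug("k exceeds a sequence length; that sequence is not indexed")
        return cls(genome.sequences, k)

    def lookup(self, query: str) -> list[tuple[str, int, str]]:
        """All exact-match locations of ``query`` over both strands, sorted."""
        q = query.upper()
        hits = [(c, o, "+") for c, o in self._fwd.get(q, ())]
        rc = revcomp(q)
        hits += [(c, o, "-") for c, o in self._fwd.get(rc, ())]
        return sorted(hits)


def _count_mismatches(a: str, b: str, limit: int) -> int:
    if a == b:
        return 0
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return mm
    return mm


def _tx_to_genomic(tx: Transcript, tpos: int) -> int:
    """Genomic coordinate of transcript-order position ``tpos``."""
    rem = tpos
    for exon in tx.exons_transcript_order():
        if rem < len(exon):
            if tx.strand == "+":
                return exon.start + rem
            return exon.end - 1 - rem
        rem -= len(exon)
    raise IndexError(f"transcript position {tpos} beyond {tx.transcript_id}")


class ReadMapper:
    """Seed-and-verify mapper over the genome and the spliced transcriptome."""

    def __init__(self, genome: ReferenceGenome, annotation: AnnotationSet,
                 k: int = 20, max_mismatch: int = 2):
        if k < 8:
            raise ParameterError(f"seed length k={k} out of range (need 8 ≤ k"
                                 " ≤ read length)")
        self.genome = genome
        self.annotation = annotation
        self.k = k
        self.max_mismatch = max_mismatch
        self.gindex = KmerIndex.from_genome(genome, k)
        self._tx: dict[str, tuple[Transcript, str]] = {
            tx.transcript_id: (tx, tx.spliced_sequence(genome))
            for tx in annotation.transcripts()
        }
        self.tindex = KmerIndex({tid: seq for tid, (_, seq) in self._tx.items()}, k)

    # -- candidate verification -------------------------------------------

    def _verify(self, ref: str, read: str, start: int) -> int | None:
        if start < 0 or start + len(read) > len(ref):
            return None
        mm = _count_mismatches(read, ref[start:start + len(read)], self.max_mismatch)
        return mm if mm <= self.max_mismatch else None

    def _genome_candidates(self, read: str) -> dict[tuple, tuple[int, bool]]:
        """Map from (chrom, gstart, strand) to (mismatches, spliced)."""
        L = len(read)
        out: dict[tuple, tuple[int, bool]] = {}
        rc = revcomp(read)
        for seed_off in (0, L - self.k):
            for chrom, o, s in self.gindex.lookup(read[seed_off:seed_off + self.k]):
                ref = self.genome[chrom]
                if s == "+":
                    gstart = o - seed_off
                    mm = self._verify(ref, read, gstart)
                else:
                    gstart = o - (L - seed_off - self.k)
                    mm = self._verify(ref, rc, gstart)
                if mm is not None:
                    key = (chrom, gstart, s)
                    if key not in out or mm < out[key][0]:
                        out[key] = (mm, False)
        return out

    def _transcript_candidates(self, read: str) -> dict[tuple, tuple[int, bool]]:
        L = len(read)
        out: dict[tuple, tuple[int, bool]] = {}
        rc = revcomp(read)
        for seed_off in (0, L - self.k):
            for tid, o, s in self.tindex.lookup(read[seed_off:seed_off + self.k]):
                tx, seq = self._tx[tid]
                if s == "+":
                    tstart = o - seed_off
                    mm = self._verify(seq, read, tstart)
                else:
                    tstart = o - (L - seed_off - self.k)
                    mm = self._verify(seq, rc, tstart)
                if mm is None:
                    continue
                gpos = (_tx_to_genomic(tx, tstart), _tx_to_genomic(tx, tstart + L - 1))
                gstart = min(gpos)
                # read orientation relative to the genome: sense hit on a −
                # transcript lies on the genomic − strand, and vice versa
                strand = s if tx.strand == "+" else ("-" if s == "+" else "+")
                spliced = max(gpos) - gstart + 1 > L
                key = (tx.chrom, gstart, strand)
                if key not in out or mm < out[key][0]:
                    out[key] = (mm, spliced)
        return out

    def map_read(self, read_id: str, read: str) -> tuple[str, LinearAlignment | None]:
        """Return (status, alignment); status ∈ mapped|unmapped|multimapped."""
        if len(read) < self.k:
            return "unmapped", None
        cands = self._genome_candidates(read)
        for key, (mm, spliced) in self._transcript_candidates(read).items():
            if key not in cands or mm < cands[key][0]:
                cands[key] = (mm, spliced)
            elif mm == cands[key][0] and spliced:
                cands[key] = (mm, spliced)
        if not cands:
            return "unmapped", None
        best = min(mm for mm, _ in cands.values())
        winners = [(key, v) for key, v in cands.items() if v[0] == best]
        if len(winners) > 1:
            return "multimapped", None
        (chrom, start, strand), (mm, spliced) = winners[0]
        return "mapped", LinearAlignment(read_id, chrom, start, strand, mm, spliced)


def iter_fastq(path: str | Path):
    """Yield (read_id, sequence) from a FASTQ file, with parse diagnostics."""
    n = 0
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            n += 1
            yield rec.id, str(rec.seq).upper()
    except ValueError as exc:
        raise FastqParseError(
            f"{path}: malformed FASTQ near record {n + 1} "
            f"(approx. line {4 * n + 1}): {exc}"
        ) from exc


def partition_reads(
    r1_path: str | Path,
    r2_path: str | Path,
    mapper: ReadMapper,
    mapped_out: str | Path | None = None,
    unmapped_out: str | Path | None = None,
) -> tuple[list[LinearAlignment], list[tuple[str, str, str]], dict]:
    """Split a paired FASTQ library into mapped and unmapped read stores.

    Every input read lands in exactly one store. Returns the mapped
    alignments, the unmapped reads as (read_id, mate, sequence) tuples, and
    a stats dict whose ``mapped`` total feeds count normalization.
    Optionally writes the mapped store as headered TSV and the unmapped
    store as FASTQ.
    """
    mapped: list[LinearAlignment] = []
    unmapped: list[tuple[str, str, str]] = []
    stats = {"total": 0, "mapped": 0, "unmapped": 0, "multimapped": 0}
    for path, mate in ((r1_path, "1"), (r2_path, "2")):
        for read_id, seq in iter_fastq(path):
            stats["total"] += 1
            status, aln = mapper.map_read(f"{read_id}/{mate}", seq)
            if status == "mapped":
                stats["mapped"] += 1
                mapped.append(aln)
            else:
                stats["unmapped"] += 1
                if status == "multimapped":
                    stats["multimapped"] += 1
                unmapped.append((read_id, mate, seq))
    log.info("partitioned %d reads: %d mapped, %d unmapped (%d multimapped)",
             stats["total"], stats["mapped"], stats["unmapped"],
             stats["multimapped"])
    if mapped_out is not None:
        with open(mapped_out, "w") as fh:
            fh.write("read_id\tchrom\tstart\tstrand\tmismatches\tspliced\n")
            for a in mapped:
                fh.write(f"{a.read_id}\t{a.chrom}\t{a.start}\t{a.strand}\t"
                         f"{a.mismatches}\t{int(a.spliced)}\n")
    if unmapped_out is not None:
        with open(unmapped_out, "w") as fh:
            for read_id, mate, seq in unmapped:
                fh.write(f"@{read_id}/{mate}\n{seq}\n+\n{'I' * len(seq)}\n")
    return mapped, unmapped, stats
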