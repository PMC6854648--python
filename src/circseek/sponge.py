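"""miRNA seed-match scanning on circular and linear targets.

Seed-site taxonomy follows the canonical target-prediction conventions:
the seed core is the reverse complement of miRNA positions 2–7; an
additional match to position 8 on the target 5' side and/or an adenine
opposite position 1 on the target 3' side upgrade the site, with
longest-match priority:

    8mer      m8 match + A1 adenine
    7mer-m8   m8 match only
    7mer-A1   A1 adenine only
    6mer      seed core only

Only seed-region pairing is modelled — no context scores or free-energy
terms. U and T are equivalent on input. Circular targets are scanned on
the doubled sequence, keeping sites whose seed core starts in the first
copy, so sites spanning the back-splice junction (position 0) are found
and flagged; site counts are invariant under rotation of the circle.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .core import revcomp

_VALID = frozenset("ACGT")


class SequenceError(ValueError):
    pass


@dataclass
class MatureCircSequence:
    """Exon-joined, strand-corrected circle sequence; position arithmetic
    is modulo length, with the back-splice junction preceding position 0."""

    circ_id: str
    sequence: str
    topology: str = "circular"


@dataclass(frozen=True)
class SeedMatch:
    target_id: str
    mirna_id: str
    site_type: str              # 8mer | 7mer-m8 | 7mer-A1 | 6mer
    start: int                  # site start on target (mod length if circular)
    length: int
    spans_junction: bool = False


def _clean(seq: str, what: str) -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - _VALID
    if bad:
        raise SequenceError(f"non-nucleotide characters in {what}: {sorted(bad)}")
    return s


def extract_circ_sequence(circ_key, genome, annotation, assignment) -> MatureCircSequence:
    """Mature circle sequence for an annotated candidate.

    For an exact (exonic) host assignment the matched exon run is joined in
    transcript order and strand-corrected; otherwise the raw genomic
    interval is used with a logged warning.
    """
    import logging

    chrom, start, end, strand = circ_key
    circ_id = f"{chrom}:{start}-{end}|{strand}"
    if assignment is not None and assignment.status == "exact":
        tx = next(t for t in annotation.transcripts()
                  if t.transcript_id == assignment.transcript_id)
        i, j = assignment.exon_range
        run = tx.exons_transcript_order()[i - 1:j]
        parts = [genome.fetch(chrom, e.start, e.end) for e in run]
        seq = ("".join(revcomp(p) for p in parts) if strand == "-"
               else "".join(parts))
    else:
        logging.getLogger(__name__).warning(
            "%s has no exact host assignment; using the raw genomic interval",
            circ_id)
        seq = genome.fetch(chrom, start, end)
        if strand == "-":
            seq = revcomp(seq)
    return MatureCircSequence(circ_id, seq)


def find_seed_matches(
    target: str | MatureCircSequence,
    mirna: str,
    mirna_id: str = "miRNA",
    target_id: str | None = None,
    topology: str | None = None,
) -> list[SeedMatch]:
    """All seed-binding elements of ``mirna`` on ``target``.

    Overlapping sites are all reported. For circular topology the site
    start is reported modulo the circle length and ``spans_junction`` marks
    sites crossing position 0.
    """
    if isinstance(target, MatureCircSequence):
        seq = _clean(target.sequence, "target")
        topology = topology or target.topology
        target_id = target_id or target.circ_id
    else:
        seq = _clean(target, "target")
        topology = topology or "linear"
        target_id = target_id or "target"
    mir = _clean(mirna, "miRNA")
    if len(mir) < 8:
        raise SequenceError(f"miRNA {mirna_id} shorter than 8 nt")
    circular = topology == "circular"

    core = revcomp(mir[1:7])            # pairs miRNA positions 7..2, 5'→3'
    m8_base = revcomp(mir[7])           # target base pairing position 8
    L = len(seq)
    if L < 6:
        return []
    scan = seq + seq if circular else seq

    matches = []
    for p in range(L if circular else L - 5):
        if scan[p:p + 6] != core:
            continue
        if circular:
            m8 = scan[p - 1] if p > 0 else seq[-1]
            a1 = scan[p + 6]
        else:
            m8 = scan[p - 1] if p > 0 else None
            a1 = scan[p + 6] if p + 6 < L else None
        has_m8 = m8 == m8_base
        has_a1 = a1 == "A"
        if has_m8 and has_a1:
            site_type = "8mer"
        elif has_m8:
            site_type = "7mer-m8"
        elif has_a1:
            site_type = "7mer-A1"
        else:
            site_type = "6mer"
        start = p - 1 if has_m8 else p
        length = 6 + int(has_m8) + int(has_a1)
        spans = circular and (start < 0 or start + length > L)
        matches.append(SeedMatch(target_id, mirna_id, site_type,
                                 start % L if circular else start,
                                 length, spans))
    return matches


def count_binding_elements(
    target: str | MatureCircSequence,
    mirna: str,
    mirna_id: str = "miRNA",
    topology: str | None = None,
    collapse_overlaps: bool = False,
) -> dict[str, int]:
    """Total and per-type site counts; deterministic.

    With ``collapse_overlaps`` sites sharing target bases are greedily
    merged (left-to-right, longest type wins); the default reports all.
    """
    matches = find_seed_matches(target, mirna, mirna_id, topology=topology)
    if collapse_overlaps:
        priority = {"8mer": 0, "7mer-m8": 1, "7mer-A1": 2, "6mer": 3}
        kept: list[SeedMatch] = []
        for m in sorted(matches, key=lambda m: (priority[m.site_type], m.start)):
            if all(m.start + m.length <= k.start or k.start + k.length <= m.start
                   for k in kept):
                kept.append(m)
        matches = kept
    counts = {"8mer": 0, "7mer-m8": 0, "7mer-A1": 0, "6mer": 0}
    for m in matches:
        counts[m.site_type] += 1
    counts["total"] = len(matches)
    return counts


def write_site_table(matches: list[SeedMatch], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("target_id\tmirna_id\tsite_type\tstart\tlength\tspans_junction\n")
        for m in matches:
            fh.write(f"{m.target_id}\t{m.mirna_id}\t{m.site_type}\t{m.start}\t"
                     f"{m.length}\t{int(m.spans_junction)}\n")
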