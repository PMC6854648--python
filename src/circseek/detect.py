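"""Back-splice junction detection from unmapped reads.

The detector takes the reads the linear mapper could not place, splits each
into two fixed-length terminal anchors, and aligns the anchors exactly to
the genome. Anchors landing in head-to-tail orientation (the 5' anchor
downstream of the 3' anchor) are the signature of a back-splice; the
breakpoint inside the read is then refined so that the full read aligns
colinearly on both sides and the junction is flanked by the canonical
splice dinucleotides (acceptor AG immediately 5' of the circle start,
donor GT immediately 3' of the circle end, in strand orientation).
Junction evidence is aggregated into circRNA candidates supported by at
least ``min_reads`` unique back-spliced reads.

Strand is inferred from the flank signature on the plus-strand genome:
AG…GT brackets a + circle, AC…CT (the reverse-complemented signals) a −
circle. This makes detection independent of which mate, or which
orientation, a junction-crossing read was sequenced in.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .core import ReferenceGenome, revcomp
from .mapping import KmerIndex, _count_mismatches

log = logging.getLogger(__name__)

DEFAULT_ANCHOR_LEN = 20
DEFAULT_MIN_READS = 2
DEFAULT_MAX_MISMATCH = 2


@dataclass
class AnchorPair:
    read_id: str
    a5: str                     # first anchor_len bases of the read
    a3: str                     # last anchor_len bases
    a5_hit: tuple[str, int, str] | str | None = None
    a3_hit: tuple[str, int, str] | str | None = None
    """Unique hit as (chrom, offset, strand); the string "ambiguous" when
    the anchor matches more than one location; None when it matches none."""


@dataclass(frozen=True)
class BackspliceJunction:
    chrom: str
    start: int                  # acceptor side, 0-based
    end: int                    # donor side, half-open
    strand: str
    breakpoint: int             # offset b of the junction inside the read
    mismatches: int
    splice_signal_ok: bool = True

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"degenerate junction [{self.start}, {self.end})")

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.strand)


@dataclass
class SupportingRead:
    read_id: str
    fragment_id: str
    sequence: str
    junction: BackspliceJunction


@dataclass
class CircCandidate:
    chrom: str
    start: int
    end: int
    strand: str
    junction_read_count: int
    read_ids: list[str] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.strand)

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}|{self.strand}"


def extract_anchors(read_id: str, read: str,
                    anchor_len: int = DEFAULT_ANCHOR_LEN) -> AnchorPair | None:
    """Terminal anchors of a read; None (with a logged reason) if too short."""
    if len(read) < 2 * anchor_len:
        log.debug("read %s shorter than 2 × anchor_len=%d; skipped",
                  read_id, anchor_len)
        return None
    read = read.upper()
    return AnchorPair(read_id, read[:anchor_len], read[-anchor_len:])


def align_anchor(anchor: str, index: KmerIndex) -> tuple[str, int, str] | str | None:
    """Unique exact-match location over both strands, else "ambiguous"/None."""
    hits = index.lookup(anchor)
    if not hits:
        return None
    if len(hits) > 1:
        return "ambiguous"
    return hits[0]


def _flank_strand(genome: ReferenceGenome, chrom: str, start: int, end: int) -> str | None:
    """Which strand's splice signature brackets [start, end), if any.

    + circle: genome[start−2:start] == AG and genome[end:end+2] == GT.
    − circle: the reverse-complemented signals, AC … CT.
    Prefers + deterministically in the (vanishing) case both match.
    """
    left = genome.fetch(chrom, start - 2, start)
    right = genome.fetch(chrom, end, end + 2)
    if left == "AG" and right == "GT":
        return "+"
    if left == "AC" and right == "CT":
        return "-"
    return None


def detect_backsplice(
    read_id: str,
    read: str,
    anchors: AnchorPair,
    genome: ReferenceGenome,
    anchor_len: int = DEFAULT_ANCHOR_LEN,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> BackspliceJunction | None:
    """Refine a head-to-tail anchor pair into a back-splice junction.

    Both anchors must have unique hits on the same chromosome and strand.
    The read is oriented so its anchors align to the plus strand; in
    head-to-tail geometry the prefix anchor then sits downstream of the
    suffix anchor. Every breakpoint b in [anchor_len, L − anchor_len] is
    scored: read[:b] must extend the prefix anchor colinearly (its last
    base abutting the donor) and read[b:] the suffix anchor (its first base
    at the acceptor). The accepted b minimizes total mismatches among
    breakpoints whose flanks pass the splice-signal test; ties break to the
    smallest b.
    """
    a5, a3 = anchors.a5_hit, anchors.a3_hit
    if not isinstance(a5, tuple) or not isinstance(a3, tuple):
        return None
    if a5[0] != a3[0] or a5[2] != a3[2]:
        return None
    chrom = a5[0]
    read = read.upper()
    L = len(read)
    if a5[2] == "+":
        s, o5, o3 = read, a5[1], a3[1]
    else:
        # reverse-complement the read onto the plus strand; anchor roles swap
        s, o5, o3 = revcomp(read), a3[1], a5[1]
    if o5 <= o3:
        return None                      # colinear, not head-to-tail

    ref = genome[chrom]
    best: tuple[int, int, int, int, str] | None = None   # (mm, b, start, end, strand)
    for b in range(anchor_len, L - anchor_len + 1):
        end = o5 + b
        start = o3 + anchor_len - (L - b)
        if start < 0 or end > len(ref) or start >= end:
            continue
        strand = _flank_strand(genome, chrom, start, end)
        if strand is None:
            continue
        mm = _count_mismatches(s[:b], ref[o5:end], max_mismatch)
        if mm > max_mismatch:
            continue
        mm += _count_mismatches(s[b:], ref[start:start + L - b], max_mismatch - mm)
        if mm > max_mismatch:
            continue
        if best is None or (mm, b) < best[:2]:
            best = (mm, b, start, end, strand)
    if best is None:
        return None
    mm, b, start, end, strand = best
    return BackspliceJunction(chrom, start, end, strand, b, mm)


def scan_read(
    read_id: str,
    fragment_id: str,
    read: str,
    genome: ReferenceGenome,
    index: KmerIndex,
    anchor_len: int = DEFAULT_ANCHOR_LEN,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> SupportingRead | None:
    """Full anchor → align → refine flow for one read."""
    anchors = extract_anchors(read_id, read, anchor_len)
    if anchors is None:
        return None
    anchors.a5_hit = align_anchor(anchors.a5, index)
    anchors.a3_hit = align_anchor(anchors.a3, index)
    junction = detect_backsplice(read_id, read, anchors, genome,
                                 anchor_len, max_mismatch)
    if junction is None:
        return None
    return SupportingRead(read_id, fragment_id, read.upper(), junction)


def call_circrnas(
    supports: list[SupportingRead],
    min_reads: int = DEFAULT_MIN_READS,
    unique_by: str = "sequence",
) -> list[CircCandidate]:
    """Aggregate junction evidence into circRNA candidates.

    Junctions are grouped by (chrom, start, end, strand). A fragment
    supports a junction at most once (the first mate seen wins). Support is
    the number of *unique* back-spliced reads: distinct read sequences by
    default (collapsing exact PCR duplicates), or distinct breakpoint
    offsets with ``unique_by="breakpoint"``. Candidates below ``min_reads``
    are dropped; output is sorted by coordinate.
    """
    if unique_by not in ("sequence", "breakpoint"):
        raise ValueError(f"unique_by must be 'sequence' or 'breakpoint', "
                         f"got {unique_by!r}")
    by_key: dict[tuple, dict[str, SupportingRead]] = {}
    for sup in supports:
        frags = by_key.setdefault(sup.junction.key, {})
        frags.setdefault(sup.fragment_id, sup)     # one vote per fragment
    out = []
    for key in sorted(by_key):
        frags = by_key[key]
        if unique_by == "sequence":
            uniq = {s.sequence for s in frags.values()}
        else:
            uniq = {s.junction.breakpoint for s in frags.values()}
        if len(uniq) < min_reads:
            continue
        chrom, start, end, strand = key
        out.append(CircCandidate(chrom, start, end, strand, len(uniq),
                                 sorted(s.read_id for s in frags.values())))
    return out


def detect_library(
    unmapped: list[tuple[str, str, str]],
    genome: ReferenceGenome,
    index: KmerIndex,
    anchor_len: int = DEFAULT_ANCHOR_LEN,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    min_reads: int = DEFAULT_MIN_READS,
    unique_by: str = "sequence",
) -> list[CircCandidate]:
    """Detect circRNA candidates from one library's unmapped read store."""
    supports = []
    for read_id, mate, seq in unmapped:
        sup = scan_read(f"{read_id}/{mate}", read_id, seq, genome, index,
                        anchor_len, max_mismatch)
        if sup is not None:
            supports.append(sup)
    return call_circrnas(supports, min_reads, unique_by)


def write_bed(candidates: list[CircCandidate], path: str | Path) -> None:
    """BED6: name = chrom:start-end|strand, score = junction read count."""
    with open(path, "w") as fh:
        for c in candidates:
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.name}\t"
                     f"{c.junction_read_count}\t{c.strand}\n")
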