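"""Back-splice detector: anchor handling, breakpoint refinement against an
exhaustive (start, end, breakpoint) oracle, flank soundness, duplicate
collapse, and full parameter recovery on simulated data."""
import re

import pytest

from circseek.core import ReferenceGenome, revcomp
from circseek.detect import (BackspliceJunction, SupportingRead, align_anchor,
                             call_circrnas, detect_backsplice, detect_library,
                             extract_anchors, scan_read)
from circseek.mapping import KmerIndex, ReadMapper, partition_reads, iter_fastq
from circseek.simulate import simulate_reads
from conftest import random_genome

ANCHOR = 20
SIGNALS = {"+": ("AG", "GT"), "-": ("AC", "CT")}


def _find_all(haystack, needle):
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def exhaustive_backsplice(read, genome, max_mismatch=2, anchor_len=ANCHOR):
    """Independent brute force over every (start, end, b) triple whose
    terminal anchors match the genome exactly, in either read orientation.

    For each candidate the read is validated by reconstructing the window
    of the circularized interval that crosses the junction b bases in —
    circle[-b:] + circle[:L−b] — and the flank signature fixes the strand.
    Small genomes only.
    """
    read = read.upper()
    L = len(read)
    best = None
    for chrom, seq in genome.sequences.items():
        for s in (read, revcomp(read)):
            for b in range(anchor_len, L - anchor_len + 1):
                for o5 in _find_all(seq, s[:anchor_len]):
                    end = o5 + b
                    for o3 in _find_all(seq, s[-anchor_len:]):
                        start = o3 + anchor_len - (L - b)
                        if start < 2 or start >= end or end + 2 > len(seq):
                            continue
                        if end - start < L:   # read must fit in the circle
                            continue
                        strand = None
                        for st, (left, right) in SIGNALS.items():
                            if (seq[start - 2:start] == left
                                    and seq[end:end + 2] == right):
                                strand = st
                                break
                        if strand is None:
                            continue
                        circle = seq[start:end]
                        window = circle[-b:] + circle[:L - b]
                        mm = sum(a != c for a, c in zip(s, window))
                        if mm <= max_mismatch:
                            cand = (mm, b, chrom, start, end, strand)
                            if best is None or cand[:2] < best[:2]:
                                best = cand
    if best is None:
        return None
    mm, b, chrom, start, end, strand = best
    return (chrom, start, end, strand, b, mm)


def test_anchor_extraction_prefix_and_suffix():
    read = "".join("ACGT"[(i * 7) % 4] for i in range(100))
    pair = extract_anchors("r", read)
    assert pair.a5 == read[:20] and pair.a3 == read[80:]

    read40 = read[:40]
    pair40 = extract_anchors("r", read40)
    assert pair40.a5 + pair40.a3 == read40

    assert extract_anchors("r", read[:39]) is None


def test_anchor_alignment_unique_ambiguous_none():
    genome = random_genome(1_000, seed=21)
    seq = genome["chr1"]
    rep = ReferenceGenome({"chr1": seq[:500] + seq[100:120] + seq[520:]})
    idx = KmerIndex(rep.sequences, k=20)
    assert align_anchor(seq[300:320], idx) == ("chr1", 300, "+")
    assert align_anchor(seq[100:120], idx) == "ambiguous"
    assert align_anchor("A" * 20, idx) is None


def test_anchor_hits_equal_brute_force(toy_circle_genome):
    genome, _, _ = toy_circle_genome
    seq = genome["chr1"]
    idx = KmerIndex.from_genome(genome, 20)
    for off in range(0, 380, 37):
        anchor = seq[off:off + 20]
        hit = align_anchor(anchor, idx)
        brute = ([("chr1", i, "+") for i in range(len(seq) - 19)
                  if seq[i:i + 20] == anchor]
                 + [("chr1", i, "-") for i in range(len(seq) - 19)
                    if revcomp(seq[i:i + 20]) == anchor])
        if len(brute) == 1:
            assert hit == brute[0]
        else:
            assert hit == "ambiguous"


def _scan(read, genome, idx):
    return scan_read("r/1", "r", read, genome, idx)


def test_planted_circle_read_detected_at_exact_breakpoint(toy_circle_genome):
    genome, start, end = toy_circle_genome
    seq = genome["chr1"]
    circle = seq[start:end]
    read = circle[-50:] + circle[:50]
    idx = KmerIndex.from_genome(genome, 20)
    sup = _scan(read, genome, idx)
    j = sup.junction
    assert (j.chrom, j.start, j.end, j.strand, j.breakpoint) == \
           ("chr1", start, end, "+", 50)
    assert exhaustive_backsplice(read, genome) == \
           ("chr1", start, end, "+", 50, 0)


def test_mutated_donor_signal_kills_the_junction(toy_circle_genome):
    genome, start, end = toy_circle_genome
    seq = bytearray(genome["chr1"], "ascii")
    seq[end:end + 2] = b"GG"
    broken = ReferenceGenome({"chr1": seq.decode()})
    circle = broken["chr1"][start:end]
    read = circle[-50:] + circle[:50]
    idx = KmerIndex.from_genome(broken, 20)
    assert _scan(read, broken, idx) is None
    assert exhaustive_backsplice(read, broken) is None


def test_colinear_read_is_not_head_to_tail(toy_circle_genome):
    genome, start, end = toy_circle_genome
    read = genome["chr1"][150:250]
    idx = KmerIndex.from_genome(genome, 20)
    assert _scan(read, genome, idx) is None


def test_minus_strand_circle_and_antisense_mate(toy_circle_genome):
    """A − strand circle (AC…CT flanks) is found from its sense read, and
    the reverse-complement mate of a + circle converges to the + record."""
    genome, start, end = toy_circle_genome
    seq = bytearray(genome["chr1"], "ascii")
    seq[start - 2:start] = b"AC"
    seq[end:end + 2] = b"CT"
    minus = ReferenceGenome({"chr1": seq.decode()})
    mature = revcomp(minus["chr1"][start:end])
    read = mature[-50:] + mature[:50]
    idx = KmerIndex.from_genome(minus, 20)
    j = _scan(read, minus, idx).junction
    assert (j.start, j.end, j.strand) == (start, end, "-")

    plus_genome, start, end = genome, start, end
    circle = plus_genome["chr1"][start:end]
    antisense = revcomp(circle[-40:] + circle[:60])
    idx = KmerIndex.from_genome(plus_genome, 20)
    j = _scan(antisense, plus_genome, idx).junction
    assert (j.start, j.end, j.strand) == (start, end, "+")


def test_detection_matches_exhaustive_oracle_on_simulated_reads(tmp_path):
    """On a ≤ 5 kb genome every simulated junction read agrees with the
    exhaustive (start, end, breakpoint) search."""
    from circseek.simulate import SimConfig, generate_genome, plant_circrnas

    config = SimConfig(genome_length=5_000, n_genes=1, exons_per_gene=(4, 4),
                       exon_len=(150, 200), intron_len=(200, 300),
                       intergenic_gap=(200, 400), n_circ_exonic=1,
                       n_circ_intergenic=1, n_pairs=1, depth_linear=0,
                       junction_reads_per_circ=(4, 4), planted_log2fc=(),
                       frag_len_mean=150.0, frag_len_sd=10.0, rng_seed=17)
    genome, annotation = generate_genome(config)
    circs = plant_circrnas(genome, annotation, config)
    libraries, _ = simulate_reads(genome, annotation, circs, config, tmp_path)
    idx = KmerIndex.from_genome(genome, 20)
    truth = {c.circ_id: c for c in circs}
    checked = 0
    for read_id, seq in iter_fastq(libraries[0].r2):
        m = re.search(r"circ=(\w+)\|junc=1\|b=(\d+)", read_id)
        if not m:
            continue
        circ = truth[m.group(1)]
        sup = scan_read(read_id, read_id, seq, genome, idx)
        oracle = exhaustive_backsplice(seq, genome)
        assert sup is not None and oracle is not None
        j = sup.junction
        assert (j.chrom, j.start, j.end, j.strand, j.breakpoint, j.mismatches) == oracle
        assert (j.start, j.end, j.strand) == (circ.start, circ.end, circ.strand)
        checked += 1
    assert checked == 8  # two circles × 4 forced junction pairs


def test_emitted_junction_flanks_recheck_against_genome(small_config, small_sim,
                                                        tmp_path):
    genome, annotation, circs = small_sim
    libraries, _ = simulate_reads(genome, annotation, circs, small_config, tmp_path)
    mapper = ReadMapper(genome, annotation)
    _, unmapped, _ = partition_reads(libraries[0].r1, libraries[0].r2, mapper)
    for cand in detect_library(unmapped, genome, mapper.gindex):
        left, right = SIGNALS[cand.strand]
        assert genome.fetch(cand.chrom, cand.start - 2, cand.start) == left
        assert genome.fetch(cand.chrom, cand.end, cand.end + 2) == right


def _support(seq, b=30, read_id="r1", frag="f1",
             key=("chr1", 100, 300, "+")):
    j = BackspliceJunction(*key, breakpoint=b, mismatches=0)
    return SupportingRead(read_id, frag, seq, j)


def test_duplicate_sequences_collapse_to_one_supporting_read():
    dup = [_support("ACGT" * 25, read_id="a", frag="fa"),
           _support("ACGT" * 25, read_id="b", frag="fb")]
    assert call_circrnas(dup, min_reads=2) == []
    distinct = [_support("ACGT" * 25, read_id="a", frag="fa"),
                _support("TGCA" * 25, b=40, read_id="b", frag="fb")]
    cands = call_circrnas(distinct, min_reads=2)
    assert len(cands) == 1 and cands[0].junction_read_count == 2


def test_one_fragment_supports_a_junction_once():
    mates = [_support("ACGT" * 25, read_id="r/1", frag="r"),
             _support("TGCA" * 25, read_id="r/2", frag="r")]
    assert call_circrnas(mates, min_reads=2) == []


def test_breakpoint_uniqueness_mode():
    same_b = [_support("ACGT" * 25, b=30, read_id="a", frag="fa"),
              _support("TGCA" * 25, b=30, read_id="b", frag="fb")]
    assert call_circrnas(same_b, min_reads=2, unique_by="breakpoint") == []
    assert len(call_circrnas(same_b, min_reads=2, unique_by="sequence")) == 1


@pytest.mark.parametrize("min_reads", [1, 2, 3, 5])
def test_raising_min_reads_never_adds_candidates(min_reads, small_config,
                                                 small_sim, tmp_path):
    genome, annotation, circs = small_sim
    libraries, _ = simulate_reads(genome, annotation, circs, small_config, tmp_path)
    mapper = ReadMapper(genome, annotation)
    _, unmapped, _ = partition_reads(libraries[0].r1, libraries[0].r2, mapper)
    supports = [s for s in
                (scan_read(f"{rid}/{mate}", rid, seq, genome, mapper.gindex)
                 for rid, mate, seq in unmapped) if s]
    loose = {c.key for c in call_circrnas(supports, min_reads=min_reads)}
    strict = {c.key for c in call_circrnas(supports, min_reads=min_reads + 1)}
    assert strict <= loose


def test_full_recovery_of_planted_circles(small_config, small_sim, tmp_path):
    """Clean data: every planted circle recovered with exact coordinates
    across libraries, no false positives."""
    genome, annotation, circs = small_sim
    libraries, counts = simulate_reads(genome, annotation, circs,
                                       small_config, tmp_path)
    mapper = ReadMapper(genome, annotation)
    truth = {c.key for c in circs}
    recovered = set()
    for lib in libraries:
        _, unmapped, _ = partition_reads(lib.r1, lib.r2, mapper)
        for cand in detect_library(unmapped, genome, mapper.gindex, min_reads=2):
            assert cand.key in truth          # soundness: no false positives
            recovered.add(cand.key)
    assert recovered == truth
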