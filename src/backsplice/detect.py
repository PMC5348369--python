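"""Back-splice junction detection from unmapped reads.

A read spanning a circRNA's head-to-tail fusion fails linear alignment: its 5'
portion comes from the genomic *tail* (donor) side of the circle and its 3'
portion from the *head* (acceptor) side.  Detection therefore splits each
unmapped read into terminal anchors (20-mers by default), realigns the anchors
exactly against the genome, keeps anchor pairs mapping in reversed
("3' to 5'") genomic order, and then extends both anchors toward the read
interior to pin the exact breakpoint, requiring the canonical AG acceptor
immediately upstream of the circle start and the GT donor immediately
downstream of the circle end (CT/AC in plus-strand genome letters for minus-
strand circles).

Anchor alignment is exact-match (0 mismatches) against a k-mer index; an
anchor containing N never aligns.  Only reads whose two anchors each map to
exactly one genomic location can seed a candidate.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Set, Tuple, Union

import pysam

from .reference import Genome, GenomicInterval, reverse_complement

__all__ = [
    "AnchorAlignment",
    "CandidateSeed",
    "CircCandidate",
    "KmerIndex",
    "UnmappedRead",
    "align_anchor",
    "detect_head_to_tail",
    "detect_sample",
    "extract_unmapped",
    "make_anchors",
    "quantify",
    "refine_breakpoint",
]

logger = logging.getLogger(__name__)

DEFAULT_ANCHOR_LEN = 20
DEFAULT_MAX_SPAN = 100_000

# splice dinucleotides flanking the circle, written in plus-strand genome
# letters: (upstream-of-start, downstream-of-end)
_SIGNALS = {"+": ("AG", "GT"), "-": ("AC", "CT")}


@dataclass(frozen=True)
class UnmappedRead:
    read_id: str
    sequence: str
    mate_index: int = 0  # 1 or 2 for paired data, 0 for single-end


@dataclass(frozen=True)
class AnchorAlignment:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    which_end: str  # "five_prime" or "three_prime" of the read


@dataclass(frozen=True)
class CandidateSeed:
    read_id: str
    chrom: str
    strand: str
    head_anchor: AnchorAlignment  # from the read's 5' end
    tail_anchor: AnchorAlignment  # from the read's 3' end


@dataclass
class CircCandidate:
    interval: GenomicInterval
    supporting_read_ids: Set[str] = field(default_factory=set)
    splice_signal: bool = True

    @property
    def support(self) -> int:
        return len(self.supporting_read_ids)

    @property
    def key(self) -> Tuple[str, int, int, str]:
        iv = self.interval
        return (iv.chrom, iv.start, iv.end, iv.strand)


def extract_unmapped(
    alignment_path: Union[str, Path],
) -> Tuple[List[UnmappedRead], int]:
    """Pull unmapped records from a SAM/BAM file.

    Each mate of a pair is treated as an independent read.  Returns the reads
    and the total unmapped-record count (used downstream for normalization;
    records with no stored sequence are counted but not returned).
    """
    reads: List[UnmappedRead] = []
    n_unmapped = 0
    with pysam.AlignmentFile(str(alignment_path), check_sq=False) as af:
        for rec in af.fetch(until_eof=True):
            if not rec.is_unmapped:
                continue
            n_unmapped += 1
            seq = rec.query_sequence
            if not seq:
                continue
            if rec.is_paired:
                mate = 1 if rec.is_read1 else 2
            else:
                mate = 0
            reads.append(UnmappedRead(rec.query_name, seq.upper(), mate))
    return reads, n_unmapped


def make_anchors(
    read: UnmappedRead, anchor_len: int = DEFAULT_ANCHOR_LEN
) -> Optional[Tuple[str, str]]:
    """Terminal anchors of a read: (first ``anchor_len`` bases, last ``anchor_len``).

    Reads shorter than two anchors cannot carry two independent terminal
    anchors and are skipped (None).
    """
    if len(read.sequence) < 2 * anchor_len:
        return None
    return read.sequence[:anchor_len], read.sequence[-anchor_len:]


class KmerIndex:
    """Exact-match index of every k-mer on the genome's forward strand.

    Minus-strand occurrences of a query are found by looking up its reverse
    complement.  k-mers containing N are not indexed (N matches nothing).
    """

    def __init__(self, genome: Genome, k: int = DEFAULT_ANCHOR_LEN):
        self.genome = genome
        self.k = k
        index: Dict[str, List[Tuple[str, int]]] = defaultdict(list)
        for chrom in sorted(genome.sequences):
            seq = genome.sequences[chrom]
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue
                index[kmer].append((chrom, i + 1))
        self._index = dict(index)

    def lookup(self, kmer: str) -> List[Tuple[str, int]]:
        return self._index.get(kmer, [])


def align_anchor(
    anchor: str, index: KmerIndex, which_end: str = "five_prime"
) -> List[AnchorAlignment]:
    """All exact genomic occurrences of ``anchor`` on both strands.

    Results are deterministically ordered by (chrom, start, strand).
    """
    if "N" in anchor or len(anchor) != index.k:
        return []
    k = index.k
    hits = [
        AnchorAlignment(chrom, pos, pos + k - 1, "+", which_end)
        for chrom, pos in index.lookup(anchor)
    ]
    rc = reverse_complement(anchor)
    if rc != anchor:  # a revcomp-palindromic anchor occupies both strands at once
        hits += [
            AnchorAlignment(chrom, pos, pos + k - 1, "-", which_end)
            for chrom, pos in index.lookup(rc)
        ]
    hits.sort(key=lambda a: (a.chrom, a.start, a.strand))
    return hits


def detect_head_to_tail(
    five_alns: List[AnchorAlignment],
    three_alns: List[AnchorAlignment],
    max_span: int = DEFAULT_MAX_SPAN,
    read_id: str = "",
) -> List[CandidateSeed]:
    """Keep anchor pairs in back-splice (reversed genomic) order.

    Both anchors must map uniquely; pairs on different chromosomes or strands,
    collinear pairs, and pairs implying a genomic span above ``max_span`` give
    no seed.  On '+' the read-5' (head) anchor must lie strictly downstream of
    the read-3' (tail) anchor; mirrored on '-'.
    """
    if len(five_alns) != 1 or len(three_alns) != 1:
        return []
    five, three = five_alns[0], three_alns[0]
    if five.chrom != three.chrom or five.strand != three.strand:
        return []
    if five.strand == "+":
        ordered = five.start > three.end
        span = five.end - three.start + 1
    else:
        ordered = three.start > five.end
        span = three.end - five.start + 1
    if not ordered or span > max_span:
        return []
    return [CandidateSeed(read_id, five.chrom, five.strand, five, three)]


def refine_breakpoint(
    seed: CandidateSeed,
    read: UnmappedRead,
    genome: Genome,
    anchor_len: int = DEFAULT_ANCHOR_LEN,
) -> Optional[CircCandidate]:
    """Extend the seed's anchors to an exact, splice-consistent breakpoint.

    Searches breakpoint offsets b (read coordinates, anchors kept intact on
    their own side) such that the first b read bases match the genome ending
    at the circle end e and the remaining bases match starting at the circle
    start s, with zero mismatches, and the canonical acceptor/donor
    dinucleotides flank (s, e).  The smallest qualifying b wins.  Returns None
    when no breakpoint qualifies.
    """
    seq = read.sequence
    n = len(seq)
    if "N" in seq:
        return None
    if seed.strand == "+":
        eff = seq
        left_anchor, right_anchor = seed.head_anchor, seed.tail_anchor
    else:
        # A minus-strand back-splice read is the reverse complement of a
        # plus-strand one over the same genomic interval, with anchor roles
        # swapped.
        eff = reverse_complement(seq)
        left_anchor, right_anchor = seed.tail_anchor, seed.head_anchor
    chrom_seq = genome.sequences[seed.chrom]
    chrom_len = len(chrom_seq)
    up_sig, down_sig = _SIGNALS[seed.strand]
    for b in range(anchor_len, n - anchor_len + 1):
        e = left_anchor.start + b - 1
        s = right_anchor.end - (n - b) + 1
        if not (3 <= s < e <= chrom_len - 2):
            continue
        if chrom_seq[left_anchor.start - 1 : e] != eff[:b]:
            continue
        if chrom_seq[s - 1 : right_anchor.end] != eff[b:]:
            continue
        if chrom_seq[s - 3 : s - 1] != up_sig:
            continue
        if chrom_seq[e : e + 2] != down_sig:
            continue
        return CircCandidate(
            GenomicInterval(seed.chrom, s, e, seed.strand),
            supporting_read_ids={seed.read_id},
            splice_signal=True,
        )
    return None


def quantify(candidates: List[CircCandidate]) -> List[CircCandidate]:
    """Merge candidates sharing (chrom, start, end, strand); union read ids.

    A read id supports a junction once even if both mates hit it.  Output is
    sorted by coordinate, so quantify is idempotent and order-independent.
    """
    merged: Dict[Tuple[str, int, int, str], CircCandidate] = {}
    for cand in candidates:
        existing = merged.get(cand.key)
        if existing is None:
            merged[cand.key] = CircCandidate(
                cand.interval, set(cand.supporting_read_ids), cand.splice_signal
            )
        else:
            existing.supporting_read_ids |= cand.supporting_read_ids
    return [merged[k] for k in sorted(merged)]


def detect_sample(
    reads: List[UnmappedRead],
    genome: Genome,
    anchor_len: int = DEFAULT_ANCHOR_LEN,
    max_span: int = DEFAULT_MAX_SPAN,
    index: Optional[KmerIndex] = None,
) -> Tuple[List[CircCandidate], Counter]:
    """Run the full per-read detection over a sample's unmapped reads.

    Returns quantified candidates plus per-category read accounting
    (short, n_containing, not_unique, no_seed, no_breakpoint, supporting).
    """
    if index is None or index.k != anchor_len:
        index = KmerIndex(genome, anchor_len)
    stats: Counter = Counter()
    raw: List[CircCandidate] = []
    for read in reads:
        anchors = make_anchors(read, anchor_len)
        if anchors is None:
            stats["short"] += 1
            continue
        five_seq, three_seq = anchors
        if "N" in five_seq or "N" in three_seq:
            stats["n_containing"] += 1
            continue
        five_alns = align_anchor(five_seq, index, "five_prime")
        three_alns = align_anchor(three_seq, index, "three_prime")
        if len(five_alns) != 1 or len(three_alns) != 1:
            stats["not_unique"] += 1
            continue
        seeds = detect_head_to_tail(five_alns, three_alns, max_span, read.read_id)
        if not seeds:
            stats["no_seed"] += 1
            continue
        cand = refine_breakpoint(seeds[0], read, genome, anchor_len)
        if cand is None:
            stats["no_breakpoint"] += 1
            continue
        stats["supporting"] += 1
        raw.append(cand)
    for category, count in sorted(stats.items()):
        logger.info("detect: %s reads in category %s", count, category)
    return quantify(raw), stats
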