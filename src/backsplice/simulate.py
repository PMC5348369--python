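"""Deterministic synthetic fixtures: genome, gene models, planted circRNAs,
back-splice reads, and cohorts.

The generator plants circRNAs into a random genome by writing the canonical
splice dinucleotides at each circle's boundaries (AG immediately upstream of
the start and GT immediately downstream of the end on '+'; AC/CT in genome
letters on '-') and emits 50-nt reads that either span the back-splice fusion
or are plain genomic substrings.  Planted junction flanks are verified unique
genome-wide (unless a duplication is explicitly requested to exercise the
uniqueness filter), and the bases adjacent to each junction are chosen so the
breakpoint cannot slide: the base at the circle start never equals the base
just past the circle end, and vice versa, so exactly one breakpoint offset is
consistent with each read.

Cohort simulation draws per-sample proliferation scores, builds an 11-gene
expression matrix whose per-sample mean z-score reproduces those scores by
construction, and draws circRNA counts with a configurable within-group
Pearson correlation to the score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import pysam

from .annotate import CircRecord
from .cohort import PROLIFERATION_GENES, CohortTable, ProliferationPanel
from .filters import count_genome_occurrences
from .reference import GeneModel, Genome, GenomicInterval, Exon, reverse_complement
from .report import SampleResult

__all__ = [
    "PlantedCircle",
    "TruthSet",
    "make_genome",
    "plant_circles",
    "simulate_cohort",
    "simulate_reads",
    "write_truth",
]

BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class PlantedCircle:
    interval: GenomicInterval
    n_reads: int
    expected_gene_class: str = "unannotated"
    expected_gene_names: Tuple[str, ...] = ()
    expected_boundary_class: str = "other"


@dataclass
class TruthSet:
    circles: List[PlantedCircle]
    genes: List[GeneModel] = field(default_factory=list)
    seed: int = 0
    duplicated_circle: Optional[int] = None  # index whose head flank is duplicated


def make_genome(
    seed: int, n_chroms: int = 2, chrom_len: int = 100_000, gc: float = 0.41
) -> Genome:
    """Random i.i.d. genome at the requested GC content, deterministic in seed."""
    if chrom_len < 1_000:
        raise ValueError("chrom_len must be >= 1000")
    if not 0 <= gc <= 1:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    sequences = {}
    for i in range(n_chroms):
        draw = rng.choice(BASES, size=chrom_len, p=p)
        sequences[f"chr{i + 1}"] = draw.tobytes().decode()
    return Genome(sequences)


_SIGNALS = {"+": ("AG", "GT"), "-": ("AC", "CT")}


def _place_intervals(
    rng: np.random.Generator,
    genome: Genome,
    n: int,
    span_range: Tuple[int, int],
    margin: int,
    pad: int,
    occupied: Optional[Dict[str, List[Tuple[int, int]]]] = None,
) -> List[Tuple[str, int, int]]:
    chroms = sorted(genome.sequences)
    lengths = genome.lengths
    if occupied is None:
        occupied = {c: [] for c in chroms}
    placed = []
    for _ in range(n):
        span = int(rng.integers(span_range[0], span_range[1] + 1))
        for _attempt in range(2_000):
            chrom = chroms[int(rng.integers(len(chroms)))]
            hi = lengths[chrom] - margin - span
            if hi <= margin:
                continue
            start = int(rng.integers(margin, hi + 1))
            end = start + span - 1
            if all(
                end + pad < s or start - pad > e for s, e in occupied[chrom]
            ):
                occupied[chrom].append((start, end))
                placed.append((chrom, start, end))
                break
        else:
            raise RuntimeError("could not place all circles; genome too small")
    return placed


def plant_circles(
    genome: Genome,
    n: int,
    span_range: Tuple[int, int] = (60, 5_000),
    strand_mix: float = 0.5,
    support_range: Tuple[int, int] = (5, 20),
    seed: int = 0,
    duplicate_flank_of: Optional[int] = None,
    flank_len: int = 50,
    with_genes: bool = True,
) -> Tuple[Genome, TruthSet]:
    """Plant ``n`` circRNAs with canonical splice signals into a genome copy.

    Each circle gets a support count drawn from ``support_range`` and, when
    ``with_genes`` is set, a gene-model context cycling through the four
    annotation categories (intra-gene exon-exon boundary, intra-gene within
    exon, inter-gene, unannotated).  ``duplicate_flank_of`` copies that
    circle's head flank to another location so the uniqueness filter removes
    exactly that circle.
    """
    if span_range[0] < 6:
        raise ValueError("span_range minimum conflicts with the size-filter domain (6)")
    rng = np.random.default_rng(seed)
    sequences = {c: bytearray(s, "ascii") for c, s in genome.sequences.items()}
    margin = flank_len + 300
    pad = 2 * flank_len + 700  # room for gene context without overlap
    occupied: Dict[str, List[Tuple[int, int]]] = {c: [] for c in genome.sequences}
    placed = _place_intervals(rng, genome, n, span_range, margin, pad, occupied)
    non_g = b"ACT"

    circles: List[PlantedCircle] = []
    genes: List[GeneModel] = []
    categories = ["exon_exon_boundary", "within_exon", "inter_gene", "unannotated"]
    for i, (chrom, start, end) in enumerate(placed):
        strand = "-" if rng.random() < strand_mix else "+"
        up_sig, down_sig = _SIGNALS[strand]
        buf = sequences[chrom]
        buf[start - 3 : start - 1] = up_sig.encode()
        buf[end : end + 2] = down_sig.encode()
        # anti-slide bases: start base must differ from the base after the end
        # signal's first letter and vice versa (both signals start with the
        # same letter per strand, so one excluded letter suffices)
        excluded = down_sig[0]
        choices = bytes(b for b in b"ACGT" if chr(b) != excluded)
        buf[start - 1] = choices[int(rng.integers(len(choices)))]
        buf[end - 1] = choices[int(rng.integers(len(choices)))]
        n_reads = int(rng.integers(support_range[0], support_range[1] + 1))
        category = categories[i % len(categories)] if with_genes else "none"
        expected_gene_class, expected_names, expected_boundary, new_genes = _gene_context(
            chrom, start, end, strand, category, i, genome.lengths[chrom]
        )
        genes.extend(new_genes)
        circles.append(
            PlantedCircle(
                GenomicInterval(chrom, start, end, strand),
                n_reads,
                expected_gene_class,
                expected_names,
                expected_boundary,
            )
        )

    duplicated = None
    if duplicate_flank_of is not None:
        target = circles[duplicate_flank_of]
        iv = target.interval
        flank = bytes(
            sequences[iv.chrom][iv.start - 1 : iv.start - 1 + flank_len]
        ).decode()
        chrom, start, end = _place_intervals(
            rng, genome, 1, (flank_len, flank_len), margin, pad, occupied
        )[0]
        sequences[chrom][start - 1 : start - 1 + flank_len] = flank.encode()
        duplicated = duplicate_flank_of

    out = Genome({c: bytes(b).decode() for c, b in sequences.items()})
    for i, circle in enumerate(circles):
        iv = circle.interval
        head = out.fetch(GenomicInterval(iv.chrom, iv.start, iv.start + flank_len - 1))
        tail = out.fetch(GenomicInterval(iv.chrom, iv.end - flank_len + 1, iv.end))
        expect_head = 2 if duplicated == i else 1
        if (
            count_genome_occurrences(out, head) != expect_head
            or count_genome_occurrences(out, tail) != 1
        ):
            raise RuntimeError(
                f"planted flank of circle {i} is not unique; re-seed the generator"
            )
    return out, TruthSet(circles, genes, seed, duplicated)


def _gene_context(chrom, start, end, strand, category, i, chrom_len):
    """Build gene models realizing one annotation category around a circle."""
    span = end - start + 1
    gid = lambda suffix: f"GENE{i:03d}{suffix}"
    if category == "exon_exon_boundary":
        exon_len = min(30, span // 2 - 1)
        g = GeneModel(
            gid("A"),
            gid("A"),
            GenomicInterval(chrom, max(1, start - 200), min(chrom_len, end + 200), strand),
            [],
        )
        g.exons = [
            Exon(GenomicInterval(chrom, start, start + exon_len - 1, strand), 1),
            Exon(GenomicInterval(chrom, end - exon_len + 1, end, strand), 2),
        ]
        return "intra_gene", (gid("A"),), "exon_exon_boundary", [g]
    if category == "within_exon":
        g = GeneModel(
            gid("A"),
            gid("A"),
            GenomicInterval(chrom, max(1, start - 200), min(chrom_len, end + 200), strand),
            [],
        )
        g.exons = [Exon(GenomicInterval(chrom, start - 10, end + 10, strand), 1)]
        return "intra_gene", (gid("A"),), "within_exon", [g]
    if category == "inter_gene":
        reach = max(10, min(span // 3, 500))
        ga = GeneModel(
            gid("A"),
            gid("A"),
            GenomicInterval(chrom, max(1, start - 150), start + reach, strand),
            [],
        )
        ga.exons = [Exon(ga.span, 1)]
        gb = GeneModel(
            gid("B"),
            gid("B"),
            GenomicInterval(chrom, end - reach, min(chrom_len, end + 150), strand),
            [],
        )
        gb.exons = [Exon(gb.span, 1)]
        return "inter_gene", (gid("A"), gid("B")), "within_exon", [ga, gb]
    return "unannotated", (), "other", []


def simulate_reads(
    genome: Genome,
    truth: TruthSet,
    read_len: int = 50,
    linear_n: int = 0,
    seed: int = 0,
    anchor_len: int = 20,
    error_rate: float = 0.0,
    out_sam: Optional[Union[str, Path]] = None,
) -> List[Tuple[str, str]]:
    """Emit unmapped reads: back-splice reads for each planted circle plus
    ``linear_n`` plain genomic substrings (which detection must reject).

    Back-splice reads place the fusion at a uniform interior offset at least
    ``anchor_len`` from both read ends so both terminal anchors map.  Returns
    (read_id, sequence) pairs; with ``out_sam`` also writes them as unmapped
    SAM records.  Deterministic in ``seed``.
    """
    if read_len < 2 * anchor_len:
        raise ValueError("read_len must be at least twice the anchor length")
    rng = np.random.default_rng(seed)
    reads: List[Tuple[str, str]] = []
    for ci, circle in enumerate(truth.circles):
        iv = circle.interval
        if len(iv) < read_len:
            raise ValueError(
                f"circle {ci} span {len(iv)} is shorter than the read length; "
                "its junction reads would wrap around"
            )
        chrom_seq = genome.sequences[iv.chrom]
        for ri in range(circle.n_reads):
            b = int(rng.integers(anchor_len, read_len - anchor_len + 1))
            tail_part = chrom_seq[iv.end - b : iv.end]
            head_part = chrom_seq[iv.start - 1 : iv.start - 1 + read_len - b]
            seq = tail_part + head_part
            if iv.strand == "-":
                seq = reverse_complement(seq)
            reads.append((f"circ{ci}_read{ri}", seq))
    for li in range(linear_n):
        chroms = sorted(genome.sequences)
        chrom = chroms[int(rng.integers(len(chroms)))]
        chrom_seq = genome.sequences[chrom]
        pos = int(rng.integers(0, len(chrom_seq) - read_len + 1))
        seq = chrom_seq[pos : pos + read_len]
        if rng.random() < 0.5:
            seq = reverse_complement(seq)
        reads.append((f"lin{li}", seq))
    if error_rate > 0:
        mutated = []
        for rid, seq in reads:
            arr = bytearray(seq, "ascii")
            for j in range(len(arr)):
                if rng.random() < error_rate:
                    arr[j] = BASES[int(rng.integers(4))][0]
            mutated.append((rid, bytes(arr).decode()))
        reads = mutated
    if out_sam is not None:
        _write_sam(reads, genome, out_sam)
    return reads


def _write_sam(reads, genome: Genome, path: Union[str, Path]) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [
            {"SN": chrom, "LN": length}
            for chrom, length in sorted(genome.lengths.items())
        ],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rid, seq in reads:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = rid
            rec.flag = 4  # unmapped, single-end
            rec.query_sequence = seq
            rec.mapping_quality = 0
            out.write(rec)


def write_truth(truth: TruthSet, path: Union[str, Path]) -> None:
    rows = [
        {
            "chrom": c.interval.chrom,
            "start": c.interval.start,
            "end": c.interval.end,
            "strand": c.interval.strand,
            "n_reads": c.n_reads,
            "expected_gene_class": c.expected_gene_class,
            "expected_gene_names": ",".join(c.expected_gene_names),
            "expected_boundary_class": c.expected_boundary_class,
        }
        for c in truth.circles
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def simulate_cohort(
    n_tumor: int,
    n_normal: int,
    count_model: Optional[dict] = None,
    target_r: float = -0.22,
    seed: int = 0,
) -> Tuple[CohortTable, ProliferationPanel]:
    """Simulate a labeled cohort with a chosen within-group correlation
    between circRNA count and proliferation score.

    Per-sample proliferation scores are standard-normal draws, empirically
    standardized so the 11-gene expression matrix (a positive linear
    transform of the score per gene) reproduces them exactly as mean
    z-scores.  Counts are ``round(mean_g + b * score + eps)`` with
    ``b = target_r * sd`` and residual sd ``sd * sqrt(1 - target_r^2)``, so
    the population Pearson correlation within each group equals ``target_r``.
    Defaults emulate a breast-tissue cohort: tumor mean 18 and
    normal-adjacent mean 25 circles per sample, sd 8, unmapped libraries of
    5-22 million reads.
    """
    if not -1 <= target_r <= 1:
        raise ValueError("target_r must lie in [-1, 1]")
    if n_tumor < 3 or n_normal < 3:
        raise ValueError("need at least 3 samples per group")
    model = {"tumor_mean": 18.0, "normal_mean": 25.0, "sd": 8.0}
    if count_model:
        model.update(count_model)
    rng = np.random.default_rng(seed)
    n = n_tumor + n_normal
    ids = [f"T{i:04d}" for i in range(n_tumor)] + [f"N{i:04d}" for i in range(n_normal)]
    groups = ["tumor"] * n_tumor + ["normal_adjacent"] * n_normal
    scores = rng.normal(size=n)
    scores = (scores - scores.mean()) / scores.std(ddof=0)
    b = target_r * model["sd"]
    resid_sd = model["sd"] * math.sqrt(1 - target_r**2)
    means = np.where(
        np.array(groups) == "tumor", model["tumor_mean"], model["normal_mean"]
    )
    counts = np.rint(means + b * scores + rng.normal(scale=resid_sd, size=n)).astype(int)
    counts = np.clip(counts, 0, None)

    # coordinate pool shared across samples so unique/recurrence/containment
    # analyses are non-trivial
    pool = _coordinate_pool(rng, size=max(400, counts.max() + 50))
    samples = []
    for i, sid in enumerate(ids):
        chosen = rng.choice(len(pool), size=min(counts[i], len(pool)), replace=False)
        records = [
            CircRecord(
                chrom=pool[j][0],
                start=pool[j][1],
                end=pool[j][2],
                strand="+",
                n_reads=int(rng.integers(5, 21)),
                size=pool[j][2] - pool[j][1] + 1,
                gene_class="unannotated",
                gene_names=(),
                boundary_class="other",
            )
            for j in sorted(int(c) for c in chosen)
        ]
        unmapped = int(rng.integers(5_000_000, 22_000_001))
        samples.append(SampleResult(sid, records, unmapped))
    labels = dict(zip(ids, groups))
    pairs = [
        (f"T{i:04d}", f"N{i:04d}") for i in range(min(n_tumor, n_normal))
    ]
    cohort = CohortTable(samples, labels, pairs)

    intercepts = rng.uniform(5, 10, size=len(PROLIFERATION_GENES))
    slopes = rng.uniform(0.5, 2.0, size=len(PROLIFERATION_GENES))
    expr = pd.DataFrame(
        intercepts[:, None] + slopes[:, None] * scores[None, :],
        index=list(PROLIFERATION_GENES),
        columns=ids,
    )
    panel = ProliferationPanel(expr)
    return cohort, panel


def _coordinate_pool(rng: np.random.Generator, size: int) -> List[Tuple[str, int, int]]:
    pool = []
    for _ in range(size):
        chrom = f"chr{int(rng.integers(1, 23))}"
        start = int(rng.integers(10_000, 5_000_000))
        span = int(rng.integers(60, 5_000))
        pool.append((chrom, start, start + span - 1))
    return sorted(set(pool))
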