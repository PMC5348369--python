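"""Candidate filtering: expression, genomic size, and genomic uniqueness.

Three per-candidate predicates clean the quantified junction list:

* expression — at least ``min_reads`` junction-spanning reads (default 5);
* genomic size — head-to-tail inclusive span of at least ``min_size`` bases
  (default 6);
* uniqueness — the flanking sequence at each junction boundary must occur at
  exactly one genomic location, eliminating calls from repetitive regions.

Because each predicate looks at one candidate at a time, the filters commute
and each output is a subset of its input.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import List, Optional, Union

import yaml

from .detect import CircCandidate
from .reference import Genome, GenomicInterval, reverse_complement

__all__ = [
    "FilterConfig",
    "count_genome_occurrences",
    "expression_filter",
    "genomic_size",
    "size_filter",
    "uniqueness_filter",
]

DEFAULT_MIN_READS = 5
DEFAULT_MIN_SIZE = 6
DEFAULT_FLANK_LEN = 50


@dataclass
class FilterConfig:
    min_reads: int = DEFAULT_MIN_READS
    min_size: int = DEFAULT_MIN_SIZE
    flank_len: int = DEFAULT_FLANK_LEN
    uniqueness_mode: str = "internal"  # or "external_blat"

    def __post_init__(self) -> None:
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")
        if self.flank_len < 20:
            raise ValueError("flank_len must be >= 20")
        if self.uniqueness_mode not in ("internal", "external_blat"):
            raise ValueError(f"unknown uniqueness_mode {self.uniqueness_mode!r}")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "FilterConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        return cls(**known)

    def to_dict(self) -> dict:
        return asdict(self)


def expression_filter(
    candidates: List[CircCandidate], min_reads: int = DEFAULT_MIN_READS
) -> List[CircCandidate]:
    """Retain candidates with at least ``min_reads`` supporting reads."""
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    return [c for c in candidates if c.support >= min_reads]


def genomic_size(candidate: CircCandidate) -> int:
    """Head-to-tail genomic distance as the inclusive span end - start + 1."""
    return len(candidate.interval)


def size_filter(
    candidates: List[CircCandidate], min_size: int = DEFAULT_MIN_SIZE
) -> List[CircCandidate]:
    """Discard candidates with genomic size below ``min_size`` bases."""
    return [c for c in candidates if genomic_size(c) >= min_size]


def count_genome_occurrences(genome: Genome, pattern: str) -> int:
    """Exact occurrences of ``pattern`` genome-wide, both strands, overlapping.

    A revcomp-palindromic pattern occupies both strands at the same position
    and is counted once there.
    """
    queries = [pattern]
    rc = reverse_complement(pattern)
    if rc != pattern:
        queries.append(rc)
    total = 0
    for seq in genome.sequences.values():
        for query in queries:
            pos = seq.find(query)
            while pos != -1:
                total += 1
                pos = seq.find(query, pos + 1)
    return total


def _flanks(
    candidate: CircCandidate, genome: Genome, flank_len: int
) -> tuple:
    iv = candidate.interval
    chrom_len = len(genome.sequences[iv.chrom])
    head = GenomicInterval(iv.chrom, iv.start, min(iv.start + flank_len - 1, chrom_len))
    tail = GenomicInterval(iv.chrom, max(iv.end - flank_len + 1, 1), iv.end)
    return genome.fetch(head), genome.fetch(tail)


def uniqueness_filter(
    candidates: List[CircCandidate],
    genome: Genome,
    flank_len: int = DEFAULT_FLANK_LEN,
    mode: str = "internal",
    genome_fasta: Optional[Union[str, Path]] = None,
    blat_executable: str = "blat",
) -> List[CircCandidate]:
    """Retain candidates whose junction boundaries are unique in the genome.

    The head flank (``flank_len`` bases starting at the circle start) and the
    tail flank (``flank_len`` bases ending at the circle end), truncated at
    chromosome edges, must each occur at exactly one genomic location.  The
    default ``internal`` mode counts exact occurrences on both strands;
    ``external_blat`` shells out to a BLAT executable and requires a single
    best hit per flank.
    """
    if mode == "internal":
        kept = []
        for cand in candidates:
            head_seq, tail_seq = _flanks(cand, genome, flank_len)
            if (
                count_genome_occurrences(genome, head_seq) == 1
                and count_genome_occurrences(genome, tail_seq) == 1
            ):
                kept.append(cand)
        return kept
    if mode == "external_blat":
        return _uniqueness_blat(
            candidates, genome, flank_len, genome_fasta, blat_executable
        )
    raise ValueError(f"unknown uniqueness mode {mode!r}")


def _uniqueness_blat(candidates, genome, flank_len, genome_fasta, blat_executable):
    if shutil.which(blat_executable) is None:
        raise EnvironmentError(
            f"uniqueness_mode=external_blat but {blat_executable!r} is not on PATH"
        )
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        if genome_fasta is None:
            genome_fasta = tmp / "genome.fa"
            with open(genome_fasta, "w") as fh:
                for chrom, seq in genome.sequences.items():
                    fh.write(f">{chrom}\n{seq}\n")
        query_fa = tmp / "flanks.fa"
        with open(query_fa, "w") as fh:
            for i, cand in enumerate(candidates):
                head_seq, tail_seq = _flanks(cand, genome, flank_len)
                fh.write(f">c{i}_head\n{head_seq}\n>c{i}_tail\n{tail_seq}\n")
        psl = tmp / "out.psl"
        subprocess.run(
            [blat_executable, str(genome_fasta), str(query_fa), str(psl), "-noHead"],
            check=True,
            capture_output=True,
        )
        hit_counts: dict = {}
        with open(psl) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 10:
                    continue
                qname = parts[9]
                hit_counts[qname] = hit_counts.get(qname, 0) + 1
        kept = []
        for i, cand in enumerate(candidates):
            if hit_counts.get(f"c{i}_head", 0) == 1 and hit_counts.get(f"c{i}_tail", 0) == 1:
                kept.append(cand)
        return kept
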