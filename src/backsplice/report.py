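"""Per-sample outputs: the circRNA quantification report and junction FASTA.

The report is a tab-separated table with one row per final circRNA carrying
its location, supporting-read count, genomic size and annotations.  The
junction FASTA holds, for each circle, a fixed-length sequence centered on
the back-splice fusion: the last 25 genomic bases of the circle concatenated
with its first 25 (by default), so the fusion sits between positions 25 and
26.  Circles smaller than half the target length contribute what they have
from each side, without wrap-around.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Union

import pandas as pd

from .annotate import CircRecord
from .filters import FilterConfig
from .reference import Genome, GenomicInterval, reverse_complement

__all__ = [
    "REPORT_COLUMNS",
    "SampleResult",
    "junction_fasta",
    "read_report",
    "write_report",
]

logger = logging.getLogger(__name__)

REPORT_COLUMNS = [
    "chrom",
    "start",
    "end",
    "strand",
    "n_supporting_reads",
    "genomic_size",
    "gene_class",
    "gene_names",
    "boundary_class",
]


@dataclass
class SampleResult:
    sample_id: str
    records: List[CircRecord]
    unmapped_read_count: int = 0
    parameters: FilterConfig = field(default_factory=FilterConfig)

    def __post_init__(self) -> None:
        self.records = sorted(self.records, key=lambda r: (r.chrom, r.start, r.end))


def write_report(result: SampleResult, path: Union[str, Path]) -> None:
    """Write the sample's circRNA quantification report as TSV."""
    rows = [
        {
            "chrom": r.chrom,
            "start": r.start,
            "end": r.end,
            "strand": r.strand,
            "n_supporting_reads": r.n_reads,
            "genomic_size": r.size,
            "gene_class": r.gene_class,
            "gene_names": ",".join(r.gene_names),
            "boundary_class": r.boundary_class,
        }
        for r in result.records
    ]
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_report(
    path: Union[str, Path], sample_id: str = None, unmapped_read_count: int = 0
) -> SampleResult:
    """Load a quantification report back into a SampleResult."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_names": str})
    records = []
    for row in df.itertuples(index=False):
        names = () if pd.isna(row.gene_names) or row.gene_names == "" else tuple(
            str(row.gene_names).split(",")
        )
        records.append(
            CircRecord(
                chrom=str(row.chrom),
                start=int(row.start),
                end=int(row.end),
                strand=str(row.strand),
                n_reads=int(row.n_supporting_reads),
                size=int(row.genomic_size),
                gene_class=str(row.gene_class),
                gene_names=names,
                boundary_class=str(row.boundary_class),
            )
        )
    if sample_id is None:
        sample_id = Path(path).stem.replace(".circs", "")
    return SampleResult(sample_id, records, unmapped_read_count)


def junction_sequence(
    record: CircRecord, genome: Genome, total_len: int = 50
) -> str:
    """The fused-junction sequence for one circle (tail side + head side)."""
    if total_len % 2 != 0:
        raise ValueError("total_len must be even so the fusion can be centered")
    half = total_len // 2
    k = min(record.size, half)
    tail = genome.fetch(GenomicInterval(record.chrom, record.end - k + 1, record.end))
    head = genome.fetch(GenomicInterval(record.chrom, record.start, record.start + k - 1))
    seq = tail + head
    if record.strand == "-":
        seq = reverse_complement(seq)
    if k < half:
        logger.info(
            "junction %s:%d-%d spans only %d bases; sequence truncated to %d",
            record.chrom, record.start, record.end, record.size, len(seq),
        )
    return seq


def junction_fasta(
    result: SampleResult,
    genome: Genome,
    path: Union[str, Path],
    total_len: int = 50,
) -> None:
    """Write the fused-junction FASTA for all circles in a sample.

    Record ids are ``chrom:start-end:strand``; sequences are wrapped at 60
    columns.  Minus-strand circles are reverse-complemented so the sequence
    reads in transcript orientation.
    """
    if total_len % 2 != 0:
        raise ValueError("total_len must be even so the fusion can be centered")
    with open(path, "w") as fh:
        for record in result.records:
            seq = junction_sequence(record, genome, total_len)
            fh.write(f">{record.chrom}:{record.start}-{record.end}:{record.strand}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
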