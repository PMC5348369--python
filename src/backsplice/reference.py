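"""Reference genome and gene-model handling.

All coordinates in this package are 1-based and inclusive on both ends, the
convention used when loci are printed as e.g. ``chr14:102,466,325-102,500,789``.
Conversion to 0-based half-open happens only at file-format boundaries
(SAM, Python string slicing).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Union

from Bio import SeqIO

__all__ = [
    "CoordinateError",
    "Exon",
    "FastaParseError",
    "GeneModel",
    "Genome",
    "GenomicInterval",
    "GtfParseError",
    "fetch",
    "load_gene_models",
    "load_genome",
    "reverse_complement",
    "write_gtf",
]

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FastaParseError(ValueError):
    """Raised when a genome FASTA cannot be loaded."""


class GtfParseError(ValueError):
    """Raised when a GTF file cannot be parsed; message carries the line number."""


class CoordinateError(ValueError):
    """Raised when an interval falls outside its chromosome."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of an upper-case A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based, inclusive genomic interval with strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (1 <= self.start <= self.end):
            raise CoordinateError(
                f"require 1 <= start <= end, got {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass
class Genome:
    """An in-memory genome: chromosome name -> upper-case sequence."""

    sequences: Dict[str, str]

    @property
    def lengths(self) -> Dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def fetch(self, iv: GenomicInterval) -> str:
        if iv.chrom not in self.sequences:
            raise CoordinateError(f"unknown chromosome {iv.chrom!r}")
        chrom_len = len(self.sequences[iv.chrom])
        if iv.end > chrom_len:
            raise CoordinateError(
                f"{iv.chrom}:{iv.start}-{iv.end} exceeds chromosome length {chrom_len}"
            )
        seq = self.sequences[iv.chrom][iv.start - 1 : iv.end]
        if iv.strand == "-":
            seq = reverse_complement(seq)
        return seq


def fetch(genome: Genome, iv: GenomicInterval) -> str:
    """Extract the sequence of ``iv``; '-' strand returns the reverse complement."""
    return genome.fetch(iv)


def load_genome(fasta_path: Union[str, Path]) -> Genome:
    """Load a FASTA genome into memory.

    Sequences are upper-cased; bases outside A/C/G/T/N and duplicate record
    names raise :class:`FastaParseError` naming the offending record.
    """
    sequences: Dict[str, str] = {}
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        name = record.id
        if name in sequences:
            raise FastaParseError(f"duplicate FASTA record name {name!r}")
        seq = str(record.seq).upper()
        bad = set(seq) - VALID_BASES
        if bad:
            raise FastaParseError(
                f"record {name!r} contains invalid characters {sorted(bad)}"
            )
        sequences[name] = seq
    return Genome(sequences)


@dataclass(frozen=True)
class Exon:
    interval: GenomicInterval
    index: int  # ordinal within the gene, 1-based, in coordinate order


@dataclass
class GeneModel:
    gene_id: str
    gene_name: str
    span: GenomicInterval
    exons: List[Exon] = field(default_factory=list)


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr_field: str) -> Dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def load_gene_models(gtf_path: Union[str, Path]) -> List[GeneModel]:
    """Load gene models from an Ensembl-dialect GTF.

    Only ``gene`` and ``exon`` features are read; other feature types are
    ignored.  Exons are deduplicated by coordinate across transcripts.  A gene
    with exon lines but no gene line gets a span equal to the exon hull.
    """
    raw: Dict[str, dict] = {}
    order: List[str] = []
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise GtfParseError(
                    f"line {lineno}: expected 9 tab-separated fields, got {len(parts)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = parts
            if feature not in ("gene", "exon"):
                continue
            attributes = _parse_attributes(attrs)
            gene_id = attributes.get("gene_id")
            if not gene_id:
                raise GtfParseError(f"line {lineno}: missing gene_id attribute")
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise GtfParseError(f"line {lineno}: non-integer coordinates") from exc
            if strand not in ("+", "-"):
                strand = "+"
            entry = raw.get(gene_id)
            if entry is None:
                entry = {
                    "chrom": chrom,
                    "strand": strand,
                    "name": attributes.get("gene_name", gene_id),
                    "span": None,
                    "exons": set(),
                }
                raw[gene_id] = entry
                order.append(gene_id)
            if "gene_name" in attributes:
                entry["name"] = attributes["gene_name"]
            if feature == "gene":
                entry["span"] = (start, end)
            else:
                entry["exons"].add((start, end))
    models: List[GeneModel] = []
    for gene_id in order:
        entry = raw[gene_id]
        exon_coords = sorted(entry["exons"])
        if entry["span"] is not None:
            span_start, span_end = entry["span"]
        elif exon_coords:
            span_start = min(s for s, _ in exon_coords)
            span_end = max(e for _, e in exon_coords)
        else:
            continue  # a gene with neither span nor exons carries no information
        span = GenomicInterval(entry["chrom"], span_start, span_end, entry["strand"])
        exons = [
            Exon(GenomicInterval(entry["chrom"], s, e, entry["strand"]), i)
            for i, (s, e) in enumerate(exon_coords, start=1)
        ]
        models.append(GeneModel(gene_id, entry["name"], span, exons))
    return models


def write_gtf(gene_models: List[GeneModel], path: Union[str, Path]) -> None:
    """Serialize gene models as Ensembl-dialect GTF (gene + exon features)."""
    with open(path, "w") as fh:
        for gene in gene_models:
            attrs = f'gene_id "{gene.gene_id}"; gene_name "{gene.gene_name}";'
            fh.write(
                "\t".join(
                    [
                        gene.span.chrom,
                        "backsplice",
                        "gene",
                        str(gene.span.start),
                        str(gene.span.end),
                        ".",
                        gene.span.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
            for exon in gene.exons:
                fh.write(
                    "\t".join(
                        [
                            exon.interval.chrom,
                            "backsplice",
                            "exon",
                            str(exon.interval.start),
                            str(exon.interval.end),
                            ".",
                            exon.interval.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )
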