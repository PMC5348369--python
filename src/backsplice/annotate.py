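"""Gene-context and exon-boundary annotation of filtered junctions.

Each final junction is classified by gene context — *intra_gene* (both
boundaries inside one gene), *inter_gene* (two or more genes hit), or
*unannotated* — and by exon-boundary status: *exon_exon_boundary* when the
circle start coincides exactly with an annotated exon start and the circle
end with an exon end (possibly of different exons), *within_exon* when both
boundaries fall strictly inside exons, and *other* for everything else
(intronic or intergenic boundaries).

Annotation is strand-agnostic: the gene models' strand is ignored when
testing overlap, which matches unstranded library preparations where the
transcribed strand of a junction is not observable.  A junction with exactly
one genic boundary is left unannotated (and logged) rather than being forced
into either genic class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Set, Tuple

from intervaltree import IntervalTree

from .detect import CircCandidate
from .filters import genomic_size
from .reference import GeneModel

__all__ = [
    "CircRecord",
    "GeneIndex",
    "annotate_all",
    "classify_exon_boundary",
    "classify_gene_context",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CircRecord:
    """A final, annotated circRNA call as it appears in the sample report."""

    chrom: str
    start: int
    end: int
    strand: str
    n_reads: int
    size: int
    gene_class: str  # intra_gene | inter_gene | unannotated
    gene_names: Tuple[str, ...]
    boundary_class: str  # exon_exon_boundary | within_exon | other

    @property
    def coord(self) -> Tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


class GeneIndex:
    """Interval-tree lookups over gene spans and exons, built once per GTF."""

    def __init__(self, gene_models: List[GeneModel]):
        self.gene_trees: Dict[str, IntervalTree] = {}
        self.exon_trees: Dict[str, IntervalTree] = {}
        self.exon_starts: Dict[str, Set[int]] = {}
        self.exon_ends: Dict[str, Set[int]] = {}
        for gene in gene_models:
            chrom = gene.span.chrom
            # interval trees use half-open ends
            self.gene_trees.setdefault(chrom, IntervalTree()).addi(
                gene.span.start, gene.span.end + 1, gene
            )
            for exon in gene.exons:
                iv = exon.interval
                self.exon_trees.setdefault(chrom, IntervalTree()).addi(
                    iv.start, iv.end + 1, exon
                )
                self.exon_starts.setdefault(chrom, set()).add(iv.start)
                self.exon_ends.setdefault(chrom, set()).add(iv.end)

    def genes_at(self, chrom: str, pos: int) -> List[GeneModel]:
        tree = self.gene_trees.get(chrom)
        if tree is None:
            return []
        return [hit.data for hit in tree.at(pos)]

    def strictly_inside_exon(self, chrom: str, pos: int) -> bool:
        tree = self.exon_trees.get(chrom)
        if tree is None:
            return False
        return any(
            hit.data.interval.start < pos < hit.data.interval.end
            for hit in tree.at(pos)
        )


def _as_index(gene_models) -> GeneIndex:
    return gene_models if isinstance(gene_models, GeneIndex) else GeneIndex(gene_models)


def classify_gene_context(
    candidate: CircCandidate, gene_models
) -> Tuple[str, List[str]]:
    """Classify a junction as intra_gene / inter_gene / unannotated.

    Genes overlapping the start position and genes overlapping the end
    position are collected; one gene containing both ends is intra_gene, two
    or more distinct genes are inter_gene, and no genic hit at either end is
    unannotated.  A single gene covering only one end is logged and left
    unannotated.
    """
    index = _as_index(gene_models)
    iv = candidate.interval
    start_hits = index.genes_at(iv.chrom, iv.start)
    end_hits = index.genes_at(iv.chrom, iv.end)
    union = {g.gene_id: g for g in start_hits + end_hits}
    if not union:
        return "unannotated", []
    if len(union) == 1:
        (gene,) = union.values()
        if gene.span.contains(iv.start) and gene.span.contains(iv.end):
            return "intra_gene", [gene.gene_name]
        logger.info(
            "junction %s:%d-%d has a single genic boundary (%s); left unannotated",
            iv.chrom, iv.start, iv.end, gene.gene_name,
        )
        return "unannotated", []
    return "inter_gene", sorted({g.gene_name for g in union.values()})


def classify_exon_boundary(candidate: CircCandidate, gene_models) -> str:
    """Exon-boundary status of a junction against annotated exons."""
    index = _as_index(gene_models)
    iv = candidate.interval
    if iv.start in index.exon_starts.get(iv.chrom, ()) and iv.end in index.exon_ends.get(
        iv.chrom, ()
    ):
        return "exon_exon_boundary"
    if index.strictly_inside_exon(iv.chrom, iv.start) and index.strictly_inside_exon(
        iv.chrom, iv.end
    ):
        return "within_exon"
    return "other"


def annotate_all(
    candidates: List[CircCandidate], gene_models
) -> List[CircRecord]:
    """Annotate every filtered candidate into a flat report record."""
    index = _as_index(gene_models)
    records = []
    for cand in candidates:
        gene_class, gene_names = classify_gene_context(cand, index)
        boundary = classify_exon_boundary(cand, index)
        iv = cand.interval
        records.append(
            CircRecord(
                chrom=iv.chrom,
                start=iv.start,
                end=iv.end,
                strand=iv.strand,
                n_reads=cand.support,
                size=genomic_size(cand),
                gene_class=gene_class,
                gene_names=tuple(gene_names),
                boundary_class=boundary,
            )
        )
    return records
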