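"""Assign each aptamer hit a genomic context class relative to gene models."""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from riboreg.aptamer_search import AptamerHit
from riboreg.genome_io import GeneModel, Interval, IntronContext, IntronRecord, derive_introns


class ContextClass(str, Enum):
    FIVE_UTR_INTRON = "FIVE_UTR_INTRON"
    INTERNAL_INTRON = "INTERNAL_INTRON"
    THREE_UTR = "THREE_UTR"
    FIVE_UTR_SINGLE_EXON = "FIVE_UTR_SINGLE_EXON"
    FIVE_UTR_EXONIC = "FIVE_UTR_EXONIC"
    INTERGENIC = "INTERGENIC"
    AMBIGUOUS = "AMBIGUOUS"


_INTRON_TO_CONTEXT = {
    IntronContext.FIVE_UTR_INTRON: ContextClass.FIVE_UTR_INTRON,
    IntronContext.INTERNAL_INTRON: ContextClass.INTERNAL_INTRON,
    IntronContext.THREE_UTR_INTRON: ContextClass.THREE_UTR,
}


@dataclass(frozen=True)
class GenomicContext:
    hit_id: str
    gene_id: str | None
    context_class: ContextClass
    containing_intron: IntronRecord | None = None
    distance_to_cds_start: int | None = None


def _cds_start_distance(hit: AptamerHit, gene: GeneModel) -> int | None:
    """Signed transcript-oriented distance from the hit 5' end to CDS start.

    Positive when the CDS start lies downstream (3') of the hit's 5' end in
    the gene's orientation — i.e. the hit is upstream of the coding region.
    """
    sp = gene.cds_span
    if sp is None:
        return None
    if gene.strand == "+":
        return sp.start - hit.interval.start
    return hit.interval.end - sp.end


def locate_hit(hit: AptamerHit, genes: Sequence[GeneModel]) -> GenomicContext:
    """Assign the hit exactly one context class.

    A hit fully inside a derived intron takes the intron's class; a hit fully
    inside a 5'UTR exon is FIVE_UTR_SINGLE_EXON (single-exon gene) or
    FIVE_UTR_EXONIC; inside a 3'UTR exon, THREE_UTR; straddling any feature
    boundary, AMBIGUOUS; overlapping no gene, INTERGENIC.  When several genes
    overlap, the gene whose CDS start is nearest downstream of the hit wins
    (ties broken lexicographically by gene_id).
    """
    iv = hit.interval
    overlapping = [
        g for g in genes if g.seq_id == hit.seq_id and g.span.overlaps(iv)
    ]
    if not overlapping:
        return GenomicContext(hit.hit_id, None, ContextClass.INTERGENIC)

    def rank(g: GeneModel) -> tuple:
        d = _cds_start_distance(hit, g)
        if d is None:
            return (2, 0, g.gene_id)
        if d >= 0:  # CDS start downstream of the hit
            return (0, d, g.gene_id)
        return (1, -d, g.gene_id)

    gene = min(overlapping, key=rank)
    dist = _cds_start_distance(hit, gene)

    for intron in derive_introns(gene):
        if intron.interval.contains(iv):
            return GenomicContext(
                hit.hit_id, gene.gene_id, _INTRON_TO_CONTEXT[intron.context],
                containing_intron=intron, distance_to_cds_start=dist,
            )

    if any(ex.contains(iv) for ex in gene.exons):
        if any(u.contains(iv) for u in gene.utr5):
            cls = (
                ContextClass.FIVE_UTR_SINGLE_EXON
                if len(gene.exons) == 1
                else ContextClass.FIVE_UTR_EXONIC
            )
            return GenomicContext(hit.hit_id, gene.gene_id, cls, distance_to_cds_start=dist)
        if any(u.contains(iv) for u in gene.utr3):
            return GenomicContext(
                hit.hit_id, gene.gene_id, ContextClass.THREE_UTR, distance_to_cds_start=dist
            )
        # fully inside an exon but not inside a single UTR interval (e.g. CDS
        # or spanning a UTR/CDS boundary): no spec'd class -> AMBIGUOUS
        return GenomicContext(
            hit.hit_id, gene.gene_id, ContextClass.AMBIGUOUS, distance_to_cds_start=dist
        )
    # overlaps the gene but straddles an exon/intron or gene boundary
    return GenomicContext(
        hit.hit_id, gene.gene_id, ContextClass.AMBIGUOUS, distance_to_cds_start=dist
    )


def locate_all(hits: Iterable[AptamerHit], genes: Sequence[GeneModel]) -> list[GenomicContext]:
    return [locate_hit(h, genes) for h in hits]


def contexts_to_tsv(contexts: Iterable[GenomicContext]) -> str:
    header = [
        "hit_id", "gene_id", "context_class", "intron_ordinal", "intron_length",
        "distance_to_cds_start",
    ]
    rows = ["\t".join(header)]
    for c in contexts:
        rows.append(
            "\t".join(
                [
                    c.hit_id,
                    c.gene_id or ".",
                    c.context_class.value,
                    str(c.containing_intron.ordinal) if c.containing_intron else ".",
                    str(c.containing_intron.length) if c.containing_intron else ".",
                    str(c.distance_to_cds_start) if c.distance_to_cds_start is not None else ".",
                ]
            )
        )
    return "\n".join(rows) + "\n"
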