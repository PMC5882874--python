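"""Sequence and gene-model I/O with coordinate/strand utilities.

Internal coordinates are 0-based half-open on the forward genomic strand.
External GFF3 follows the standard 1-based inclusive convention; conversion
happens only at the I/O boundary.  All downstream analysis operates on the
transcript (sense) strand: minus-strand genes are handled by extracting
reverse-complemented sequence and then applying identical 5'->3' logic.
"""

from __future__ import annotations

import logging
import tempfile
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_BASES = frozenset("ACGTN")


class FormatError(ValueError):
    """Raised on malformed FASTA/GFF3 input."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


class Interval(NamedTuple):
    """0-based half-open genomic interval."""

    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, other: "Interval") -> bool:
        return self.start <= other.start and other.end <= self.end

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class GenomeRecord:
    seq_id: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise FormatError(
                f"sequence {self.seq_id!r} contains invalid characters: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


class IntronContext(str, Enum):
    FIVE_UTR_INTRON = "FIVE_UTR_INTRON"
    INTERNAL_INTRON = "INTERNAL_INTRON"
    THREE_UTR_INTRON = "THREE_UTR_INTRON"


@dataclass(frozen=True)
class GeneModel:
    """One transcript's exon/CDS/UTR structure in genomic coordinates.

    Multi-isoform genes yield one ``GeneModel`` per mRNA; classification is
    per transcript.
    """

    gene_id: str
    seq_id: str
    strand: str
    exons: tuple[Interval, ...]
    cds: tuple[Interval, ...] = ()
    utr5: tuple[Interval, ...] = ()
    utr3: tuple[Interval, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        for prev, cur in zip(self.exons, self.exons[1:]):
            if cur.start < prev.end:
                raise ValueError(f"gene {self.gene_id}: exons unsorted or overlapping")
        for name, ivals in (("cds", self.cds), ("utr5", self.utr5), ("utr3", self.utr3)):
            for iv in ivals:
                if not any(ex.contains(iv) for ex in self.exons):
                    raise ValueError(
                        f"gene {self.gene_id}: {name} interval {iv} not inside any exon"
                    )

    @property
    def span(self) -> Interval:
        return Interval(self.exons[0].start, self.exons[-1].end)

    @property
    def cds_span(self) -> Interval | None:
        if not self.cds:
            return None
        return Interval(self.cds[0].start, self.cds[-1].end)

    def cds_start_genomic(self) -> int | None:
        """Genomic coordinate of the translation start (strand-aware)."""
        sp = self.cds_span
        if sp is None:
            return None
        return sp.start if self.strand == "+" else sp.end


@dataclass(frozen=True)
class IntronRecord:
    gene_id: str
    ordinal: int  # 1-based, transcript order
    interval: Interval
    context: IntronContext

    @property
    def length(self) -> int:
        return self.interval.length


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a (multi-)FASTA file into :class:`GenomeRecord` objects.

    Sequences are uppercased; U is mapped to T with a logged warning.
    Raises :class:`FormatError` on an empty file or duplicate ids.
    """
    path = Path(path)
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if "U" in seq:
            log.warning("sequence %s contains U; mapping U->T", rec.id)
            seq = seq.replace("U", "T")
        records.append(GenomeRecord(rec.id, seq))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path, width: int = 70) -> None:
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.seq_id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


# ---------------------------------------------------------------------------
# GFF3


def _subtract(intervals: Sequence[Interval], sub: Sequence[Interval]) -> list[Interval]:
    """Set difference of sorted interval lists (exon minus CDS -> UTR pieces)."""
    out: list[Interval] = []
    for iv in intervals:
        pieces = [iv]
        for s in sub:
            nxt: list[Interval] = []
            for p in pieces:
                if s.end <= p.start or s.start >= p.end:
                    nxt.append(p)
                    continue
                if p.start < s.start:
                    nxt.append(Interval(p.start, s.start))
                if s.end < p.end:
                    nxt.append(Interval(s.end, p.end))
            pieces = nxt
        out.extend(pieces)
    return [p for p in sorted(out) if p.length > 0]


def read_gff3(path: str | Path, genome: Sequence[GenomeRecord]) -> list[GeneModel]:
    """Read gene models (one per mRNA) from a GFF3 subset.

    Accepted feature types: gene, mRNA, exon, CDS, five_prime_UTR,
    three_prime_UTR with ID/Parent attributes.  Coordinates are converted to
    internal 0-based half-open.  When no UTR features are present, UTRs are
    inferred as exon minus CDS, split around the CDS span.
    """
    lengths = {g.seq_id: g.length for g in genome}
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    for mrna in db.features_of_type("mRNA", order_by=("seqid", "start")):
        exons: list[Interval] = []
        cds: list[Interval] = []
        utr5: list[Interval] = []
        utr3: list[Interval] = []
        for child in db.children(mrna.id, order_by="start"):
            iv = Interval(child.start - 1, child.end)  # 1-based inclusive -> 0-based half-open
            if child.featuretype == "exon":
                exons.append(iv)
            elif child.featuretype == "CDS":
                cds.append(iv)
            elif child.featuretype == "five_prime_UTR":
                utr5.append(iv)
            elif child.featuretype == "three_prime_UTR":
                utr3.append(iv)
        exons.sort()
        cds.sort()
        seq_len = lengths.get(mrna.seqid)
        if seq_len is None:
            raise FormatError(f"mRNA {mrna.id}: unknown sequence {mrna.seqid!r}")
        for ex in exons:
            if ex.start < 0 or ex.end > seq_len:
                raise FormatError(
                    f"mRNA {mrna.id}: exon {ex} outside sequence {mrna.seqid} "
                    f"bounds (length {seq_len})"
                )
        for c in cds:
            if not any(ex.contains(c) for ex in exons):
                raise FormatError(f"mRNA {mrna.id}: CDS {c} not inside any exon")
        if cds and not (utr5 or utr3):
            utr5, utr3 = _infer_utrs(exons, cds, mrna.strand)
        models.append(
            GeneModel(
                gene_id=mrna.id,
                seq_id=mrna.seqid,
                strand=mrna.strand,
                exons=tuple(exons),
                cds=tuple(cds),
                utr5=tuple(sorted(utr5)),
                utr3=tuple(sorted(utr3)),
            )
        )
    return models


def _infer_utrs(
    exons: Sequence[Interval], cds: Sequence[Interval], strand: str
) -> tuple[list[Interval], list[Interval]]:
    noncoding = _subtract(exons, cds)
    cds_lo = cds[0].start
    cds_hi = cds[-1].end
    left = [iv for iv in noncoding if iv.end <= cds_lo]
    right = [iv for iv in noncoding if iv.start >= cds_hi]
    if strand == "+":
        return left, right
    return right, left


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models in the GFF3 subset read by :func:`read_gff3`.

    Emits an enclosing gene feature per mRNA (ID ``g:<gene_id>``) so the
    output is valid standalone GFF3; round trip preserves all coordinates.
    """
    lines = ["##gff-version 3"]
    for g in genes:
        sp = g.span
        gid = f"g:{g.gene_id}"
        lines.append(
            "\t".join(
                [g.seq_id, "riboreg", "gene", str(sp.start + 1), str(sp.end), ".",
                 g.strand, ".", f"ID={gid}"]
            )
        )
        lines.append(
            "\t".join(
                [g.seq_id, "riboreg", "mRNA", str(sp.start + 1), str(sp.end), ".",
                 g.strand, ".", f"ID={g.gene_id};Parent={gid}"]
            )
        )
        for ftype, ivals in (
            ("exon", g.exons),
            ("CDS", g.cds),
            ("five_prime_UTR", g.utr5),
            ("three_prime_UTR", g.utr3),
        ):
            for iv in ivals:
                lines.append(
                    "\t".join(
                        [g.seq_id, "riboreg", ftype, str(iv.start + 1), str(iv.end),
                         ".", g.strand, ".", f"Parent={g.gene_id}"]
                    )
                )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Introns / extraction


def derive_introns(gene: GeneModel) -> list[IntronRecord]:
    """One :class:`IntronRecord` per gap between consecutive exons.

    Ordinals follow transcript orientation (reverse genomic order on the
    minus strand).  Context is FIVE_UTR_INTRON when both flanking exonic
    bases lie 5' of the CDS start in transcript orientation, mirrored for
    the 3' side; otherwise INTERNAL_INTRON.
    """
    gaps = [
        Interval(prev.end, cur.start)
        for prev, cur in zip(gene.exons, gene.exons[1:])
    ]
    if not gaps:
        return []
    cds_span = gene.cds_span
    if cds_span is None:
        raise ValueError(f"gene {gene.gene_id} has no CDS; cannot assign intron context")
    records = []
    ordered = gaps if gene.strand == "+" else list(reversed(gaps))
    for ordinal, iv in enumerate(ordered, start=1):
        if gene.strand == "+":
            if iv.end <= cds_span.start:
                ctx = IntronContext.FIVE_UTR_INTRON
            elif iv.start >= cds_span.end:
                ctx = IntronContext.THREE_UTR_INTRON
            else:
                ctx = IntronContext.INTERNAL_INTRON
        else:
            if iv.start >= cds_span.end:
                ctx = IntronContext.FIVE_UTR_INTRON
            elif iv.end <= cds_span.start:
                ctx = IntronContext.THREE_UTR_INTRON
            else:
                ctx = IntronContext.INTERNAL_INTRON
        records.append(IntronRecord(gene.gene_id, ordinal, iv, ctx))
    return records


def extract(genome: GenomeRecord | str, interval: Interval | tuple[int, int], strand: str = "+") -> str:
    """Subsequence of ``genome`` over ``interval``; reverse-complemented on '-'.

    Raises ``ValueError`` when the interval is out of bounds.
    """
    seq = genome.sequence if isinstance(genome, GenomeRecord) else genome
    start, end = interval
    if start < 0 or end > len(seq) or start > end:
        raise ValueError(f"interval ({start},{end}) out of bounds for length {len(seq)}")
    sub = seq[start:end]
    return sub if strand == "+" else reverse_complement(sub)
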