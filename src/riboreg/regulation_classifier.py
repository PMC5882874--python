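"""Rule-based classification of riboswitch regulation mechanisms.

Four location-defined mechanism types are recognised from splice-site,
uORF, stop-codon, intron-length and α-element evidence gathered on the
transcript (sense) strand:

- TYPE_I   — 5'UTR intron, uORF flanked by alternative donors, terminal AG;
- TYPE_II  — long internal intron (650–900 nt default) with ≥2 donors and a
  distal α element (RGCGGYRRY) complementary to the aptamer's P1 window;
- TYPE_III — short internal intron (200–400 nt default) with a donor pair
  bracketing an in-frame stop codon and an acceptor downstream of the aptamer;
- TYPE_IV  — splice-site-free 5'UTR of a single-exon gene.

Rules are evaluated in the fixed order II -> III -> I -> IV; the first match
wins, guaranteeing exclusivity.  All thresholds are parameters with defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

from riboreg.aptamer_search import AptamerHit, iupac_find_all
from riboreg.context_mapper import ContextClass, GenomicContext
from riboreg.genome_io import (
    GeneModel,
    GenomeRecord,
    Interval,
    extract,
    reverse_complement,
)

STOP_CODONS = ("TAA", "TAG", "TGA")
ALPHA_PATTERN = "RGCGGYRRY"


class RegType(str, Enum):
    TYPE_I = "TYPE_I"
    TYPE_II = "TYPE_II"
    TYPE_III = "TYPE_III"
    TYPE_IV = "TYPE_IV"
    UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class SpliceSite:
    kind: str  # donor | acceptor
    position: int  # 0-based offset within the region, sense strand
    dinucleotide: str
    label: str | None = None  # S1/S2/... for donors, 5'->3'


@dataclass(frozen=True)
class UORF:
    start: int
    end: int  # half-open; includes the stop codon
    n_codons: int
    frame: int

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0:
            raise ValueError("uORF length must be divisible by 3")


@dataclass(frozen=True)
class AlphaElement:
    position: int
    matched: str
    complementarity: int  # Watson–Crick matches vs revcomp of the P1 window
    separation: int  # nt between α 3' end and the aptamer 5' end


@dataclass(frozen=True)
class ClassifierParams:
    """Every mechanism-rule threshold, overridable via config/CLI."""

    len2_lo: int = 650
    len2_hi: int = 900
    len3_lo: int = 200
    len3_hi: int = 400
    uorf_min_codons: int = 10
    uorf_max_codons: int = 100
    alpha_max_separation: int = 700
    alpha_min_complementarity: int = 6
    alpha_require_between_s1_s2: bool = False


@dataclass(frozen=True)
class Evidence:
    context_class: ContextClass
    intron_length: int | None = None
    donors: tuple[SpliceSite, ...] = ()
    s1: SpliceSite | None = None
    s2: SpliceSite | None = None
    acceptor: SpliceSite | None = None
    uorf: UORF | None = None
    alpha: AlphaElement | None = None
    stop_position: int | None = None


@dataclass(frozen=True)
class RegulationCall:
    hit_id: str
    gene_id: str | None
    reg_type: RegType
    evidence: Evidence
    notes: str


# ---------------------------------------------------------------------------
# Evidence primitives


def find_splice_sites(region: str) -> list[SpliceSite]:
    """All GT donor and AG acceptor candidates in a sense-strand region.

    Donors are labeled S1, S2, ... in 5'->3' order.
    """
    sites: list[SpliceSite] = []
    donors = [i for i in range(len(region) - 1) if region[i: i + 2] == "GT"]
    for n, pos in enumerate(donors, start=1):
        sites.append(SpliceSite("donor", pos, "GT", f"S{n}"))
    for i in range(len(region) - 1):
        if region[i: i + 2] == "AG":
            sites.append(SpliceSite("acceptor", i, "AG"))
    return sites


def find_uorfs(region: str, min_codons: int = 2, max_codons: int = 10_000) -> list[UORF]:
    """Every ATG..first-in-frame-stop span with a codon count in range.

    ``n_codons`` includes the stop codon; spans have no internal in-frame
    stop by construction (the first stop terminates the ORF).  All three
    frames are searched; results are sorted by start.
    """
    if min_codons < 2:
        raise ValueError("min_codons must be >= 2")
    out: list[UORF] = []
    n = len(region)
    for frame in range(3):
        stops_ahead: list[int] = [
            q for q in range(frame, n - 2, 3) if region[q: q + 3] in STOP_CODONS
        ]
        for p in range(frame, n - 2, 3):
            if region[p: p + 3] != "ATG":
                continue
            stop = next((q for q in stops_ahead if q > p), None)
            if stop is None:
                continue
            n_codons = (stop + 3 - p) // 3
            if min_codons <= n_codons <= max_codons:
                out.append(UORF(p, stop + 3, n_codons, p % 3))
    out.sort(key=lambda u: (u.start, u.end))
    return out


def complementarity(alpha_seq: str, p1_seq: str) -> int:
    """Watson–Crick matches between an α candidate and revcomp(P1 window)."""
    target = reverse_complement(p1_seq)
    return sum(a == b and a in "ACGT" for a, b in zip(alpha_seq, target))


def find_alpha_element(
    intron: str,
    aptamer_offset: int,
    p1_sequence: str,
    max_separation: int = 700,
    min_complementarity: int = 6,
    lo_bound: int = 0,
    hi_bound: int | None = None,
) -> AlphaElement | None:
    """Best α-element candidate 5' of the aptamer within the intron.

    Among all RGCGGYRRY matches ending 5' of ``aptamer_offset`` and within
    ``max_separation`` nt of it, returns the one with maximal complementarity
    to the reverse complement of the P1 window (ties: 5'-most), or ``None``
    if no candidate reaches ``min_complementarity``.  ``lo_bound``/``hi_bound``
    optionally restrict the search window (e.g. between S1 and S2).
    """
    k = len(ALPHA_PATTERN)
    hi = aptamer_offset - k if hi_bound is None else min(hi_bound, aptamer_offset - k)
    best: AlphaElement | None = None
    for pos in iupac_find_all(ALPHA_PATTERN, intron):
        if pos < lo_bound or pos > hi:
            continue
        sep = aptamer_offset - (pos + k)
        if sep > max_separation:
            continue
        cand = AlphaElement(pos, intron[pos: pos + k], complementarity(intron[pos: pos + k], p1_sequence), sep)
        if best is None or cand.complementarity > best.complementarity:
            best = cand
    if best is None or best.complementarity < min_complementarity:
        return None
    return best


# ---------------------------------------------------------------------------
# Classification


def _hit_offsets_in_region(
    hit: AptamerHit, region: Interval, strand: str
) -> tuple[int, int]:
    """Sense-strand (start, end) offsets of the hit within a region."""
    if strand == "+":
        return hit.interval.start - region.start, hit.interval.end - region.start
    return region.end - hit.interval.end, region.end - hit.interval.start


def _upstream_cds_length(gene: GeneModel, intron: Interval) -> int:
    """Total CDS nt upstream (transcript orientation) of the intron."""
    if gene.strand == "+":
        return sum(c.length for c in gene.cds if c.end <= intron.start)
    return sum(c.length for c in gene.cds if c.start >= intron.end)


def _mask_hit(seq: str, lo: int, hi: int) -> str:
    lo = max(0, lo)
    hi = min(len(seq), hi)
    if hi <= lo:
        return seq
    return seq[:lo] + "N" * (hi - lo) + seq[hi:]


def classify_hit(
    hit: AptamerHit,
    context: GenomicContext,
    gene: GeneModel | None,
    genome: GenomeRecord,
    params: ClassifierParams | None = None,
) -> RegulationCall:
    """Classify one located hit into TYPE_I..TYPE_IV or UNCLASSIFIED.

    Deterministic; the ``notes`` trace records the rule order and, for
    UNCLASSIFIED, every failed condition.
    """
    params = params or ClassifierParams()
    trace: list[str] = ["rule order: II -> III -> I -> IV"]

    if gene is not None and gene.seq_id != genome.seq_id:
        raise ValueError(
            f"gene {gene.gene_id} is on {gene.seq_id}, not on genome {genome.seq_id}"
        )

    cls = context.context_class
    intron = context.containing_intron
    intron_len = intron.length if intron else None

    intron_seq = ""
    apt_lo = apt_hi = -1
    donors: tuple[SpliceSite, ...] = ()
    acceptors: list[SpliceSite] = []
    if intron is not None and gene is not None:
        intron_seq = extract(genome, intron.interval, gene.strand)
        apt_lo, apt_hi = _hit_offsets_in_region(hit, intron.interval, gene.strand)
        sites = find_splice_sites(intron_seq)
        donors = tuple(s for s in sites if s.kind == "donor")
        acceptors = [s for s in sites if s.kind == "acceptor"]

    base_ev = Evidence(
        context_class=cls, intron_length=intron_len, donors=donors,
    )

    # ---- TYPE II -----------------------------------------------------------
    fails: list[str] = []
    if cls is not ContextClass.INTERNAL_INTRON:
        fails.append(f"II: context is {cls.value}, need INTERNAL_INTRON")
    else:
        if not (params.len2_lo <= intron_len <= params.len2_hi):
            fails.append(
                f"II: intron length {intron_len} outside [{params.len2_lo},{params.len2_hi}]"
            )
        upstream_donors = [d for d in donors if d.position < apt_lo]
        if len(upstream_donors) < 2:
            fails.append(f"II: {len(upstream_donors)} donor(s) 5' of aptamer, need >=2")
        alpha = None
        if cls is ContextClass.INTERNAL_INTRON:
            lo_bound = 0
            hi_bound = None
            if params.alpha_require_between_s1_s2 and len(upstream_donors) >= 2:
                lo_bound = upstream_donors[0].position
                hi_bound = upstream_donors[1].position
            alpha = find_alpha_element(
                intron_seq, apt_lo, hit.p1_sequence,
                max_separation=params.alpha_max_separation,
                min_complementarity=params.alpha_min_complementarity,
                lo_bound=lo_bound, hi_bound=hi_bound,
            )
        if alpha is None:
            fails.append(
                f"II: no {ALPHA_PATTERN} element with complementarity >= "
                f"{params.alpha_min_complementarity} within {params.alpha_max_separation} nt"
            )
        if not fails:
            ev = replace(
                base_ev, s1=upstream_donors[0], s2=upstream_donors[1], alpha=alpha,
                acceptor=next((a for a in acceptors if a.position >= apt_hi), None),
            )
            trace.append("II: all conditions met")
            return RegulationCall(hit.hit_id, context.gene_id, RegType.TYPE_II, ev, "; ".join(trace))
    trace.extend(fails)

    # ---- TYPE III ----------------------------------------------------------
    fails = []
    if cls is not ContextClass.INTERNAL_INTRON:
        fails.append(f"III: context is {cls.value}, need INTERNAL_INTRON")
    else:
        if not (params.len3_lo <= intron_len <= params.len3_hi):
            fails.append(
                f"III: intron length {intron_len} outside [{params.len3_lo},{params.len3_hi}]"
            )
        up_len = _upstream_cds_length(gene, intron.interval)
        frame_offset = (3 - up_len % 3) % 3
        inframe_stops = [
            p for p in range(frame_offset, len(intron_seq) - 2, 3)
            if intron_seq[p: p + 3] in STOP_CODONS
        ]
        pair = _donor_pair_bracketing_stop(donors, inframe_stops, apt_lo)
        if pair is None:
            fails.append(
                "III: no donor pair 5' of the aptamer with an in-frame stop between them"
            )
        acc = next((a for a in acceptors if a.position >= apt_hi), None)
        if acc is None:
            fails.append("III: no acceptor AG downstream of the aptamer")
        if not fails:
            d1, d2, stop = pair
            ev = replace(base_ev, s1=d1, s2=d2, acceptor=acc, stop_position=stop)
            trace.append("III: all conditions met")
            return RegulationCall(hit.hit_id, context.gene_id, RegType.TYPE_III, ev, "; ".join(trace))
    trace.extend(fails)

    # ---- TYPE I ------------------------------------------------------------
    fails = []
    if cls is not ContextClass.FIVE_UTR_INTRON:
        fails.append(f"I: context is {cls.value}, need FIVE_UTR_INTRON")
    else:
        uorfs = find_uorfs(intron_seq, params.uorf_min_codons, params.uorf_max_codons)
        picked = None
        for u in uorfs:
            d1 = next((d for d in donors if d.position < u.start), None)
            d2 = next((d for d in donors if u.end <= d.position < apt_lo), None)
            if d1 is not None and d2 is not None:
                picked = (u, d1, d2)
                break
        if not uorfs:
            fails.append(
                f"I: no uORF of {params.uorf_min_codons}-{params.uorf_max_codons} codons in the intron"
            )
        elif picked is None:
            fails.append("I: no uORF flanked by donors (S1 5' of uORF, S2 between uORF and aptamer)")
        if not intron_seq.endswith("AG"):
            fails.append("I: intron does not end with acceptor AG")
        if not fails:
            u, d1, d2 = picked
            acc = SpliceSite("acceptor", len(intron_seq) - 2, "AG")
            ev = replace(base_ev, s1=d1, s2=d2, acceptor=acc, uorf=u)
            trace.append("I: all conditions met")
            return RegulationCall(hit.hit_id, context.gene_id, RegType.TYPE_I, ev, "; ".join(trace))
    trace.extend(fails)

    # ---- TYPE IV -----------------------------------------------------------
    fails = []
    if cls is not ContextClass.FIVE_UTR_SINGLE_EXON:
        fails.append(f"IV: context is {cls.value}, need FIVE_UTR_SINGLE_EXON")
    else:
        utr = gene.utr5[0]
        utr_seq = extract(genome, utr, gene.strand)
        lo, hi = _hit_offsets_in_region(hit, utr, gene.strand)
        masked = _mask_hit(utr_seq, lo, hi)  # the aptamer itself is not splice-site context
        if "GT" in masked:
            fails.append("IV: donor GT present in the 5'UTR outside the aptamer")
        if "AG" in masked:
            fails.append("IV: acceptor AG present in the 5'UTR outside the aptamer")
        if not fails:
            trace.append("IV: all conditions met")
            return RegulationCall(
                hit.hit_id, context.gene_id, RegType.TYPE_IV, base_ev, "; ".join(trace)
            )
    trace.extend(fails)

    return RegulationCall(
        hit.hit_id, context.gene_id, RegType.UNCLASSIFIED, base_ev, "; ".join(trace)
    )


def _donor_pair_bracketing_stop(
    donors: Sequence[SpliceSite], inframe_stops: Sequence[int], apt_lo: int
) -> tuple[SpliceSite, SpliceSite, int] | None:
    """First donor pair (d1 < d2), both 5' of the aptamer, with an in-frame
    stop codon strictly between them."""
    up = [d for d in donors if d.position < apt_lo]
    for i, d1 in enumerate(up):
        for d2 in up[i + 1:]:
            stop = next(
                (p for p in inframe_stops if d1.position + 2 <= p and p + 3 <= d2.position),
                None,
            )
            if stop is not None:
                return d1, d2, stop
    return None


def classify_all(
    hits: Sequence[AptamerHit],
    contexts: Sequence[GenomicContext],
    genes: Sequence[GeneModel],
    genomes: Sequence[GenomeRecord],
    params: ClassifierParams | None = None,
) -> list[RegulationCall]:
    gene_by_id = {g.gene_id: g for g in genes}
    genome_by_id = {g.seq_id: g for g in genomes}
    calls = []
    for hit, ctx in zip(hits, contexts):
        gene = gene_by_id.get(ctx.gene_id) if ctx.gene_id else None
        calls.append(classify_hit(hit, ctx, gene, genome_by_id[hit.seq_id], params))
    return calls


def calls_to_tsv(calls: Iterable[RegulationCall]) -> str:
    header = [
        "hit_id", "gene_id", "reg_type", "intron_length", "s1_pos", "s2_pos",
        "acceptor_pos", "uorf_start", "uorf_codons", "alpha_pos",
        "alpha_complementarity", "stop_pos", "notes",
    ]

    def opt(x) -> str:
        return "." if x is None else str(x)

    rows = ["\t".join(header)]
    for c in calls:
        e = c.evidence
        rows.append(
            "\t".join(
                [
                    c.hit_id, c.gene_id or ".", c.reg_type.value, opt(e.intron_length),
                    opt(e.s1.position if e.s1 else None),
                    opt(e.s2.position if e.s2 else None),
                    opt(e.acceptor.position if e.acceptor else None),
                    opt(e.uorf.start if e.uorf else None),
                    opt(e.uorf.n_codons if e.uorf else None),
                    opt(e.alpha.position if e.alpha else None),
                    opt(e.alpha.complementarity if e.alpha else None),
                    opt(e.stop_position), c.notes,
                ]
            )
        )
    return "\n".join(rows) + "\n"
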