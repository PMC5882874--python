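"""Ground-truth genome generator for every pipeline stage.

Each generated architecture is a single contig carrying one gene flanked by
random intergenic sequence.  Planted evidence (aptamer, uORF, donors,
acceptor, α element, in-frame stop) is emitted as a :class:`TruthRecord`
whose coordinates are consistent with the emitted FASTA/GFF3.

Reproducibility: every gene gets its own RNG stream seeded from
``(config.seed, gene_index)``, so output is independent of generation order
and byte-identical across runs for the same config.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from riboreg.annotation_filters import HomologyRecord, write_homology_tsv
from riboreg.aptamer_search import AptamerHit, iupac_match
from riboreg.genome_io import (
    GeneModel,
    GenomeRecord,
    Interval,
    extract,
    reverse_complement,
    write_fasta,
    write_gff3,
)

log = logging.getLogger(__name__)

STOP_CODONS = ("TAA", "TAG", "TGA")

# Aptamer consensus used by the synthetic suite.  Constructed so that:
#  - GAGAT (the TPP-ring recognition motif, DNA alphabet), then GCG (J4/5),
#    then TAAT (L5) occur in 5'->3' order;
#  - a G directly after GAGAT and the G opening GCG are separated by exactly
#    18 intervening bases (the conserved G–G pair spacing);
#  - the final 9 nt form the P1 window, whose reverse complement AGCGGTAAT
#    satisfies the α-element pattern RGCGGYRRY;
#  - the only GT/AG dinucleotide anywhere is the AG inside GAGAT, so a
#    splice-site-free 5'UTR can host the aptamer.
DEFAULT_CONSENSUS = (
    "CCTCACCTCC"          # 0-10   mutable prefix
    "GAGAT"               # 10-15  GAGAU motif (invariant)
    "G"                   # 15     first G of the G–G pair (invariant)
    "CACCATCTCATCCACCTC"  # 16-34  18 intervening bases (mutable)
    "GCG"                 # 34-37  J4/5 GCG; its G closes the G–G pair (invariant)
    "CCAACCACAC"          # 37-47  mutable
    "TAAT"                # 47-51  L5 UAAU motif (invariant)
    "CCACCA"              # 51-57  mutable
    "ATTACCGCT"           # 57-66  P1 window (invariant); revcomp = AGCGGTAAT
)

P1_LEN = 9
ALPHA_PATTERN = "RGCGGYRRY"
_P1_REV_PATTERN = "RYYRCCGCY"  # reverse complement of ALPHA_PATTERN


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_per_type: int = 50
    n_decoys: int = 10
    intergenic_gc: float = 0.45
    intron_length_by_type: dict = field(
        default_factory=lambda: {"I": (300, 600), "II": (650, 900), "III": (200, 400)}
    )
    uorf_codons: tuple[int, int] = (10, 40)
    alpha_separation: tuple[int, int] = (400, 600)
    aptamer_mutation_rate: float = 0.02
    flank_len: int = 300
    consensus: str = DEFAULT_CONSENSUS

    def __post_init__(self) -> None:
        if not (0.0 <= self.aptamer_mutation_rate <= 0.25):
            raise ValueError("aptamer_mutation_rate must be in [0, 0.25]")
        for key, (lo, hi) in self.intron_length_by_type.items():
            if hi < lo:
                raise ValueError(f"empty intron length range for type {key}")
        for name, (lo, hi) in (("uorf_codons", self.uorf_codons), ("alpha_separation", self.alpha_separation)):
            if hi < lo:
                raise ValueError(f"empty range for {name}")
        if not (0.0 < self.intergenic_gc < 1.0):
            raise ValueError("intergenic_gc must be in (0, 1)")


@dataclass(frozen=True)
class TruthRecord:
    gene_id: str
    seq_id: str
    strand: str
    planted_type: str  # I | II | III | IV | DECOY
    aptamer_interval: Interval | None = None
    uorf_interval: Interval | None = None
    s1_pos: int | None = None
    s2_pos: int | None = None
    acceptor_pos: int | None = None
    alpha_pos: int | None = None
    stop_pos: int | None = None


@dataclass
class SimResult:
    config: SimConfig
    genomes: list[GenomeRecord]
    genes: list[GeneModel]
    truths: list[TruthRecord]
    seed_alignment: list[tuple[str, str]]


# ---------------------------------------------------------------------------
# Consensus validation / aptamer sampling


def validate_consensus(consensus: str, gg_separation: int = 18, p1_len: int = P1_LEN) -> dict:
    """Check every planted-motif constraint; returns the invariant offsets.

    Raises ``ValueError`` naming each violated motif.
    """
    problems = []
    g = consensus.find("GAGAT")
    if g < 0:
        problems.append("GAGAU (GAGAT) motif missing")
    gcg = consensus.find("GCG", g + 5) if g >= 0 else -1
    if g >= 0 and gcg < 0:
        problems.append("J4/5 GCG motif missing downstream of GAGAT")
    taat = consensus.find("TAAT", gcg + 3) if gcg >= 0 else -1
    if gcg >= 0 and taat < 0:
        problems.append("L5 UAAU (TAAT) motif missing downstream of GCG")
    gg = None
    if g >= 0 and gcg >= 0:
        g1 = next(
            (i for i in range(g + 5, min(len(consensus), g + 9)) if consensus[i] == "G"),
            None,
        )
        if g1 is not None and gcg - g1 - 1 == gg_separation:
            gg = (g1, gcg)
        if gg is None:
            problems.append(f"G–G pair with exactly {gg_separation} intervening bases missing")
    p1 = consensus[-p1_len:]
    if len(p1) < p1_len or not iupac_match(_P1_REV_PATTERN, p1, 0):
        problems.append(
            f"P1 window {p1!r} is not reverse-complementary to the α pattern {ALPHA_PATTERN}"
        )
    if problems:
        raise ValueError("consensus violates constraints: " + "; ".join(problems))
    return {
        "gagat": g,
        "gcg": gcg,
        "taat": taat,
        "gg_pair": gg,
        "p1_window": Interval(len(consensus) - p1_len, len(consensus)),
    }


def _invariant_positions(consensus: str, offsets: dict) -> set[int]:
    inv = set(range(offsets["gagat"], offsets["gagat"] + 5))
    inv |= set(range(offsets["gcg"], offsets["gcg"] + 3))
    inv |= set(range(offsets["taat"], offsets["taat"] + 4))
    inv |= set(offsets["gg_pair"])
    inv |= set(range(offsets["p1_window"].start, offsets["p1_window"].end))
    return inv


def make_aptamer(
    consensus: str, mutation_rate: float, rng: np.random.Generator,
    gg_separation: int = 18,
) -> tuple[str, Interval, dict]:
    """Mutated copy of the consensus with motif and P1 positions held fixed.

    Returns (sequence, p1_window, motif offsets).
    """
    offsets = validate_consensus(consensus, gg_separation=gg_separation)
    inv = _invariant_positions(consensus, offsets)
    bases = "ACGT"
    seq = list(consensus)
    for i in range(len(seq)):
        if i in inv:
            continue
        if rng.random() < mutation_rate:
            alts = [b for b in bases if b != seq[i]]
            seq[i] = alts[rng.integers(3)]
    return "".join(seq), offsets["p1_window"], offsets


# ---------------------------------------------------------------------------
# Random sequence helpers


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.45) -> str:
    if n <= 0:
        return ""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def gt_ag_free_dna(rng: np.random.Generator, n: int) -> str:
    """Random DNA containing no GT or AG dinucleotide."""
    out: list[str] = []
    prev = ""
    for _ in range(n):
        allowed = [
            b for b in "ACGT"
            if not (prev == "G" and b == "T") and not (prev == "A" and b == "G")
        ]
        b = allowed[rng.integers(len(allowed))]
        out.append(b)
        prev = b
    return "".join(out)


def _random_codons(rng: np.random.Generator, n: int) -> str:
    """n codons, none of them a stop codon."""
    out = []
    for _ in range(n):
        while True:
            codon = random_dna(rng, 3, 0.5)
            if codon not in STOP_CODONS:
                out.append(codon)
                break
    return "".join(out)


def _split_gap(rng: np.random.Generator, total: int, k: int, minimum: int) -> list[int]:
    """Split ``total`` into k parts, each >= minimum."""
    extra = total - k * minimum
    if extra < 0:
        raise ValueError(f"cannot split {total} into {k} parts of >= {minimum}")
    cuts = sorted(rng.integers(0, extra + 1, size=k - 1).tolist()) if k > 1 else []
    parts = []
    prev = 0
    for c in cuts + [extra]:
        parts.append(minimum + c - prev)
        prev = c
    return parts


# ---------------------------------------------------------------------------
# Architecture assembly


@dataclass
class _Layout:
    """Sense-strand gene region with relative features and truth offsets."""

    region: str
    exons: list[Interval]
    cds: list[Interval]
    utr5: list[Interval]
    utr3: list[Interval]
    aptamer: Interval | None = None
    uorf: Interval | None = None
    s1: int | None = None
    s2: int | None = None
    acceptor: int | None = None
    alpha: int | None = None
    stop: int | None = None


def _layout_type_I(config: SimConfig, rng: np.random.Generator) -> _Layout:
    lo, hi = config.intron_length_by_type["I"]
    apt, _, _ = make_aptamer(config.consensus, config.aptamer_mutation_rate, rng)
    k = int(rng.integers(config.uorf_codons[0], config.uorf_codons[1] + 1))
    uorf_seq = "ATG" + _random_codons(rng, k - 2) + "TAA"
    fixed = 2 + len(uorf_seq) + 2 + len(apt) + 2
    il = int(rng.integers(max(lo, fixed + 32), hi + 1))
    gaps = _split_gap(rng, il - fixed, 4, 8)
    g1, g2, g3, g4 = (random_dna(rng, n, 0.4) for n in gaps)
    intron = "GT" + g1 + uorf_seq + g2 + "GT" + g3 + apt + g4 + "AG"
    assert len(intron) == il

    e1 = random_dna(rng, int(rng.integers(80, 151)), 0.45)
    utr5b = random_dna(rng, int(rng.integers(20, 41)), 0.45)
    cds_seq = "ATG" + _random_codons(rng, int(rng.integers(80, 151))) + "TAA"
    utr3 = random_dna(rng, int(rng.integers(30, 61)), 0.45)
    exon2 = utr5b + cds_seq + utr3

    region = e1 + intron + exon2
    o = len(e1)  # intron offset
    e2o = o + il
    cds_start = e2o + len(utr5b)
    uorf_off = o + 2 + len(g1)
    apt_off = o + 2 + len(g1) + len(uorf_seq) + len(g2) + 2 + len(g3)
    return _Layout(
        region=region,
        exons=[Interval(0, o), Interval(e2o, len(region))],
        cds=[Interval(cds_start, cds_start + len(cds_seq))],
        utr5=[Interval(0, o), Interval(e2o, cds_start)],
        utr3=[Interval(cds_start + len(cds_seq), len(region))],
        aptamer=Interval(apt_off, apt_off + len(apt)),
        uorf=Interval(uorf_off, uorf_off + len(uorf_seq)),
        s1=o,
        s2=o + 2 + len(g1) + len(uorf_seq) + len(g2),
        acceptor=o + il - 2,
    )


def _three_exon_skeleton(rng: np.random.Generator) -> tuple[str, str, int, int]:
    """(exon1, intron1, c1, c2) — exon1 is utr5a+cds1, intron1 is plain."""
    utr5a = random_dna(rng, int(rng.integers(50, 101)), 0.45)
    c1 = int(rng.integers(90, 151))
    cds1 = random_dna(rng, c1, 0.5)
    i1_len = int(rng.integers(60, 91))
    intron1 = "GT" + random_dna(rng, i1_len - 4, 0.4) + "AG"
    c2 = int(rng.integers(150, 301))
    return utr5a + cds1, intron1, c1, c2


def _finish_three_exon(
    rng: np.random.Generator, c1: int, c2: int
) -> tuple[str, int]:
    """(exon3, c3) with total CDS length divisible by 3."""
    c3 = int(rng.integers(90, 151))
    c3 += (3 - (c1 + c2 + c3) % 3) % 3
    cds3 = random_dna(rng, c3, 0.5)
    utr3 = random_dna(rng, int(rng.integers(30, 61)), 0.45)
    return cds3 + utr3, c3


def _layout_internal_intron(
    config: SimConfig, rng: np.random.Generator, planted: str
) -> _Layout:
    """Shared builder for Type II and Type III (riboswitch in intron 2)."""
    exon1, intron1, c1, c2 = _three_exon_skeleton(rng)
    cds2 = random_dna(rng, c2, 0.5)
    apt, p1_window, _ = make_aptamer(config.consensus, config.aptamer_mutation_rate, rng)

    alpha_off = stop_off = None
    if planted == "II":
        lo, hi = config.intron_length_by_type["II"]
        # S1 GT + α; the S2 GT is inside the α->aptamer separation; aptamer + AG
        fixed = 2 + 9 + len(apt) + 2
        il = int(rng.integers(lo, hi + 1))
        sep_lo, sep_hi = config.alpha_separation
        sep_hi = min(sep_hi, il - fixed - 24)
        sep = int(rng.integers(sep_lo, sep_hi + 1))
        spB = int(rng.integers(10, sep - 2 - 10 + 1))
        spC = sep - 2 - spB
        rem = il - fixed - sep
        spA = int(rng.integers(12, rem - 12 + 1))
        spD = rem - spA
        alpha = reverse_complement(apt[p1_window.start: p1_window.end])
        assert iupac_match(ALPHA_PATTERN, alpha, 0)
        intron2 = (
            "GT" + random_dna(rng, spA, 0.4) + alpha + random_dna(rng, spB, 0.4)
            + "GT" + random_dna(rng, spC, 0.4) + apt + random_dna(rng, spD, 0.4) + "AG"
        )
        alpha_off = 2 + spA
        s2_off = 2 + spA + 9 + spB
        apt_off = s2_off + 2 + spC
    else:  # Type III
        lo, hi = config.intron_length_by_type["III"]
        fixed = 2 + 3 + 2 + len(apt) + 2
        il = int(rng.integers(max(lo, fixed + 46), hi + 1))
        spA, spB, spC, spD = _split_gap(rng, il - fixed, 4, 10)
        # in-frame relative to read-through of the upstream CDS
        frame_offset = (3 - (c1 + c2) % 3) % 3
        shift = (frame_offset - (2 + spA)) % 3
        spA += shift
        spD -= shift
        stop_off = 2 + spA
        s2_off = stop_off + 3 + spB
        apt_off = s2_off + 2 + spC
        intron2 = (
            "GT" + random_dna(rng, spA, 0.4) + "TAA" + random_dna(rng, spB, 0.4)
            + "GT" + random_dna(rng, spC, 0.4) + apt + random_dna(rng, spD, 0.4) + "AG"
        )
    assert len(intron2) == il

    exon3, c3 = _finish_three_exon(rng, c1, c2)
    region = exon1 + intron1 + cds2 + intron2 + exon3
    e1 = len(exon1)
    e2o = e1 + len(intron1)
    i2o = e2o + len(cds2)
    e3o = i2o + il
    utr5a_len = e1 - c1
    lay = _Layout(
        region=region,
        exons=[Interval(0, e1), Interval(e2o, i2o), Interval(e3o, len(region))],
        cds=[
            Interval(utr5a_len, e1),
            Interval(e2o, i2o),
            Interval(e3o, e3o + c3),
        ],
        utr5=[Interval(0, utr5a_len)],
        utr3=[Interval(e3o + c3, len(region))],
        aptamer=Interval(i2o + apt_off, i2o + apt_off + len(apt)),
        s1=i2o,
        s2=i2o + s2_off,
        acceptor=i2o + il - 2,
        alpha=(i2o + alpha_off) if alpha_off is not None else None,
        stop=(i2o + stop_off) if stop_off is not None else None,
    )
    return lay


def _layout_type_IV(config: SimConfig, rng: np.random.Generator) -> _Layout:
    pre = gt_ag_free_dna(rng, int(rng.integers(40, 121)))
    post = gt_ag_free_dna(rng, int(rng.integers(20, 61)))
    apt = None
    for _ in range(500):
        cand, _, _ = make_aptamer(config.consensus, config.aptamer_mutation_rate, rng)
        utr5 = pre + cand + post
        ok = True
        lo = len(pre)
        hi = lo + len(cand)
        for i in range(len(utr5) - 1):
            if utr5[i: i + 2] in ("GT", "AG") and not (lo + 3 <= i < hi - 3):
                ok = False
                break
        if ok:
            apt = cand
            break
    if apt is None:
        raise RuntimeError("could not draw a splice-site-free Type IV 5'UTR")
    utr5 = pre + apt + post
    cds_seq = "ATG" + _random_codons(rng, int(rng.integers(80, 151))) + "TAA"
    utr3 = random_dna(rng, int(rng.integers(30, 61)), 0.45)
    region = utr5 + cds_seq + utr3
    return _Layout(
        region=region,
        exons=[Interval(0, len(region))],
        cds=[Interval(len(utr5), len(utr5) + len(cds_seq))],
        utr5=[Interval(0, len(utr5))],
        utr3=[Interval(len(utr5) + len(cds_seq), len(region))],
        aptamer=Interval(len(pre), len(pre) + len(apt)),
    )


def _layout_decoy(config: SimConfig, rng: np.random.Generator) -> _Layout:
    shuffled = rng.integers(2) == 0
    e1 = random_dna(rng, int(rng.integers(80, 151)), 0.45)
    if shuffled:
        letters = np.array(list(config.consensus))
        decoy_apt = "".join(letters[rng.permutation(len(letters))])
        g1 = random_dna(rng, int(rng.integers(40, 101)), 0.4)
        g2 = random_dna(rng, int(rng.integers(40, 101)), 0.4)
        intron = "GT" + g1 + decoy_apt + g2 + "AG"
    else:
        intron = "GT" + random_dna(rng, int(rng.integers(100, 301)), 0.4) + "AG"
    utr5b = random_dna(rng, int(rng.integers(20, 41)), 0.45)
    cds_seq = "ATG" + _random_codons(rng, int(rng.integers(80, 151))) + "TAA"
    utr3 = random_dna(rng, int(rng.integers(30, 61)), 0.45)
    exon2 = utr5b + cds_seq + utr3
    region = e1 + intron + exon2
    o = len(e1)
    e2o = o + len(intron)
    cds_start = e2o + len(utr5b)
    return _Layout(
        region=region,
        exons=[Interval(0, o), Interval(e2o, len(region))],
        cds=[Interval(cds_start, cds_start + len(cds_seq))],
        utr5=[Interval(0, o), Interval(e2o, cds_start)],
        utr3=[Interval(cds_start + len(cds_seq), len(region))],
    )


_LAYOUT_BUILDERS = {
    "I": _layout_type_I,
    "II": lambda c, r: _layout_internal_intron(c, r, "II"),
    "III": lambda c, r: _layout_internal_intron(c, r, "III"),
    "IV": _layout_type_IV,
    "DECOY": _layout_decoy,
}


def make_architecture(
    planted_type: str,
    config: SimConfig,
    rng: np.random.Generator,
    index: int = 0,
) -> tuple[GenomeRecord, GeneModel, TruthRecord]:
    """One contig + gene + truth record for the given planted type.

    Strand is drawn from the RNG; minus-strand genes are emitted as the
    reverse complement of the sense-built region so the full pipeline's
    strand handling is exercised.
    """
    if planted_type not in _LAYOUT_BUILDERS:
        raise ValueError(f"unknown planted type {planted_type!r}")
    lay = _LAYOUT_BUILDERS[planted_type](config, rng)
    strand = "+" if rng.integers(2) == 0 else "-"
    flank = config.flank_len
    L = len(lay.region)
    left = random_dna(rng, flank, config.intergenic_gc)
    right = random_dna(rng, flank, config.intergenic_gc)
    core = lay.region if strand == "+" else reverse_complement(lay.region)
    seq_id = f"sim{index:04d}"
    gene_id = f"gene{index:04d}"
    genome = GenomeRecord(seq_id, left + core + right)

    def map_iv(iv: Interval | None) -> Interval | None:
        if iv is None:
            return None
        if strand == "+":
            return Interval(flank + iv.start, flank + iv.end)
        return Interval(flank + L - iv.end, flank + L - iv.start)

    def map_pos(pos: int | None, length: int) -> int | None:
        """Genomic start of a sense element of ``length`` nt at offset pos."""
        if pos is None:
            return None
        return map_iv(Interval(pos, pos + length)).start

    gene = GeneModel(
        gene_id=gene_id,
        seq_id=seq_id,
        strand=strand,
        exons=tuple(sorted(map_iv(iv) for iv in lay.exons)),
        cds=tuple(sorted(map_iv(iv) for iv in lay.cds)),
        utr5=tuple(sorted(map_iv(iv) for iv in lay.utr5)),
        utr3=tuple(sorted(map_iv(iv) for iv in lay.utr3)),
    )
    truth = TruthRecord(
        gene_id=gene_id,
        seq_id=seq_id,
        strand=strand,
        planted_type=planted_type,
        aptamer_interval=map_iv(lay.aptamer),
        uorf_interval=map_iv(lay.uorf),
        s1_pos=map_pos(lay.s1, 2),
        s2_pos=map_pos(lay.s2, 2),
        acceptor_pos=map_pos(lay.acceptor, 2),
        alpha_pos=map_pos(lay.alpha, 9),
        stop_pos=map_pos(lay.stop, 3),
    )
    return genome, gene, truth


def truth_hit(truth: TruthRecord, genome: GenomeRecord, p1_len: int = P1_LEN) -> AptamerHit:
    """AptamerHit at the planted coordinates (generator-side oracle input)."""
    if truth.aptamer_interval is None:
        raise ValueError(f"{truth.gene_id} has no planted aptamer")
    seq = extract(genome, truth.aptamer_interval, truth.strand)
    return AptamerHit(
        seq_id=truth.seq_id,
        interval=truth.aptamer_interval,
        strand=truth.strand,
        score=float("inf"),
        hit_sequence=seq,
        p1_window=Interval(len(seq) - p1_len, len(seq)),
    )


# ---------------------------------------------------------------------------
# Whole-run simulation


def make_seed_alignment(
    config: SimConfig, n_sequences: int = 10
) -> list[tuple[str, str]]:
    """Ungapped aligned replicates of the consensus (the shipped seed)."""
    rng = np.random.default_rng([config.seed, 1_000_003])
    out = []
    for i in range(n_sequences):
        seq, _, _ = make_aptamer(config.consensus, config.aptamer_mutation_rate, rng)
        out.append((f"seed{i + 1:02d}", seq))
    return out


def simulate(config: SimConfig, verify: bool = True) -> SimResult:
    """Generate all architectures (n_per_type of each of I–IV, plus decoys).

    With ``verify=True`` each non-decoy architecture is classified from its
    planted coordinates and must reproduce its planted type.
    """
    from riboreg.context_mapper import locate_hit
    from riboreg.regulation_classifier import RegType, classify_hit

    plan = [t for t in ("I", "II", "III", "IV") for _ in range(config.n_per_type)]
    plan += ["DECOY"] * config.n_decoys
    genomes: list[GenomeRecord] = []
    genes: list[GeneModel] = []
    truths: list[TruthRecord] = []
    for idx, planted in enumerate(plan):
        rng = np.random.default_rng([config.seed, idx])
        genome, gene, truth = make_architecture(planted, config, rng, index=idx)
        if verify and planted != "DECOY":
            hit = truth_hit(truth, genome)
            ctx = locate_hit(hit, [gene])
            call = classify_hit(hit, ctx, gene, genome)
            if call.reg_type is not RegType[f"TYPE_{planted}"]:
                raise RuntimeError(
                    f"generated {gene.gene_id} (type {planted}) classifies as "
                    f"{call.reg_type.value}: {call.notes}"
                )
        genomes.append(genome)
        genes.append(gene)
        truths.append(truth)
    return SimResult(
        config=config,
        genomes=genomes,
        genes=genes,
        truths=truths,
        seed_alignment=make_seed_alignment(config),
    )


# ---------------------------------------------------------------------------
# Homology-table fixture


def make_homology_table(
    n_pass: int, n_fail: int, rng: np.random.Generator
) -> tuple[list[HomologyRecord], set[str]]:
    """Synthetic transporter-evidence rows with planted pass/fail labels.

    Pass rows satisfy all five filter conditions; each fail row violates at
    least one, sampled uniformly.
    """
    records: list[HomologyRecord] = []
    pass_ids: set[str] = set()
    for i in range(n_pass):
        qid = f"qpass{i:03d}"
        records.append(
            HomologyRecord(
                query_id=qid,
                subject_id=f"tcdb{i:03d}",
                evalue=float(10 ** rng.uniform(-30, -5)),
                similarity_pct=float(rng.uniform(50, 100)),
                coverage_pct=float(rng.uniform(30, 100)),
                has_transporter_domain=True,
                n_tm_helices=int(rng.integers(1, 9)),
            )
        )
        pass_ids.add(qid)
    for i in range(n_fail):
        qid = f"qfail{i:03d}"
        evalue = float(10 ** rng.uniform(-30, -5))
        sim = float(rng.uniform(50, 100))
        cov = float(rng.uniform(30, 100))
        domain = True
        tm = int(rng.integers(1, 9))
        which = int(rng.integers(5))
        if which == 0:
            evalue = float(10 ** rng.uniform(-4.9, 0))
        elif which == 1:
            sim = float(rng.uniform(0, 49.9))
        elif which == 2:
            cov = float(rng.uniform(0, 29.9))
        elif which == 3:
            domain = False
        else:
            tm = 0
        records.append(
            HomologyRecord(
                query_id=qid, subject_id=f"tcdb_f{i:03d}", evalue=evalue,
                similarity_pct=sim, coverage_pct=cov,
                has_transporter_domain=domain, n_tm_helices=tm,
            )
        )
    return records, pass_ids


# ---------------------------------------------------------------------------
# Run directory output


def write_truth_tsv(truths: Iterable[TruthRecord], path: str | Path) -> None:
    header = [
        "gene_id", "seq_id", "strand", "planted_type", "apt_start", "apt_end",
        "uorf_start", "uorf_end", "s1_pos", "s2_pos", "acceptor_pos",
        "alpha_pos", "stop_pos",
    ]

    def opt(x) -> str:
        return "." if x is None else str(x)

    lines = ["\t".join(header)]
    for t in truths:
        ai = t.aptamer_interval
        ui = t.uorf_interval
        lines.append(
            "\t".join(
                [t.gene_id, t.seq_id, t.strand, t.planted_type,
                 opt(ai.start if ai else None), opt(ai.end if ai else None),
                 opt(ui.start if ui else None), opt(ui.end if ui else None),
                 opt(t.s1_pos), opt(t.s2_pos), opt(t.acceptor_pos),
                 opt(t.alpha_pos), opt(t.stop_pos)]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_truth_tsv(path: str | Path) -> list[TruthRecord]:
    lines = Path(path).read_text().splitlines()
    header = lines[0].split("\t")
    idx = {h: i for i, h in enumerate(header)}

    def opt_int(v: str) -> int | None:
        return None if v == "." else int(v)

    out = []
    for ln in lines[1:]:
        f = ln.split("\t")
        a_s, a_e = opt_int(f[idx["apt_start"]]), opt_int(f[idx["apt_end"]])
        u_s, u_e = opt_int(f[idx["uorf_start"]]), opt_int(f[idx["uorf_end"]])
        out.append(
            TruthRecord(
                gene_id=f[idx["gene_id"]], seq_id=f[idx["seq_id"]],
                strand=f[idx["strand"]], planted_type=f[idx["planted_type"]],
                aptamer_interval=Interval(a_s, a_e) if a_s is not None else None,
                uorf_interval=Interval(u_s, u_e) if u_s is not None else None,
                s1_pos=opt_int(f[idx["s1_pos"]]), s2_pos=opt_int(f[idx["s2_pos"]]),
                acceptor_pos=opt_int(f[idx["acceptor_pos"]]),
                alpha_pos=opt_int(f[idx["alpha_pos"]]),
                stop_pos=opt_int(f[idx["stop_pos"]]),
            )
        )
    return out


def write_seed_alignment(seed_alignment: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in seed_alignment:
            fh.write(f">{name}\n{seq}\n")


def write_run(result: SimResult, outdir: str | Path) -> Path:
    """Write genome FASTA, GFF3, truth TSV, seed alignment, homology table
    and a config echo into one directory.  Byte-identical per config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(result.genomes, outdir / "genome.fasta")
    write_gff3(result.genes, outdir / "genes.gff3")
    write_truth_tsv(result.truths, outdir / "truth.tsv")
    write_seed_alignment(result.seed_alignment, outdir / "seed_alignment.fasta")
    records, pass_ids = make_homology_table(
        20, 20, np.random.default_rng([result.config.seed, 2_000_003])
    )
    write_homology_tsv(records, outdir / "homology.tsv")
    (outdir / "homology_truth.txt").write_text("\n".join(sorted(pass_ids)) + "\n")
    cfg = asdict(result.config)
    lines = [f"{k}={cfg[k]}" for k in sorted(cfg)]
    (outdir / "config.txt").write_text("\n".join(lines) + "\n")
    return outdir
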