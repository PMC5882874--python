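"""Position-specific profile scanning for aptamer candidates.

A :class:`ProfileModel` is a per-column log-odds model over A,C,G,T against a
uniform 0.25 background, with affine gap scores relative to match columns.
:func:`scan` computes gapped local alignments of the profile against both
genomic strands and reports maximal-scoring non-overlapping hits.

Conventions:

- scores are in bits (log2);
- `gap_open` is the score of the *first* gap position of a run, `gap_extend`
  of each subsequent one; insertion and deletion runs may not be adjacent;
- N scores 0 (background) in every column and fails every literal motif match.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from riboreg.genome_io import GenomeRecord, Interval, reverse_complement

log = logging.getLogger(__name__)

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate("ACGTN")}
_NEG = -1e30

#: IUPAC degenerate DNA codes (subset used by the α-element pattern plus N).
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "W": "AT", "S": "CG",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}


def iupac_match(pattern: str, seq: str, pos: int) -> bool:
    """True iff ``seq[pos:pos+len(pattern)]`` matches the degenerate pattern.

    N in the *sequence* never matches (conservative on ambiguity).
    """
    if pos < 0 or pos + len(pattern) > len(seq):
        return False
    for p, s in zip(pattern, seq[pos: pos + len(pattern)]):
        if s not in IUPAC[p]:
            return False
    return True


def iupac_find_all(pattern: str, seq: str) -> list[int]:
    """All start offsets where ``pattern`` (IUPAC) matches ``seq``."""
    return [i for i in range(len(seq) - len(pattern) + 1) if iupac_match(pattern, seq, i)]


# ---------------------------------------------------------------------------
# Profile


@dataclass(frozen=True)
class ProfileModel:
    """Per-column log-odds profile with affine gap scores."""

    match_logodds: np.ndarray  # shape (L, 4), columns A,C,G,T, bits
    gap_open: float = -4.0
    gap_extend: float = -2.0
    source_n: int = 0

    def __post_init__(self) -> None:
        if self.match_logodds.ndim != 2 or self.match_logodds.shape[1] != 4:
            raise ValueError("match_logodds must have shape (L, 4)")
        if self.length < 1:
            raise ValueError("profile must have at least one match column")
        if not np.all(np.isfinite(self.match_logodds)):
            raise ValueError("non-finite log-odds; use a positive pseudocount")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap scores must be non-positive")

    @property
    def length(self) -> int:
        return self.match_logodds.shape[0]

    def consensus(self) -> str:
        return "".join(_BASES[i] for i in np.argmax(self.match_logodds, axis=1))

    def self_score(self) -> float:
        """Score of the consensus: sum of per-column maxima."""
        return float(np.max(self.match_logodds, axis=1).sum())

    def score_matrix(self) -> np.ndarray:
        """(L, 5) score lookup with a fifth all-zero column for N."""
        return np.hstack([self.match_logodds, np.zeros((self.length, 1))])


def build_profile(
    seed_alignment: Sequence[str], pseudocount: float = 1.0,
    gap_open: float = -4.0, gap_extend: float = -2.0,
) -> ProfileModel:
    """Build a log-odds profile from an aligned set of gapped DNA strings.

    Columns with gap fraction > 50% are dropped from the match columns.
    Per column c and base b::

        score[c][b] = log2(((count_b + pc) / (n_c + 4 pc)) / 0.25)

    where ``n_c`` counts non-gap, non-N residues in the column.
    """
    if len(seed_alignment) < 2:
        raise ValueError("seed alignment needs at least 2 sequences")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    width = len(seed_alignment[0])
    if width == 0:
        raise ValueError("zero-length alignment")
    if any(len(s) != width for s in seed_alignment):
        raise ValueError("aligned sequences must all have the same length")
    seqs = [s.upper().replace("U", "T") for s in seed_alignment]
    n = len(seqs)
    cols: list[np.ndarray] = []
    for c in range(width):
        column = [s[c] for s in seqs]
        gap_frac = sum(ch in "-." for ch in column) / n
        if gap_frac > 0.5:
            continue
        counts = np.zeros(4)
        for ch in column:
            i = _BASE_INDEX.get(ch)
            if i is not None and i < 4:
                counts[i] += 1
        n_c = counts.sum()
        freqs = (counts + pseudocount) / (n_c + 4 * pseudocount)
        cols.append(np.log2(freqs / 0.25))
    if not cols:
        raise ValueError("all alignment columns were gap-majority")
    return ProfileModel(
        match_logodds=np.vstack(cols),
        gap_open=gap_open,
        gap_extend=gap_extend,
        source_n=n,
    )


def default_threshold(profile: ProfileModel, fraction: float = 0.6) -> float:
    """Calibrated scan threshold: a fraction of the consensus self-score."""
    return fraction * profile.self_score()


# ---------------------------------------------------------------------------
# Scan


@dataclass(frozen=True)
class AptamerHit:
    seq_id: str
    interval: Interval
    strand: str
    score: float
    hit_sequence: str  # sense strand of the aptamer
    p1_window: Interval  # 3'-proximal window within hit_sequence (α' partner)

    @property
    def hit_id(self) -> str:
        return f"{self.seq_id}:{self.interval.start}-{self.interval.end}({self.strand})"

    @property
    def p1_sequence(self) -> str:
        return self.hit_sequence[self.p1_window.start: self.p1_window.end]


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_BASE_INDEX.get(ch, 4) for ch in seq), dtype=np.int64, count=len(seq))


def best_local_score(profile: ProfileModel, seq: str) -> float:
    """Optimal affine-gap local alignment score of profile vs sequence.

    Alignments start and end on a match column; the empty alignment is not
    allowed (a single negative-scoring match can be optimal when every score
    is negative).  This is the quantity the exhaustive path-enumeration
    oracle recomputes in the tests.
    """
    cands = _local_candidates(profile, _encode(seq.upper()), -math.inf)
    if not cands:
        return -math.inf
    return max(c[0] for c in cands)


def _local_candidates(
    profile: ProfileModel, seq_idx: np.ndarray, threshold: float
) -> list[tuple[float, int, int]]:
    """Per-end-row best local alignments: (score, start_row, end_row_exclusive).

    Row-vectorized Smith–Waterman-style DP over match columns with affine
    gaps.  M = match state, Ix = insertion (sequence base, no column),
    Iy = deletion (column skipped, no sequence base).  Iy runs within a row
    are resolved with a running-max closed form.
    """
    L = profile.length
    n = len(seq_idx)
    if n == 0:
        return []
    smat = profile.score_matrix()
    go, ge = profile.gap_open, profile.gap_extend
    cols = np.arange(L)
    col_ext = cols * ge

    M_prev = np.full(L, _NEG)
    Ix_prev = np.full(L, _NEG)
    Iy_prev = np.full(L, _NEG)
    sM_prev = np.zeros(L, dtype=np.int64)
    sIx_prev = np.zeros(L, dtype=np.int64)
    sIy_prev = np.zeros(L, dtype=np.int64)
    out: list[tuple[float, int, int]] = []

    for i in range(n):
        s = smat[:, seq_idx[i]]
        # diagonal predecessors (i-1, j-1)
        Mp = np.empty(L); Mp[0] = _NEG; Mp[1:] = M_prev[:-1]
        Ixp = np.empty(L); Ixp[0] = _NEG; Ixp[1:] = Ix_prev[:-1]
        Iyp = np.empty(L); Iyp[0] = _NEG; Iyp[1:] = Iy_prev[:-1]
        sMp = np.empty(L, dtype=np.int64); sMp[0] = 0; sMp[1:] = sM_prev[:-1]
        sIxp = np.empty(L, dtype=np.int64); sIxp[0] = 0; sIxp[1:] = sIx_prev[:-1]
        sIyp = np.empty(L, dtype=np.int64); sIyp[0] = 0; sIyp[1:] = sIy_prev[:-1]

        prev = np.maximum(np.maximum(Mp, Ixp), Iyp)
        prev_start = np.where(Mp >= prev, sMp, np.where(Ixp >= prev, sIxp, sIyp))
        fresh = prev <= 0.0
        M_cur = s + np.where(fresh, 0.0, prev)
        sM_cur = np.where(fresh, i, prev_start)

        from_open = M_prev + go
        from_ext = Ix_prev + ge
        Ix_cur = np.maximum(from_open, from_ext)
        sIx_cur = np.where(from_open >= from_ext, sM_prev, sIx_prev)

        # Iy within-row: Iy[j] = max_{k<=j-1} M_cur[k] + go + (j-1-k) * ge
        f = M_cur - col_ext
        runmax = np.maximum.accumulate(f)
        argbest = np.maximum.accumulate(np.where(f >= runmax, cols, -1))
        Iy_cur = np.full(L, _NEG)
        sIy_cur = np.zeros(L, dtype=np.int64)
        if L > 1:
            Iy_cur[1:] = go + col_ext[:-1] + runmax[:-1]
            sIy_cur[1:] = sM_cur[argbest[:-1]]

        jbest = int(np.argmax(M_cur))
        if M_cur[jbest] >= threshold:
            out.append((float(M_cur[jbest]), int(sM_cur[jbest]), i + 1))

        M_prev, Ix_prev, Iy_prev = M_cur, Ix_cur, Iy_cur
        sM_prev, sIx_prev, sIy_prev = sM_cur, sIx_cur, sIy_cur
    return out


def scan(
    profile: ProfileModel,
    genome: GenomeRecord,
    threshold_bits: float | None = None,
    p1_len: int = 9,
) -> list[AptamerHit]:
    """Scan both strands for profile hits with score >= threshold.

    Returns maximal-scoring non-overlapping hits sorted by genomic position;
    overlaps are resolved to the higher score (ties: leftmost, then + strand).
    The default threshold is 60% of the consensus self-score.
    """
    if threshold_bits is None:
        threshold_bits = default_threshold(profile)
    n = genome.length
    if n == 0:
        return []
    L = profile.length
    lo_len, hi_len = math.ceil(0.5 * L), 2 * L

    candidates: list[tuple[float, int, int, str]] = []  # score, gstart, gend, strand
    fwd = _encode(genome.sequence)
    for score, start, end in _local_candidates(profile, fwd, threshold_bits):
        candidates.append((score, start, end, "+"))
    rev = _encode(reverse_complement(genome.sequence))
    for score, start, end in _local_candidates(profile, rev, threshold_bits):
        candidates.append((score, n - end, n - start, "-"))

    candidates = [
        c for c in candidates if lo_len <= c[2] - c[1] <= hi_len
    ]
    # higher score wins; ties leftmost, then + strand
    candidates.sort(key=lambda c: (-c[0], c[1], c[3] != "+"))
    chosen: list[tuple[float, int, int, str]] = []
    for c in candidates:
        if all(c[2] <= k[1] or c[1] >= k[2] for k in chosen):
            chosen.append(c)

    hits = []
    for score, start, end, strand in sorted(chosen, key=lambda c: (c[1], c[2])):
        sub = genome.sequence[start:end]
        hit_seq = sub if strand == "+" else reverse_complement(sub)
        w = min(p1_len, len(hit_seq))
        hits.append(
            AptamerHit(
                seq_id=genome.seq_id,
                interval=Interval(start, end),
                strand=strand,
                score=score,
                hit_sequence=hit_seq,
                p1_window=Interval(len(hit_seq) - w, len(hit_seq)),
            )
        )
    return hits


def scan_all(
    profile: ProfileModel, genomes: Iterable[GenomeRecord],
    threshold_bits: float | None = None, p1_len: int = 9,
) -> list[AptamerHit]:
    hits: list[AptamerHit] = []
    for g in genomes:
        hits.extend(scan(profile, g, threshold_bits=threshold_bits, p1_len=p1_len))
    return hits


# ---------------------------------------------------------------------------
# Motif annotation


@dataclass(frozen=True)
class MotifConfig:
    """Spacing parameters for conserved-motif annotation.

    ``gg_separation`` counts *intervening* bases between the paired G's;
    ``gg_proximal_window`` is how far past (before) the anchor motifs a G may
    sit while still counting as motif-proximal.
    """

    gg_separation: int = 18
    gg_proximal_window: int = 4


@dataclass(frozen=True)
class MotifAnnotation:
    motif_name: str  # GAGAU | J45_GCG | L5_UAAU | GG_PAIR
    positions: tuple[int, ...]
    satisfied: bool
    spacing: int | None = None


def annotate_motifs(hit: AptamerHit, config: MotifConfig | None = None) -> list[MotifAnnotation]:
    """Annotate the conserved aptamer motifs within a hit sequence.

    RNA motifs are matched in the DNA alphabet (GAGAU -> GAGAT, UAAU -> TAAT).
    Reports the 5'-most GAGAT, the first GCG downstream of it, the first TAAT
    downstream of that, and a G–G pair with exactly ``gg_separation``
    intervening bases anchored near the GAGAT and GCG motifs.
    """
    cfg = config or MotifConfig()
    s = hit.hit_sequence
    out: list[MotifAnnotation] = []

    g = s.find("GAGAT")
    out.append(MotifAnnotation("GAGAU", (g,) if g >= 0 else (), g >= 0))
    gcg = s.find("GCG", g + 5) if g >= 0 else -1
    out.append(MotifAnnotation("J45_GCG", (gcg,) if gcg >= 0 else (), gcg >= 0))
    taat = s.find("TAAT", gcg + 3) if gcg >= 0 else -1
    out.append(MotifAnnotation("L5_UAAU", (taat,) if taat >= 0 else (), taat >= 0))

    # G–G pair anchors: the first G following the GAGAT motif (within the
    # proximal window) and the G opening the GCG motif; satisfied iff exactly
    # gg_separation bases intervene between the two.
    gg_pos: tuple[int, ...] = ()
    gg_ok = False
    if g >= 0 and gcg >= 0:
        a_end = min(len(s), g + 5 + cfg.gg_proximal_window)
        g1 = next((i for i in range(g + 5, a_end) if s[i] == "G"), None)
        if g1 is not None and gcg - g1 - 1 == cfg.gg_separation:
            gg_pos = (g1, gcg)
            gg_ok = True
    out.append(
        MotifAnnotation("GG_PAIR", gg_pos, gg_ok, cfg.gg_separation if gg_ok else None)
    )
    return out


# ---------------------------------------------------------------------------
# Output


def hits_to_bed(hits: Iterable[AptamerHit]) -> str:
    """BED6; score column is bits scaled x100 (integer)."""
    lines = []
    for h in hits:
        lines.append(
            "\t".join(
                [h.seq_id, str(h.interval.start), str(h.interval.end), h.hit_id,
                 str(int(round(h.score * 100))), h.strand]
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")


def hits_to_tsv(hits: Iterable[AptamerHit], config: MotifConfig | None = None) -> str:
    header = [
        "hit_id", "seq_id", "start", "end", "strand", "score", "hit_sequence",
        "p1_start", "p1_end", "gagat_pos", "j45_gcg_pos", "l5_taat_pos",
        "gg_pair", "gg_spacing",
    ]
    rows = ["\t".join(header)]
    for h in hits:
        motifs = {m.motif_name: m for m in annotate_motifs(h, config)}

        def pos(name: str) -> str:
            m = motifs[name]
            return str(m.positions[0]) if m.satisfied else "."

        rows.append(
            "\t".join(
                [h.hit_id, h.seq_id, str(h.interval.start), str(h.interval.end),
                 h.strand, f"{h.score:.4f}", h.hit_sequence,
                 str(h.p1_window.start), str(h.p1_window.end),
                 pos("GAGAU"), pos("J45_GCG"), pos("L5_UAAU"),
                 "1" if motifs["GG_PAIR"].satisfied else "0",
                 str(motifs["GG_PAIR"].spacing) if motifs["GG_PAIR"].spacing is not None else "."]
            )
        )
    return "\n".join(rows) + "\n"


def hits_from_tsv(text: str) -> list[AptamerHit]:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    idx = {name: i for i, name in enumerate(header)}
    hits = []
    for ln in lines[1:]:
        f = ln.split("\t")
        hits.append(
            AptamerHit(
                seq_id=f[idx["seq_id"]],
                interval=Interval(int(f[idx["start"]]), int(f[idx["end"]])),
                strand=f[idx["strand"]],
                score=float(f[idx["score"]]),
                hit_sequence=f[idx["hit_sequence"]],
                p1_window=Interval(int(f[idx["p1_start"]]), int(f[idx["p1_end"]])),
            )
        )
    return hits
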