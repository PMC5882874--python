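"""Independent oracles used by unit and acceptance tests.

These deliberately re-derive quantities by brute force (path enumeration,
pattern expansion, codon-pair enumeration) without touching the production
algorithms they check.
"""

from __future__ import annotations

import itertools
import math

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
STOPS = {"TAA", "TAG", "TGA"}


def enumerate_local_score(score_matrix, gap_open: float, gap_extend: float, seq: str) -> float:
    """Best local alignment score by exhaustive path enumeration.

    Alignments start and end with a match; gap runs are single-type
    (no adjacent insertion/deletion); the first gap of a run scores
    gap_open, each further one gap_extend.
    """
    L = len(score_matrix)
    n = len(seq)
    idx = [_BASE_INDEX[c] for c in seq]
    best = -math.inf

    def rec(i: int, j: int, score: float, last: str) -> None:
        nonlocal best
        if last == "M" and score > best:
            best = score
        if i < n and j < L:
            rec(i + 1, j + 1, score + score_matrix[j][idx[i]], "M")
        if i < n and j < L and last in ("M", "I"):
            rec(i + 1, j, score + (gap_open if last == "M" else gap_extend), "I")
        if j < L and last in ("M", "D"):
            rec(i, j + 1, score + (gap_open if last == "M" else gap_extend), "D")

    for i in range(n):
        for j in range(L):
            rec(i + 1, j + 1, score_matrix[j][idx[i]], "M")
    return best


IUPAC_EXPAND = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "W": "AT", "S": "CG",
    "K": "GT", "M": "AC",
}


def expand_pattern(pattern: str) -> list[str]:
    """All literal strings matching a degenerate IUPAC pattern."""
    return ["".join(p) for p in itertools.product(*(IUPAC_EXPAND[c] for c in pattern))]


def brute_force_pattern_positions(pattern: str, seq: str) -> list[int]:
    """Match positions found by scanning every expanded literal."""
    literals = expand_pattern(pattern)
    k = len(pattern)
    out = []
    for i in range(len(seq) - k + 1):
        if seq[i: i + k] in literals:
            out.append(i)
    return out


def brute_force_uorfs(region: str, min_codons: int, max_codons: int) -> list[tuple[int, int, int, int]]:
    """All (start, end, n_codons, frame) by enumerating ATG/stop codon pairs."""
    n = len(region)
    found = []
    for p in range(n - 2):
        if region[p: p + 3] != "ATG":
            continue
        for q in range(p + 3, n - 2, 3):
            codon = region[q: q + 3]
            internal_stop = any(
                region[m: m + 3] in STOPS for m in range(p + 3, q, 3)
            )
            if codon in STOPS:
                if not internal_stop:
                    n_codons = (q + 3 - p) // 3
                    if min_codons <= n_codons <= max_codons:
                        found.append((p, q + 3, n_codons, p % 3))
                break
    found.sort(key=lambda t: (t[0], t[1]))
    return found
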