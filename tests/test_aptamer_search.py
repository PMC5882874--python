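import math

import numpy as np
import pytest

from oracles import enumerate_local_score

from riboreg.aptamer_search import (
    AptamerHit,
    MotifConfig,
    ProfileModel,
    annotate_motifs,
    best_local_score,
    build_profile,
    default_threshold,
    iupac_find_all,
    scan,
)
from riboreg.genome_io import GenomeRecord, Interval, reverse_complement
from riboreg.synthetic_data import DEFAULT_CONSENSUS, SimConfig, make_aptamer


# --------------------------------------------------------------------------- profile


def test_build_profile_closed_form():
    prof = build_profile(["AA", "AA"], pseudocount=1.0)
    # log2((2+1)/(2+4)/0.25) = 1 bit for A in both columns
    assert prof.length == 2
    assert prof.match_logodds[0][0] == pytest.approx(1.0)
    assert prof.match_logodds[1][0] == pytest.approx(1.0)


def test_build_profile_uniform_column_scores_zero():
    # uniform counts give exactly zero log-odds for any pseudocount
    prof = build_profile(["A", "C", "G", "T"], pseudocount=0.37)
    assert np.allclose(prof.match_logodds, 0.0)


def test_build_profile_drops_gap_majority_columns():
    prof = build_profile(["A-A", "A-A", "A-A"], pseudocount=1.0)
    assert prof.length == 2


def test_build_profile_errors():
    with pytest.raises(ValueError):
        build_profile(["ACGT"])
    with pytest.raises(ValueError):
        build_profile(["", ""])
    with pytest.raises(ValueError):
        build_profile(["AC", "ACG"])
    with pytest.raises(ValueError):
        build_profile(["AC", "AC"], pseudocount=0.0)


def test_consensus_and_self_score():
    prof = build_profile(["ACG", "ACG", "ACT"], pseudocount=0.5)
    assert prof.consensus() == "ACG"
    assert prof.self_score() == pytest.approx(
        float(np.max(prof.match_logodds, axis=1).sum())
    )


# --------------------------------------------------------------------------- scan


def _flank(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def test_scan_finds_planted_consensus(profile):
    rng = np.random.default_rng(5)
    consensus = profile.consensus()
    seq = _flank(rng, 400) + consensus + _flank(rng, 400)
    hits = scan(profile, GenomeRecord("g", seq), default_threshold(profile))
    assert len(hits) == 1
    (h,) = hits
    assert h.interval == Interval(400, 400 + len(consensus))
    assert h.strand == "+"
    assert h.score == pytest.approx(profile.self_score())
    assert h.hit_sequence == consensus


def test_scan_reverse_strand_symmetric(profile):
    rng = np.random.default_rng(6)
    consensus = profile.consensus()
    seq = _flank(rng, 300) + consensus + _flank(rng, 300)
    fwd = scan(profile, GenomeRecord("g", seq), default_threshold(profile))
    rev = scan(
        profile, GenomeRecord("g", reverse_complement(seq)), default_threshold(profile)
    )
    assert len(fwd) == len(rev) == 1
    n = len(seq)
    assert rev[0].strand == "-"
    assert rev[0].interval == Interval(n - fwd[0].interval.end, n - fwd[0].interval.start)
    assert rev[0].score == pytest.approx(fwd[0].score)
    assert rev[0].hit_sequence == fwd[0].hit_sequence


def test_scan_random_sequence_no_hits_at_self_score(profile):
    # Monte-Carlo: i.i.d. uniform sequence essentially never reaches the
    # consensus self-score (scaled to 1 kb replicates to stay fast)
    thr = profile.self_score()
    n_hits = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        g = GenomeRecord("r", _flank(rng, 1000))
        n_hits += len(scan(profile, g, thr))
    assert n_hits <= 1  # 0 hits in >= 99% of seeds


def test_scan_threshold_monotonicity(profile):
    rng = np.random.default_rng(11)
    consensus = profile.consensus()
    apt, _, _ = make_aptamer(DEFAULT_CONSENSUS, 0.05, rng)
    seq = _flank(rng, 200) + consensus + _flank(rng, 150) + apt + _flank(rng, 200)
    g = GenomeRecord("g", seq)
    t1 = 0.4 * profile.self_score()
    hits_low = {h.interval for h in scan(profile, g, t1)}
    for frac in (0.5, 0.7, 0.9, 1.01):
        hits_high = {h.interval for h in scan(profile, g, frac * profile.self_score())}
        assert hits_high <= hits_low


def test_scan_empty_genome(profile):
    assert scan(profile, GenomeRecord("e", ""), 5.0) == []


def test_best_local_score_matches_enumeration_oracle():
    rng = np.random.default_rng(99)
    for _ in range(40):
        L = int(rng.integers(1, 7))
        n = int(rng.integers(1, 9))
        prof = ProfileModel(
            rng.uniform(-2, 2, size=(L, 4)),
            gap_open=float(-rng.uniform(0.5, 3.0)),
            gap_extend=float(-rng.uniform(0.1, 2.0)),
        )
        seq = _flank(rng, n)
        dp = best_local_score(prof, seq)
        brute = enumerate_local_score(prof.score_matrix(), prof.gap_open, prof.gap_extend, seq)
        assert dp == pytest.approx(brute, abs=1e-9)


# --------------------------------------------------------------------------- motifs


def _hit_from_seq(seq: str) -> AptamerHit:
    return AptamerHit(
        "s", Interval(0, len(seq)), "+", 100.0, seq, Interval(max(0, len(seq) - 9), len(seq))
    )


def test_annotate_motifs_on_planted_consensus():
    motifs = {m.motif_name: m for m in annotate_motifs(_hit_from_seq(DEFAULT_CONSENSUS))}
    assert motifs["GAGAU"].satisfied and motifs["GAGAU"].positions == (10,)
    assert motifs["J45_GCG"].satisfied and motifs["J45_GCG"].positions == (34,)
    assert motifs["L5_UAAU"].satisfied and motifs["L5_UAAU"].positions == (47,)
    assert motifs["GG_PAIR"].satisfied
    assert motifs["GG_PAIR"].positions == (15, 34)
    assert motifs["GG_PAIR"].spacing == 18


def test_annotate_motifs_all_absent():
    motifs = annotate_motifs(_hit_from_seq("ACACAC" * 12))
    assert all(not m.satisfied for m in motifs)


def test_gg_pair_requires_exact_spacing():
    # G right after GAGAT, then 17 intervening bases, then GCG: spacing 17
    seq = "CCTCC" + "GAGAT" + "G" + "C" * 17 + "GCG" + "CCTAATCC"
    motifs = {m.motif_name: m for m in annotate_motifs(_hit_from_seq(seq))}
    assert motifs["GAGAU"].satisfied and motifs["J45_GCG"].satisfied
    assert not motifs["GG_PAIR"].satisfied

    seq18 = "CCTCC" + "GAGAT" + "G" + "C" * 18 + "GCG" + "CCTAATCC"
    motifs18 = {m.motif_name: m for m in annotate_motifs(_hit_from_seq(seq18))}
    assert motifs18["GG_PAIR"].satisfied


def test_gg_pair_configurable_spacing():
    seq = "CCTCC" + "GAGAT" + "G" + "C" * 20 + "GCG" + "CCTAATCC"
    cfg = MotifConfig(gg_separation=20)
    motifs = {m.motif_name: m for m in annotate_motifs(_hit_from_seq(seq), cfg)}
    assert motifs["GG_PAIR"].satisfied and motifs["GG_PAIR"].spacing == 20


def test_n_bases_fail_motif_matches():
    seq = DEFAULT_CONSENSUS.replace("GAGAT", "GANAT")
    motifs = {m.motif_name: m for m in annotate_motifs(_hit_from_seq(seq))}
    assert not motifs["GAGAU"].satisfied


def test_iupac_find_all_rejects_n_in_sequence():
    assert iupac_find_all("RG", "NG") == []
    assert iupac_find_all("RG", "AG") == [0]
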