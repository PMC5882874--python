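import numpy as np
import pytest

from oracles import brute_force_uorfs

from riboreg.aptamer_search import AptamerHit
from riboreg.context_mapper import locate_hit
from riboreg.genome_io import GeneModel, GenomeRecord, Interval, reverse_complement
from riboreg.regulation_classifier import (
    ClassifierParams,
    RegType,
    classify_hit,
    complementarity,
    find_alpha_element,
    find_splice_sites,
    find_uorfs,
)
from riboreg.synthetic_data import (
    DEFAULT_CONSENSUS,
    SimConfig,
    make_architecture,
    truth_hit,
)


# --------------------------------------------------------------------------- splice sites


def test_find_splice_sites_labels_donors():
    sites = find_splice_sites("GTAAGTCCAG")
    donors = [s for s in sites if s.kind == "donor"]
    acceptors = [s for s in sites if s.kind == "acceptor"]
    assert [(d.position, d.label) for d in donors] == [(0, "S1"), (4, "S2")]
    assert acceptors[-1].position == 8  # AG ending at the 3' end


def test_find_splice_sites_none():
    assert find_splice_sites("CCCCCC") == []


def test_find_splice_sites_three_donors():
    donors = [s for s in find_splice_sites("GTCCGTCCGTCC") if s.kind == "donor"]
    assert [d.label for d in donors] == ["S1", "S2", "S3"]


# --------------------------------------------------------------------------- uORFs


def test_find_uorfs_simple():
    (u,) = find_uorfs("ATGAAATAG", min_codons=2)
    assert (u.start, u.end, u.n_codons, u.frame) == (0, 9, 3, 0)


def test_find_uorfs_minimal():
    (u,) = find_uorfs("ATGTAG", min_codons=2)
    assert u.n_codons == 2


def test_find_uorfs_requires_stop():
    assert find_uorfs("ATGAAA", min_codons=2) == []


def test_find_uorfs_min_codons_validation():
    with pytest.raises(ValueError):
        find_uorfs("ATGTAG", min_codons=1)


def test_find_uorfs_matches_brute_force():
    rng = np.random.default_rng(17)
    for _ in range(20):
        region = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 1000)])
        got = [(u.start, u.end, u.n_codons, u.frame) for u in find_uorfs(region, 2, 50)]
        assert got == brute_force_uorfs(region, 2, 50)


# --------------------------------------------------------------------------- α element


def _hit_with_p1(p1: str) -> AptamerHit:
    seq = "C" * 20 + p1
    return AptamerHit("s", Interval(0, len(seq)), "+", 99.0, seq, Interval(20, 29))


def test_find_alpha_exact_complement():
    p1 = "ATTACCGCT"
    alpha = reverse_complement(p1)  # AGCGGTAAT, matches RGCGGYRRY
    intron = "C" * 50 + alpha + "C" * 300
    apt_offset = 380
    got = find_alpha_element(intron, apt_offset, p1)
    assert got is not None
    assert got.position == 50
    assert got.complementarity == 9
    assert got.separation == apt_offset - (50 + 9)


def test_find_alpha_rejects_pattern_violation():
    # TGCGGTAGC: first base T fails R
    intron = "C" * 50 + "TGCGGTAGC" + "C" * 300
    assert find_alpha_element(intron, 380, "ATTACCGCT") is None


def test_find_alpha_only_searches_five_prime_of_aptamer():
    p1 = "ATTACCGCT"
    alpha = reverse_complement(p1)
    intron = "C" * 100 + alpha + "C" * 50
    # aptamer upstream of the α match -> none
    assert find_alpha_element(intron, 40, p1) is None


def test_find_alpha_respects_max_separation():
    p1 = "ATTACCGCT"
    alpha = reverse_complement(p1)
    intron = alpha + "C" * 900
    assert find_alpha_element(intron, 905, p1, max_separation=700) is None
    assert find_alpha_element(intron, 500, p1, max_separation=700) is not None


def test_find_alpha_min_complementarity():
    p1 = "ATTACCGCT"
    # α-pattern match with poor pairing to revcomp(p1) = AGCGGTAAT
    weak = "GGCGGCGGC"  # matches RGCGGYRRY? G,G,C,G,G,C,G,G,C -> R,G,C,G,G,Y,R,R,Y ok
    intron = "C" * 30 + weak + "C" * 300
    assert find_alpha_element(intron, 340, p1, min_complementarity=6) is None
    got = find_alpha_element(intron, 340, p1, min_complementarity=0)
    assert got is not None
    assert got.complementarity == complementarity(weak, p1)


def test_complementarity_counts_watson_crick_matches():
    p1 = "ATTACCGCT"
    assert complementarity(reverse_complement(p1), p1) == 9
    # revcomp("GGGGGGGGG") == "CCCCCCCCC": full pairing
    assert complementarity("CCCCCCCCC", "GGGGGGGGG") == 9
    # and an all-purine candidate cannot pair with an all-purine target
    assert complementarity("AAAAAAAAA", "AAAAAAAAA") == 0


# --------------------------------------------------------------------------- bespoke architectures

CT_FILLER = "CCT"  # repeated: contains no ATG, GT, AG, and no stop codons


def _fill(n: int) -> str:
    return (CT_FILLER * (n // 3 + 1))[:n]


def _two_exon_gene(intron: str, seq_id="c", gene_id="g"):
    """exon1 (5'UTR) + intron + exon2 (utr5b + CDS + utr3), plus strand."""
    e1 = _fill(60)
    utr5b = _fill(20)
    cds = "ATG" + "GCC" * 40 + "TAA"
    utr3 = _fill(30)
    region = e1 + intron + utr5b + cds + utr3
    o = len(e1)
    e2o = o + len(intron)
    cds_start = e2o + len(utr5b)
    gene = GeneModel(
        gene_id, seq_id, "+",
        exons=(Interval(0, o), Interval(e2o, len(region))),
        cds=(Interval(cds_start, cds_start + len(cds)),),
        utr5=(Interval(0, o), Interval(e2o, cds_start)),
        utr3=(Interval(cds_start + len(cds), len(region)),),
    )
    return GenomeRecord(seq_id, region), gene, o


def _hit_at(genome, start, end, strand="+"):
    seq = genome.sequence[start:end]
    return AptamerHit(genome.seq_id, Interval(start, end), strand, 90.0, seq,
                      Interval(len(seq) - 9, len(seq)))


def _type_I_intron(uorf_codons=12):
    uorf = "ATG" + "GCC" * (uorf_codons - 2) + "TAA"
    return (
        "GT" + _fill(15) + uorf + _fill(12) + "GT" + _fill(12)
        + DEFAULT_CONSENSUS + _fill(10) + "AG"
    ), uorf


def test_type_I_bespoke_architecture():
    intron, uorf = _type_I_intron()
    genome, gene, o = _two_exon_gene(intron)
    apt_start = o + 2 + 15 + len(uorf) + 12 + 2 + 12
    hit = _hit_at(genome, apt_start, apt_start + len(DEFAULT_CONSENSUS))
    ctx = locate_hit(hit, [gene])
    call = classify_hit(hit, ctx, gene, genome)
    assert call.reg_type is RegType.TYPE_I
    ev = call.evidence
    assert ev.s1.position < ev.uorf.start < ev.uorf.end <= ev.s2.position
    assert ev.s2.position < apt_start - o
    assert ev.acceptor.position == len(intron) - 2


def test_type_I_without_uorf_is_unclassified():
    intron = (
        "GT" + _fill(51) + _fill(12) + "GT" + _fill(12)
        + DEFAULT_CONSENSUS + _fill(10) + "AG"
    )
    genome, gene, o = _two_exon_gene(intron)
    apt_start = o + 2 + 51 + 12 + 2 + 12
    hit = _hit_at(genome, apt_start, apt_start + len(DEFAULT_CONSENSUS))
    call = classify_hit(hit, locate_hit(hit, [gene]), gene, genome)
    assert call.reg_type is RegType.UNCLASSIFIED
    assert "no uORF" in call.notes


def _three_exon_gene(intron2: str, seq_id="c", gene_id="g"):
    """utr5a+cds1 | intron1 | cds2 | intron2 | cds3+utr3; CDS length % 3 == 0."""
    utr5a = _fill(30)
    cds1 = "ATG" + "GCC" * 20  # 63 nt
    intron1 = "GT" + _fill(40) + "AG"
    cds2 = "GCC" * 30  # 90 nt
    cds3 = "GCC" * 15 + "TAA"  # 48 nt
    utr3 = _fill(30)
    region = utr5a + cds1 + intron1 + cds2 + intron2 + cds3 + utr3
    e1_end = len(utr5a) + len(cds1)
    e2o = e1_end + len(intron1)
    i2o = e2o + len(cds2)
    e3o = i2o + len(intron2)
    gene = GeneModel(
        gene_id, seq_id, "+",
        exons=(Interval(0, e1_end), Interval(e2o, i2o), Interval(e3o, len(region))),
        cds=(
            Interval(len(utr5a), e1_end),
            Interval(e2o, i2o),
            Interval(e3o, e3o + len(cds3)),
        ),
        utr5=(Interval(0, len(utr5a)),),
        utr3=(Interval(e3o + len(cds3), len(region)),),
    )
    return GenomeRecord(seq_id, region), gene, i2o, len(cds1) + len(cds2)


def _type_II_intron(total=720, sep_fill=450):
    p1 = DEFAULT_CONSENSUS[-9:]
    alpha = reverse_complement(p1)
    head = "GT" + _fill(30) + alpha
    mid = _fill(sep_fill) + "GT" + _fill(48)
    tail_len = total - len(head) - len(mid) - len(DEFAULT_CONSENSUS) - 2
    return head + mid + DEFAULT_CONSENSUS + _fill(tail_len) + "AG", len(head) + len(mid)


def test_type_II_bespoke_architecture():
    intron2, apt_off = _type_II_intron(720)
    assert len(intron2) == 720
    genome, gene, i2o, _ = _three_exon_gene(intron2)
    hit = _hit_at(genome, i2o + apt_off, i2o + apt_off + len(DEFAULT_CONSENSUS))
    call = classify_hit(hit, locate_hit(hit, [gene]), gene, genome)
    assert call.reg_type is RegType.TYPE_II
    assert call.evidence.alpha is not None
    assert call.evidence.alpha.complementarity == 9
    assert call.evidence.intron_length == 720


def test_type_II_intron_resized_to_500_is_unclassified():
    intron2, apt_off = _type_II_intron(500, sep_fill=250)
    genome, gene, i2o, _ = _three_exon_gene(intron2)
    hit = _hit_at(genome, i2o + apt_off, i2o + apt_off + len(DEFAULT_CONSENSUS))
    call = classify_hit(hit, locate_hit(hit, [gene]), gene, genome)
    assert call.reg_type is RegType.UNCLASSIFIED
    assert "intron length 500 outside [650,900]" in call.notes


def _type_III_intron(total=300, up_cds_len=153):
    # stop codon in the read-through frame of the upstream CDS
    frame_offset = (3 - up_cds_len % 3) % 3
    spA = 15 + ((frame_offset - (2 + 15)) % 3)
    head = "GT" + _fill(spA) + "TAA" + _fill(12) + "GT" + _fill(30)
    tail_len = total - len(head) - len(DEFAULT_CONSENSUS) - 2
    return head + DEFAULT_CONSENSUS + _fill(tail_len) + "AG", len(head)


def test_type_III_bespoke_architecture():
    genome0, gene0, i2o0, up_len = _three_exon_gene("GT" + _fill(296) + "AG")
    intron2, apt_off = _type_III_intron(300, up_cds_len=up_len)
    genome, gene, i2o, up2 = _three_exon_gene(intron2)
    assert up2 == up_len
    hit = _hit_at(genome, i2o + apt_off, i2o + apt_off + len(DEFAULT_CONSENSUS))
    call = classify_hit(hit, locate_hit(hit, [gene]), gene, genome)
    assert call.reg_type is RegType.TYPE_III
    assert call.evidence.stop_position is not None
    assert call.evidence.s1.position < call.evidence.stop_position < call.evidence.s2.position


def test_internal_intron_500_with_type_III_evidence_is_unclassified():
    _, _, _, up_len = _three_exon_gene("GT" + _fill(496) + "AG")
    intron2, apt_off = _type_III_intron(500, up_cds_len=up_len)
    genome, gene, i2o, _ = _three_exon_gene(intron2)
    hit = _hit_at(genome, i2o + apt_off, i2o + apt_off + len(DEFAULT_CONSENSUS))
    call = classify_hit(hit, locate_hit(hit, [gene]), gene, genome)
    assert call.reg_type is RegType.UNCLASSIFIED
    assert "intron length 500 outside [200,400]" in call.notes


def test_type_III_stop_in_wrong_frame_is_unclassified():
    _, _, _, up_len = _three_exon_gene("GT" + _fill(296) + "AG")
    intron2, apt_off = _type_III_intron(300, up_cds_len=up_len + 1)  # shift frame
    genome, gene, i2o, _ = _three_exon_gene(intron2)
    hit = _hit_at(genome, i2o + apt_off, i2o + apt_off + len(DEFAULT_CONSENSUS))
    call = classify_hit(hit, locate_hit(hit, [gene]), gene, genome)
    assert call.reg_type is RegType.UNCLASSIFIED
    assert "in-frame stop" in call.notes


# --------------------------------------------------------------------------- generator loop-back


def test_generated_architectures_classify_as_planted():
    cfg = SimConfig(seed=3, n_per_type=2, n_decoys=0)
    for idx, planted in enumerate(["I", "II", "III", "IV"]):
        rng = np.random.default_rng([cfg.seed, idx])
        genome, gene, truth = make_architecture(planted, cfg, rng, index=idx)
        hit = truth_hit(truth, genome)
        call = classify_hit(hit, locate_hit(hit, [gene]), gene, genome)
        assert call.reg_type is RegType[f"TYPE_{planted}"], call.notes


def test_classification_is_deterministic(sim_small):
    truth = next(t for t in sim_small.truths if t.planted_type == "II")
    i = sim_small.truths.index(truth)
    genome, gene = sim_small.genomes[i], sim_small.genes[i]
    hit = truth_hit(truth, genome)
    ctx = locate_hit(hit, [gene])
    a = classify_hit(hit, ctx, gene, genome)
    b = classify_hit(hit, ctx, gene, genome)
    assert a == b
    assert a.notes == b.notes


def test_wrong_genome_errors(sim_small):
    truth = next(t for t in sim_small.truths if t.planted_type == "I")
    i = sim_small.truths.index(truth)
    genome, gene = sim_small.genomes[i], sim_small.genes[i]
    hit = truth_hit(truth, genome)
    ctx = locate_hit(hit, [gene])
    other = GenomeRecord("other", "ACGT" * 100)
    with pytest.raises(ValueError):
        classify_hit(hit, ctx, gene, other)
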