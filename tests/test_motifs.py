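import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lncscape.annotation import GeneModel
from lncscape.intervals import GenomicInterval
from lncscape.motifs import (
    PWM,
    coverage_fraction,
    load_jaspar,
    promoter_window,
    revcomp,
    scan_sequence,
    write_jaspar,
)
from lncscape.simulate import TF_CONSENSUS
from tests.oracles import oracle_scan

BASES = "ACGT"


def one_hot(consensus, p=0.97):
    m = np.full((4, len(consensus)), (1 - p) / 3)
    for j, b in enumerate(consensus):
        m[BASES.index(b), j] = p
    return m


def test_promoter_window_plus_strand_arithmetic():
    genome = {"chr1": "A" * 10_000}
    g = GeneModel("G", "G", GenomicInterval("chr1", 5000, 6000, "+"), "lncRNA")
    seq = promoter_window(g, genome, upstream=2000, downstream=100)
    assert len(seq) == 2100  # [3000, 5100)


def test_promoter_window_minus_strand_is_reverse_complemented_mirror():
    rng = np.random.default_rng(0)
    chrom = "".join(rng.choice(list(BASES), size=10_000))
    genome = {"chr1": chrom}
    minus = GeneModel("G", "G", GenomicInterval("chr1", 4001, 5001, "-"), "lncRNA")
    seq = promoter_window(minus, genome, upstream=2000, downstream=100)
    assert len(seq) == 2100
    tss = 5000  # locus.end - 1
    assert seq == revcomp(chrom[tss - 100 + 1 : tss + 2000 + 1])


def test_promoter_window_clipped_at_chromosome_start():
    genome = {"chr1": "A" * 3000}
    g = GeneModel("G", "G", GenomicInterval("chr1", 500, 900, "+"), "lncRNA")
    assert len(promoter_window(g, genome, upstream=2000, downstream=100)) == 600
    with pytest.raises(KeyError):
        promoter_window(GeneModel("G", "G", GenomicInterval("chrX", 5, 10, "+"), "lncRNA"), genome)


@settings(max_examples=50, deadline=None)
@given(st.text(alphabet="ACGTN", min_size=0, max_size=60))
def test_revcomp_is_an_involution(seq):
    assert revcomp(revcomp(seq)) == seq.upper()


def test_one_hot_consensus_hit_at_full_threshold():
    pwm = PWM("TF", one_hot("ACGGTCGT"), score_threshold=1.0)  # non-palindromic
    hits, best = scan_sequence("TTTTACGGTCGTTTTT", pwm)
    assert hits == 1 and best == pytest.approx(pwm.max_score)
    assert scan_sequence("TTTTTTTTTTTTTTTT", pwm)[0] == 0
    # a palindromic consensus is found on both strands
    pal = PWM("PAL", one_hot("ACGTACGT"), score_threshold=1.0)
    assert scan_sequence("TTTTACGTACGTTTTT", pal)[0] == 2


def test_all_n_sequence_never_hits():
    pwm = PWM("TF", one_hot("ACGTAC"), score_threshold=0.5)
    assert scan_sequence("N" * 50, pwm)[0] == 0


def test_sequence_shorter_than_motif_yields_zero_hits():
    pwm = PWM("TF", one_hot("ACGTACGT"))
    assert scan_sequence("ACG", pwm) == (0, float("-inf"))


def test_scan_matches_brute_force_oracle_on_random_sequences():
    rng = np.random.default_rng(1)
    pwm_matrix = rng.dirichlet(np.ones(4) * 0.4, size=8).T  # random 4x8 PWM
    pwm = PWM("RND", pwm_matrix, score_threshold=0.8)
    for _ in range(50):
        seq = "".join(rng.choice(list("ACGTN"), size=80, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        got = scan_sequence(seq, pwm)
        want = oracle_scan(seq, pwm.matrix, pwm.background, 0.8)
        assert got[0] == want[0]
        assert got[1] == pytest.approx(want[1])


def test_double_strand_symmetry():
    rng = np.random.default_rng(2)
    pwm = PWM("TF", one_hot("ACGGTACA"), score_threshold=0.7)
    for _ in range(20):
        seq = "".join(rng.choice(list(BASES), size=60))
        assert scan_sequence(seq, pwm)[0] == scan_sequence(revcomp(seq), pwm)[0]


def test_raising_threshold_never_raises_hit_counts():
    rng = np.random.default_rng(3)
    pwm_lo = PWM("TF", one_hot("ACGTACGT", p=0.7), score_threshold=0.6)
    pwm_hi = PWM("TF", one_hot("ACGTACGT", p=0.7), score_threshold=0.9)
    for _ in range(20):
        seq = "".join(rng.choice(list(BASES), size=100))
        assert scan_sequence(seq, pwm_hi)[0] <= scan_sequence(seq, pwm_lo)[0]


def test_jaspar_round_trip(tmp_path):
    pwms = [PWM("FOXP3", one_hot("TGTTTGCTT")), PWM("GATA1", one_hot("CTATCTCAG"))]
    path = tmp_path / "m.jaspar"
    write_jaspar(pwms, path)
    loaded = load_jaspar(path)
    assert [p.tf_name for p in loaded] == ["FOXP3", "GATA1"]
    for orig, back in zip(pwms, loaded):
        assert np.allclose(orig.matrix, back.matrix, atol=0.01)
        assert orig.consensus == back.consensus


def test_planted_coverage_fractions_recovered_exactly(sim_small):
    """Coverage equals the planted per-TF promoter fraction, and the TF
    expression filter reproduces the planted fGC expression plan."""
    res, gt = sim_small, sim_small.ground_truth
    meiotic = gt.stage_specific["fGC"]["meiotic"]
    if not meiotic:
        pytest.skip("no meiotic plants at this scale")
    gene_map = {g.gene_id: g for g in res.lncs for _ in [0]} | {
        g.gene_id: g for g in res.coding
    }
    fgc = res.dataset.select_cells(lineage="fGC")
    reports = coverage_fraction(
        meiotic, res.pwms, res.dataset, fgc, res.genome, gene_map, stage_label="meiotic"
    )
    for r in reports:
        info = gt.motif_plants[r.tf_name]
        assert r.fraction == pytest.approx(info["fraction"])
        assert r.expression_pass == info["expressed_in_fgc"]


def test_coverage_invariant_to_promoter_order(sim_small):
    res, gt = sim_small, sim_small.ground_truth
    meiotic = gt.stage_specific["fGC"]["meiotic"]
    if not meiotic:
        pytest.skip("no meiotic plants at this scale")
    gene_map = {g.gene_id: g for g in res.lncs}
    a = coverage_fraction(meiotic, res.pwms, None, None, res.genome, gene_map)
    b = coverage_fraction(list(reversed(meiotic)), res.pwms, None, None, res.genome, gene_map)
    assert [(r.tf_name, r.n_hit) for r in a] == [(r.tf_name, r.n_hit) for r in b]


def test_simulated_consensus_table_is_substring_free():
    """No example consensus equals another or another's reverse complement,
    which the planted-fraction guarantee relies on."""
    items = list(TF_CONSENSUS.values())
    for i, a in enumerate(items):
        for j, b in enumerate(items):
            if i != j:
                assert a != b and a != revcomp(b)
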