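"""Promoter extraction, PWM scoring, background fit, enrichment test."""

import numpy as np
import pytest

from genefam.genome import GeneModel, reverse_complement
from genefam.promoters import (PositionWeightMatrix, bh_adjust, enrich,
                               extract_promoters, fit_background,
                               group_enrichment, presence_calls, pwm_affinity,
                               read_pwms, score_promoters, universal_motifs,
                               write_jaspar)


def _gene(strand, start, end, chrom="c"):
    return GeneModel("g", chrom, strand, start, end, [(start, end)],
                     [(start, end)])


# -- extraction ----------------------------------------------------------

def test_short_promoter_excluded():
    genome = {"c": "A" * 400}
    genes = {"g": _gene("+", 150, 250)}  # 149 bp upstream
    out = extract_promoters(genome, genes)
    assert not out.seqs and out.exclusions[0][1].startswith("shorter")


def test_ambiguous_base_threshold_is_strictly_more_than():
    for n_amb, retained in [(1500, True), (1501, False)]:
        # the 2 kb window (genomic 501..2500) holds exactly n_amb Ns
        seq = "A" * 500 + "N" * n_amb + "A" * (2000 - n_amb)
        genome = {"c": seq + "ATG" + "A" * 50}
        genes = {"g": _gene("+", 2501, 2550)}
        out = extract_promoters(genome, genes)
        assert ("g" in out.seqs) is retained


def test_minus_strand_window_hand_oracle():
    # 60-bp toy chromosome; minus gene at 11..28, start codon at 28, so the
    # promoter is the reverse complement of genomic 29..58 (30 bp window)
    chrom = "".join("ACGT"[i % 4] for i in range(60))
    genes = {"g": _gene("-", 11, 28)}
    out = extract_promoters({"c": chrom}, genes, length=30, min_len=10,
                            max_ambiguous=5)
    assert out.seqs["g"] == reverse_complement(chrom[28:58])


def test_gene_without_cds_logged():
    genome = {"c": "A" * 3000}
    g = GeneModel("g", "c", "+", 2500, 2600, [(2500, 2600)], [])
    out = extract_promoters(genome, {"g": g})
    assert out.exclusions == [("g", "no CDS")]


def test_retained_plus_excluded_covers_all_genes(bundle):
    sim, _ = bundle
    out = extract_promoters(sim.genome, sim.genes)
    assert len(out.seqs) + len(out.exclusions) == len(sim.genes)


# -- affinity scoring ----------------------------------------------------

def test_uniform_pwm_gives_affinity_one():
    p = PositionWeightMatrix("u", np.full((3, 4), 0.25))
    assert pwm_affinity("ACGTACGT", p) == pytest.approx(1.0)


def test_width_one_pwm_hand_computation():
    # P(A)=1, uniform background: forward odds 4 at 4 positions, reverse
    # odds 0 -> mean over the 8 windows is 2
    p = PositionWeightMatrix("a", np.array([[1.0, 0, 0, 0]]))
    assert pwm_affinity("AAAA", p) == pytest.approx(2.0)


def test_affinity_invariant_under_reverse_complement():
    rng = np.random.default_rng(0)
    probs = rng.dirichlet(np.ones(4), size=6)
    p = PositionWeightMatrix("m", probs)
    for _ in range(20):
        seq = "".join(rng.choice(list("ACGT"), size=50))
        assert pwm_affinity(seq, p) == \
            pytest.approx(pwm_affinity(reverse_complement(seq), p), rel=1e-9)


def test_sequence_shorter_than_motif_errors():
    p = PositionWeightMatrix("m", np.full((5, 4), 0.25))
    with pytest.raises(ValueError):
        pwm_affinity("ACG", p)


def test_numba_and_numpy_scanners_agree():
    rng = np.random.default_rng(1)
    seqs = ["".join(rng.choice(list("ACGTN"), size=int(rng.integers(20, 80))))
            for _ in range(10)]
    pwms = [PositionWeightMatrix(f"m{i}", rng.dirichlet(np.ones(4), size=7))
            for i in range(3)]
    fast = score_promoters(seqs, pwms, use_numba=True)
    slow = score_promoters(seqs, pwms, use_numba=False)
    np.testing.assert_allclose(fast["affinity"], slow["affinity"], rtol=1e-12)
    np.testing.assert_allclose(fast["max_odds"], slow["max_odds"], rtol=1e-12)


def test_ambiguous_bases_contribute_odds_one():
    p = PositionWeightMatrix("a", np.array([[1.0, 0, 0, 0]]))
    # "N" scores odds 1 on both strands at its single window
    assert pwm_affinity("N", p) == pytest.approx(1.0)


# -- background fit ------------------------------------------------------

def test_background_constant_scores():
    bg = fit_background({"m": np.full(10, 3.0)})
    assert bg.mu["m"] == pytest.approx(np.log(3.0))
    assert bg.sigma["m"] == pytest.approx(0.0, abs=1e-12)


def test_background_recovers_lognormal_parameters():
    rng = np.random.default_rng(2)
    scores = rng.lognormal(1.0, 0.5, size=10_000)
    bg = fit_background({"m": scores})
    assert bg.mu["m"] == pytest.approx(1.0, abs=0.02)
    assert bg.sigma["m"] == pytest.approx(0.5, abs=0.02)


def test_background_needs_two_scores():
    with pytest.raises(ValueError):
        fit_background({"m": np.array([1.0])})


# -- enrichment test -----------------------------------------------------

def test_target_at_background_mean_gives_half():
    _, z, p = group_enrichment(np.array([np.e]), mu=1.0, sigma=0.5, eps=1e-9)
    assert z == pytest.approx(0.0) and p == pytest.approx(0.5)


def test_normal_quantile():
    # one target at mu + 1.6449 sigma -> upper-tail p ~ 0.05
    _, z, p = group_enrichment(np.array([np.exp(1.0 + 1.6449 * 0.5)]),
                               mu=1.0, sigma=0.5, eps=1e-9)
    assert z == pytest.approx(1.6449, abs=1e-4)
    assert p == pytest.approx(0.05, abs=1e-4)


def test_zero_sigma_degenerate_cases():
    _, _, p_hi = group_enrichment(np.array([10.0]), mu=0.0, sigma=0.0, eps=1e-9)
    _, _, p_lo = group_enrichment(np.array([0.1]), mu=0.0, sigma=0.0, eps=1e-9)
    assert p_hi == 0.0 and p_lo == 1.0


def test_bh_hand_computation():
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.9]),
                               [0.03, 0.03, 0.9])
    assert bh_adjust([0.2]) == pytest.approx([0.2])
    np.testing.assert_allclose(bh_adjust([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


# -- presence / universal motifs ----------------------------------------

def test_universal_motifs_require_every_family_promoter():
    calls = np.array([[True, True, True],
                      [True, False, True]])
    fam = np.array([0, 1, 2])
    assert universal_motifs(calls, ["m1", "m2"], fam) == ["m1"]
    assert universal_motifs(calls, ["m1", "m2"], np.array([0, 2])) == ["m1", "m2"]
    with pytest.raises(ValueError):
        universal_motifs(calls, ["m1", "m2"], np.array([], dtype=int))


def test_planted_motif_present_in_every_family_promoter(bundle):
    sim, _ = bundle
    proms = extract_promoters(sim.genome, sim.genes)
    gene_order = list(proms.seqs)
    scored = score_promoters([proms.seqs[g] for g in gene_order], sim.pwms)
    calls = presence_calls(scored["max_odds"], sim.pwms)
    fam_idx = np.array([gene_order.index(g) for g in sim.truth.family_ids])
    motif_ids = [p.motif_id for p in sim.pwms]
    found = universal_motifs(calls, motif_ids, fam_idx)
    assert set(sim.truth.planted_motif_ids) <= set(found)


# -- PWM file round trips ------------------------------------------------

def test_jaspar_round_trip(tmp_path):
    rng = np.random.default_rng(5)
    pwms = [PositionWeightMatrix(f"M{i}", rng.dirichlet(np.ones(4) * 5, size=8))
            for i in range(3)]
    write_jaspar(pwms, tmp_path / "p.jaspar", scale=10_000)
    back = read_pwms(tmp_path / "p.jaspar", pseudocount=0.0)
    assert [b.motif_id for b in back] == [p.motif_id for p in pwms]
    for a, b in zip(pwms, back):
        np.testing.assert_allclose(a.probs, b.probs, atol=1e-3)


def test_transfac_parsing(tmp_path):
    text = ("AC  M0001\nXX\nID  toy\nXX\nP0      A      C      G      T\n"
            "01      10      0      0      0      A\n"
            "02      0      10      0      0      C\n"
            "//\n")
    (tmp_path / "t.transfac").write_text(text)
    back = read_pwms(tmp_path / "t.transfac", fmt="transfac")
    assert back[0].consensus() == "AC"


def test_enrich_flags_planted_motif(bundle):
    sim, _ = bundle
    proms = extract_promoters(sim.genome, sim.genes)
    table = enrich(proms, sim.truth.family_ids, sim.pwms)
    best = table.sort_values("p").iloc[0]
    assert best.motif_id in sim.truth.planted_motif_ids
    assert best.enriched and best.presence_n == len(sim.truth.family_ids)
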