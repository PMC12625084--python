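"""Allele mining: filtering, haplotype tables, classification, consequences."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from genefam import alleles
from genefam.alleles import (HaplotypeTable, VariantRecord, annotate_consequence,
                             build_haplotype_table, classify_trait_specific,
                             classify_variant_type, filter_variants,
                             stability_report)
from genefam.genome import GeneModel

from conftest import GROUP1, GROUP2, random_gene


def _rec(pos, qual=60.0, dp=20, ref="A", chrom="c", **acc):
    return VariantRecord(chrom, pos, ref, acc, qual=qual, dp=dp)


# -- QUAL/DP filter ------------------------------------------------------

@pytest.mark.parametrize("qual,dp,kept", [
    (30.0, 5, True),    # both thresholds inclusive
    (29.9, 100, False),
    (100.0, 4, False),
    (30.0, 4, False),
])
def test_filter_boundaries(qual, dp, kept):
    recs = [_rec(10, qual=qual, dp=dp)]
    assert (len(filter_variants(recs)) == 1) is kept


def test_filter_drops_and_counts_missing_fields():
    recs = [_rec(10), VariantRecord("c", 11, "A", {}, qual=None, dp=5)]
    with pytest.warns(UserWarning, match="1 record"):
        kept = filter_variants(recs)
    assert len(kept) == 1


# -- haplotype table construction ---------------------------------------

def _toy_gene(strand="+"):
    # 100-bp chromosome window; gene body 41..70, single CDS exon
    return GeneModel("g", "c", strand, 41, 70, [(41, 70)], [(41, 70)])


def test_variant_at_start_codon_is_plus_one():
    g = _toy_gene("+")
    t = build_haplotype_table(
        [_rec(41, ref="A", **{a: "G" for a in GROUP1 + GROUP2})],
        g, GROUP1, GROUP2, promoter_len=40)
    assert list(t.df.position) == [1]


def test_minus_strand_coordinates_hand_oracle():
    """On a minus-strand gene the base one step 3' of the start codon on
    the genome is gene-relative -1, and alleles are complemented."""
    g = _toy_gene("-")  # atg at genomic 70
    recs = [_rec(71, ref="A", **{a: "G" for a in GROUP1 + GROUP2}),
            _rec(70, ref="C", **{a: "T" for a in GROUP1 + GROUP2})]
    t = build_haplotype_table(recs, g, GROUP1, GROUP2, promoter_len=40)
    assert list(t.df.position) == [-1, 1]
    up = t.df[t.df.position == -1].iloc[0]
    assert up.reference == "T" and up[GROUP1[0]] == "C"  # complemented


def test_rows_outside_window_excluded():
    g = _toy_gene("+")
    recs = [_rec(41 - 41, ref="A"), _rec(75, ref="A")]  # upstream of window; 3' of span
    t = build_haplotype_table(recs, g, GROUP1, GROUP2, promoter_len=30)
    assert len(t.df) == 0


def test_gene_without_cds_errors():
    g = GeneModel("g", "c", "+", 41, 70, [(41, 70)], [])
    with pytest.raises(ValueError):
        build_haplotype_table([], g, GROUP1, GROUP2)


def test_insertion_decomposes_to_consecutive_rows():
    g = _toy_gene("+")
    alle = {GROUP1[0]: "A", GROUP1[1]: "A",
            GROUP2[0]: "ACAT", GROUP2[1]: "ACAT"}
    t = build_haplotype_table([_rec(30, ref="A", **alle)], g, GROUP1, GROUP2)
    # anchor at -11; inserted bases at -10, -9, -8 with reference '-'
    assert list(t.df.position) == [-10, -9, -8]
    assert set(t.df.reference) == {"-"}
    assert list(t.df[GROUP2[0]]) == ["C", "A", "T"]
    assert list(t.df[GROUP1[0]]) == ["-", "-", "-"]
    assert list(classify_variant_type(t)) == ["indel"] * 3


def test_deletion_decomposes_per_base():
    g = _toy_gene("+")
    alle = {GROUP1[0]: "ACT", GROUP1[1]: "ACT", GROUP2[0]: "A", GROUP2[1]: "A"}
    t = build_haplotype_table([_rec(20, ref="ACT", **alle)], g, GROUP1, GROUP2)
    assert list(t.df.position) == [-20, -19]
    assert list(t.df[GROUP2[0]]) == ["-", "-"]
    assert list(t.df[GROUP1[0]]) == ["C", "T"]


# -- classification ------------------------------------------------------

def _table(rows):
    df = pd.DataFrame(rows, columns=["position", "reference", *GROUP1, *GROUP2])
    return HaplotypeTable("g", df, GROUP1, GROUP2)


def test_trait_specific_rule():
    t = _table([
        (10, "G", "A", "A", "G", "G"),   # clean split -> flagged
        (20, "G", "A", "G", "G", "G"),   # group 1 not uniform
        (30, "T", "T", "T", "T", "T"),   # all identical
        (40, "-", "-", "-", "C", "C"),   # deletion symbol is comparable
        (50, "G", "A", "A", ".", "G"),   # missing call disqualifies
    ])
    assert classify_trait_specific(t) == [10, 40]


def test_variant_typing():
    t = _table([
        (10, "G", "A", "A", "G", "G"),
        (20, "-", "-", "-", "C", "C"),
        (30, "T", "T", "T", "-", "T"),
    ])
    assert list(classify_variant_type(t)) == ["SNP", "indel", "indel"]


def test_empty_groups_error():
    t = _table([(10, "G", "A", "A", "G", "G")])
    t.group1 = []
    with pytest.raises(ValueError):
        classify_trait_specific(t)


# -- consequence annotation ---------------------------------------------

def _coding_gene(cds_seq, strand="+", pad=30):
    """Single-exon gene holding the given coding sequence."""
    from genefam.genome import reverse_complement

    body = cds_seq if strand == "+" else reverse_complement(cds_seq)
    g = GeneModel("g", "c", strand, pad + 1, pad + len(body),
                  [(pad + 1, pad + len(body))], [(pad + 1, pad + len(body))])
    chrom = "T" * pad + body + "T" * pad
    return g, chrom


def test_gly_to_val_substitution():
    # codon 2 GGT -> GTT: Gly -> Val at residue 2
    g, chrom = _coding_gene("ATGGGTTAA")
    call = annotate_consequence(5, "G", "T", g, chrom)
    assert call.effect == "nonsynonymous"
    assert call.protein_change == "Gly2Val"


def test_synonymous_third_position():
    g, chrom = _coding_gene("ATGGGGTAA")
    call = annotate_consequence(6, "G", "A", g, chrom)  # GGG -> GGA
    assert call.effect == "synonymous" and call.protein_change is None


def test_intronic_and_promoter_calls():
    g = GeneModel("g", "c", "+", 31, 60, [(31, 39), (52, 60)],
                  [(31, 39), (52, 60)])
    chrom = "A" * 100
    intron_rel = g.to_relative(45)
    assert annotate_consequence(intron_rel, "A", "G", g, chrom).effect == "intronic"
    assert annotate_consequence(-5, "A", "G", g, chrom).effect == "upstream"


def test_cds_indel_is_frameshift():
    g, chrom = _coding_gene("ATGGGTTAA")
    call = annotate_consequence(5, "G", "-", g, chrom)
    assert call.effect == "frameshift"


def test_position_beyond_span_errors():
    g, chrom = _coding_gene("ATGGGTTAA")
    with pytest.raises(ValueError):
        annotate_consequence(1000, "A", "G", g, chrom)


def test_consequence_matches_whole_cds_translation_oracle():
    """1,000 random single-base CDS substitutions vs translate-before/after."""
    rng = np.random.default_rng(21)
    n_done = 0
    while n_done < 1000:
        gene, chrom, protein = random_gene(rng)
        cds_positions = [p for s, e in gene.cds for p in range(s, e + 1)]
        for _ in range(10):
            gpos = int(cds_positions[rng.integers(len(cds_positions))])
            rel = gene.to_relative(gpos)
            cds = gene.spliced_cds(chrom)
            off = gene.cds_offset(gpos)
            ref = cds[off - 1]
            alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[ref]
            call = annotate_consequence(rel, ref, alt, gene, chrom)
            mutated = cds[: off - 1] + alt + cds[off:]
            aa_before = str(Seq(cds).translate())
            aa_after = str(Seq(mutated).translate())
            if aa_before == aa_after:
                assert call.effect == "synonymous"
            else:
                assert call.effect == "nonsynonymous"
                diff = [i for i, (x, y) in enumerate(zip(aa_before, aa_after))
                        if x != y]
                assert len(diff) == 1
                assert f"{diff[0] + 1}" in call.protein_change
            n_done += 1


# -- stability report ----------------------------------------------------

def test_stability_labels():
    assert stability_report(-708.44, -715.47) == (-7.03, "Stabilizing")
    assert stability_report(-700.0, -700.0) == (0.0, "Neutral")
    assert stability_report(-700.0, -690.0) == (10.0, "Destabilizing")
    with pytest.raises(ValueError):
        stability_report(float("nan"), 0.0)


# -- planted-truth recovery on the synthetic VCF -------------------------

def test_vcf_round_trip_and_trait_specific_recovery(bundle):
    sim, outdir = bundle
    records = alleles.read_vcf(outdir / "variants.vcf")
    kept = alleles.filter_variants(records)
    assert len(kept) < len(records)  # sub-threshold records planted
    found = {}
    for gid in sim.truth.family_ids:
        t = build_haplotype_table(kept, sim.genes[gid], GROUP1, GROUP2)
        flagged = classify_trait_specific(t)
        if flagged:
            found[gid] = sorted(flagged)
    assert found == {g: sorted(v) for g, v in sim.truth.trait_specific.items()}
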