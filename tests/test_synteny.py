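"""Collinear chaining, the exhaustive-search oracle, GCN, QTN proximity."""

import numpy as np
import pytest

from genefam.genome import GeneModel
from genefam.synteny import (AnchorHit, ChainParams, build_gcn, build_rank_index,
                             chain_collinear, csb_census, filter_family_blocks,
                             gcn_components, parse_qtn_id, qtn_proximity)


def _indexes(n_a=40, n_b=40):
    idx_a = {f"a{i}": ("A1", i) for i in range(n_a)}
    idx_b = {f"b{i}": ("B1", i) for i in range(n_b)}
    return idx_a, idx_b


def _hits(pairs):
    return [AnchorHit(a, b, 1e-20, 100.0) for a, b in pairs]


# -- basic chaining ------------------------------------------------------

def test_perfect_diagonal_is_one_plus_block():
    idx_a, idx_b = _indexes()
    blocks = chain_collinear(_hits([(f"a{i}", f"b{i}") for i in range(5)]),
                             idx_a, idx_b)
    assert len(blocks) == 1
    assert blocks[0].size == 5 and blocks[0].orientation == "plus"
    assert blocks[0].score == pytest.approx(250.0)


def test_perfect_antidiagonal_is_one_minus_block():
    idx_a, idx_b = _indexes()
    blocks = chain_collinear(_hits([(f"a{i}", f"b{9 - i}") for i in range(5)]),
                             idx_a, idx_b)
    assert len(blocks) == 1 and blocks[0].orientation == "minus"


@pytest.mark.parametrize("gap,expect_block", [(25, True), (26, False)])
def test_internal_gap_boundary(gap, expect_block):
    """A rank gap of 25 intervening genes chains; 26 breaks the chain."""
    idx_a, idx_b = _indexes(80, 80)
    pairs = [(f"a{i}", f"b{i}") for i in range(4)]
    pairs.append((f"a{4 + gap}", f"b{4 + gap}"))
    blocks = chain_collinear(_hits(pairs), idx_a, idx_b)
    assert (len(blocks) == 1) is expect_block
    if expect_block:
        assert blocks[0].size == 5
        # 50 * 5 anchors - 1 * (25 + 25) intervening genes
        assert blocks[0].score == pytest.approx(200.0)


def test_short_chain_not_emitted():
    idx_a, idx_b = _indexes()
    blocks = chain_collinear(_hits([(f"a{i}", f"b{i}") for i in range(4)]),
                             idx_a, idx_b)
    assert blocks == []


def test_unknown_gene_raises_with_ids():
    idx_a, idx_b = _indexes(3, 3)
    with pytest.raises(KeyError, match="ghost"):
        chain_collinear(_hits([("ghost", "b0")]), idx_a, idx_b)


def test_reversing_genome_b_swaps_orientations():
    # the two chains are separated by > max_gaps ranks in both genomes so
    # they cannot legally bridge into one chain
    idx_a, idx_b = _indexes(100, 100)
    pairs = [(f"a{i}", f"b{i}") for i in range(6)] + \
        [(f"a{60 + i}", f"b{95 - i}") for i in range(6)]
    fwd = chain_collinear(_hits(pairs), idx_a, idx_b)
    rev_b = {g: (c, 99 - r) for g, (c, r) in idx_b.items()}
    rev = chain_collinear(_hits(pairs), idx_a, rev_b)
    assert len(fwd) == len(rev) == 2
    assert sorted(b.orientation for b in fwd) == ["minus", "plus"]
    assert sorted(b.orientation for b in rev) == ["minus", "plus"]
    key = lambda b: sorted(a for a, _ in b.anchors)
    fwd_by = {tuple(key(b)): b.orientation for b in fwd}
    rev_by = {tuple(key(b)): b.orientation for b in rev}
    for k, o in fwd_by.items():
        assert rev_by[k] != o


# -- exhaustive oracle ---------------------------------------------------

def _exhaustive_best(anchors, params):
    """Maximum chain score over all legal chains (both directions)."""
    best = {"score": None, "size": 0}
    gmax = params.max_gaps + 1

    def extend(chain_end, score, size, direction, order):
        nonlocal best
        if size >= params.match_size and score > 0:
            if best["score"] is None or score > best["score"]:
                best = {"score": score, "size": size}
        ra0, rb0 = order[chain_end][:2]
        for j in range(len(order)):
            ra, rb = order[j][:2]
            da = ra - ra0
            db = (rb - rb0) * direction
            if 1 <= da <= gmax and 1 <= db <= gmax:
                extend(j, score + params.match_score
                       + params.gap_penalty * ((da - 1) + (db - 1)),
                       size + 1, direction, order)

    order = sorted(anchors)
    for direction in (1, -1):
        for i in range(len(order)):
            extend(i, params.match_score, 1, direction, order)
    return best


def test_chaining_equals_exhaustive_search_on_random_instances():
    """Top chain equals brute-force maximal-chain search, 500 random
    instances with up to 12 anchors."""
    rng = np.random.default_rng(17)
    params = ChainParams(match_size=3, max_gaps=5)
    for _ in range(500):
        n = int(rng.integers(2, 13))
        ra = rng.choice(30, size=n, replace=False)
        rb = rng.choice(30, size=n, replace=False)
        anchors = sorted(zip(ra.tolist(), rb.tolist()))
        idx_a = {f"a{r}": ("A1", r) for r, _ in anchors}
        idx_b = {f"b{r}": ("B1", r) for _, r in anchors}
        hits = _hits([(f"a{x}", f"b{y}") for x, y in anchors])
        blocks = chain_collinear(hits, idx_a, idx_b, params=params)
        oracle = _exhaustive_best([(x, y) for x, y in anchors], params)
        if oracle["score"] is None:
            assert blocks == []
        else:
            assert blocks, f"oracle found a chain of score {oracle['score']}"
            top = max(b.score for b in blocks)
            assert top == pytest.approx(oracle["score"])


def test_every_block_is_rank_monotone(bundle):
    sim, outdir = bundle
    from genefam import synteny
    from genefam.genome import read_gff3

    genes = read_gff3(outdir / "genes.gff3")
    idx = build_rank_index(genes)
    hits = synteny.read_hits(outdir / "homolog_hits.tsv")
    blocks = chain_collinear(hits, idx, idx, "self", "self")
    assert blocks
    for b in blocks:
        ras = [idx[a][1] for a, _ in b.anchors]
        rbs = [idx[x][1] for _, x in b.anchors]
        assert ras == sorted(ras) and len(set(ras)) == len(ras)
        ordered = sorted(rbs) if b.orientation == "plus" else sorted(rbs, reverse=True)
        assert rbs == ordered and len(set(rbs)) == len(rbs)


# -- family filtering and GCN -------------------------------------------

def _block(anchors, species=("self", "self"), chroms=("A1", "B1"),
           orientation="plus", score=250.0):
    from genefam.synteny import CollinearBlock
    return CollinearBlock(species[0], species[1], chroms[0], chroms[1],
                          anchors, orientation, score)


def test_family_filter():
    b1 = _block([("x", "y"), ("u", "v")])
    b2 = _block([("p", "q")])
    assert filter_family_blocks([b1, b2], {"u"}) == [b1]
    assert filter_family_blocks([b1, b2], {"nope"}) == []


def test_gcn_components_from_blocks():
    b1 = _block([("f1", "f2"), ("x", "y")])
    b2 = _block([("f2", "f3")])
    b3 = _block([("f4", "f5")])
    g = build_gcn([b1, b2, b3], {"f1", "f2", "f3", "f4", "f5"})
    comps = gcn_components(g)
    assert [sorted(c) for c in comps] == [["f1", "f2", "f3"], ["f4", "f5"]]


def test_gcn_invariant_to_block_order():
    rng = np.random.default_rng(3)
    blocks = [_block([(f"f{i}", f"f{i + 1}")]) for i in range(6)]
    fam = {f"f{i}" for i in range(8)}
    base = [len(c) for c in gcn_components(build_gcn(blocks, fam))]
    for _ in range(5):
        perm = [blocks[i] for i in rng.permutation(len(blocks))]
        assert [len(c) for c in gcn_components(build_gcn(perm, fam))] == base


def test_gcn_recovers_planted_duplication_groups(pipeline_out):
    sim, out, _ = pipeline_out
    comps = gcn_components(out["gcn"])
    want = sorted((set(g) for g in sim.truth.duplication_groups),
                  key=lambda s: (-len(s), sorted(s)[0]))
    assert comps == want


# -- QTN proximity -------------------------------------------------------

def _span(gid, chrom, start, end):
    return GeneModel(gid, chrom, "+", start, end, [(start, end)], [(start, end)])


def test_qtn_distance_rules():
    genes = {"g": _span("g", "Lu11", 3_000_000, 3_500_000)}
    inside = qtn_proximity(genes, ["Lu11_3283122"])
    assert inside.distance_bp.iloc[0] == 0
    at_window = qtn_proximity(genes, ["Lu11_4500000"])
    assert at_window.distance_bp.iloc[0] == 1_000_000  # inclusive boundary
    assert at_window.distance_mb.iloc[0] == 1.0
    beyond = qtn_proximity(genes, ["Lu11_4500001"])
    assert beyond.empty
    other_chrom = qtn_proximity(genes, ["Lu12_3000000"])
    assert other_chrom.empty


def test_malformed_qtn_id():
    with pytest.raises(ValueError):
        parse_qtn_id("no-position")


def test_csb_census_counts_and_orientations():
    blocks = [_block([("a", "b")] * 5, orientation="plus")] * 3 + \
        [_block([("a", "b")] * 7, orientation="minus")] * 2
    tab = csb_census(blocks)
    row = tab.iloc[0]
    assert row.n_blocks == 5 and row.plus == 3 and row.minus == 2
    assert row.min_size == 5 and row.max_size == 7
    assert csb_census([]).empty
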