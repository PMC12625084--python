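"""Collinear-block detection, syntenic gene networks, and QTN proximity.

Blocks are chains of homologous gene pairs (anchors) whose gene-order ranks
increase in genome A and increase (plus orientation) or decrease (minus)
in genome B.  Chaining follows the classical MCScanX parameterization:
anchors at e-value <= 1e-5, top five hits per query, chains of at least
five anchors, rank gaps of at most 25 intervening genes, chain score =
50 per anchor minus 1 per intervening gene, and an overlap window of five
genes within which stray anchors are absorbed into an emitted block instead
of seeding duplicates.

Family-filtered blocks feed a gene collinearity network (GCN): nodes are
family genes, edges are family-gene anchor pairs, and connected components
group anciently duplicated copies.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .genome import GeneModel

__all__ = [
    "ChainParams",
    "AnchorHit",
    "CollinearBlock",
    "build_rank_index",
    "read_hits",
    "chain_collinear",
    "filter_family_blocks",
    "build_gcn",
    "gcn_components",
    "qtn_proximity",
    "parse_qtn_id",
    "csb_census",
]


@dataclass(frozen=True)
class ChainParams:
    e_max: float = 1e-5
    top_k: int = 5
    match_size: int = 5
    max_gaps: int = 25
    match_score: float = 50.0
    gap_penalty: float = -1.0
    overlap_window: int = 5


@dataclass(frozen=True)
class AnchorHit:
    gene_a: str
    gene_b: str
    evalue: float = 0.0
    bitscore: float = 0.0


@dataclass
class CollinearBlock:
    species_a: str
    species_b: str
    chrom_a: str
    chrom_b: str
    anchors: list[tuple[str, str]]  # (gene_a, gene_b) in chain order
    orientation: str  # 'plus' | 'minus'
    score: float
    merged: list[tuple[str, str]] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.anchors)

    def genes(self) -> set[str]:
        out = set()
        for a, b in self.anchors:
            out.add(a)
            out.add(b)
        return out


def build_rank_index(genes: dict[str, GeneModel]) -> dict[str, tuple[str, int]]:
    """gene id -> (chromosome, dense rank by start coordinate)."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes.values():
        by_chrom.setdefault(g.chrom, []).append(g)
    idx = {}
    for chrom, gs in by_chrom.items():
        for rank, g in enumerate(sorted(gs, key=lambda x: (x.start, x.gene_id))):
            idx[g.gene_id] = (chrom, rank)
    return idx


def read_hits(path) -> list[AnchorHit]:
    """Read a (query, subject, evalue, bitscore) TSV (BLAST outfmt-6 subset)."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["query", "subject", "evalue", "bitscore"], header=0)
    return [AnchorHit(r.query, r.subject, float(r.evalue), float(r.bitscore))
            for r in df.itertuples(index=False)]


def _prefilter(hits: list[AnchorHit], params: ChainParams) -> list[AnchorHit]:
    by_query: dict[str, list[AnchorHit]] = {}
    for h in hits:
        if h.evalue <= params.e_max and h.gene_a != h.gene_b:
            by_query.setdefault(h.gene_a, []).append(h)
    kept = []
    for q, hs in by_query.items():
        hs.sort(key=lambda h: (h.evalue, -h.bitscore, h.gene_b))
        kept.extend(hs[: params.top_k])
    return kept


def _best_chain(anchors, direction, params):
    """Max-score chain by DP over anchors sorted by rank in genome A.

    ``anchors`` are (ra, rb, gene_a, gene_b) tuples; a transition is legal
    when both rank gaps lie in [1, max_gaps + 1] and genome-B ranks move in
    ``direction``.  Returns (score, [indices]) or (None, []).
    """
    n = len(anchors)
    if n == 0:
        return None, []
    order = sorted(range(n), key=lambda i: (anchors[i][0], anchors[i][1]))
    best_score = [params.match_score] * n
    best_len = [1] * n
    parent = [-1] * n
    gmax = params.max_gaps + 1
    for oi, i in enumerate(order):
        ra_i, rb_i = anchors[i][0], anchors[i][1]
        for j in (order[k] for k in range(oi)):
            ra_j, rb_j = anchors[j][0], anchors[j][1]
            da = ra_i - ra_j
            db = (rb_i - rb_j) * direction
            if 1 <= da <= gmax and 1 <= db <= gmax:
                cand = best_score[j] + params.match_score + \
                    params.gap_penalty * ((da - 1) + (db - 1))
                better = cand > best_score[i] + 1e-12
                tied_longer = abs(cand - best_score[i]) <= 1e-12 and \
                    best_len[j] + 1 > best_len[i]
                if better or tied_longer:
                    best_score[i] = cand
                    best_len[i] = best_len[j] + 1
                    parent[i] = j
    # score ties resolved toward the longer chain
    end = max(range(n),
              key=lambda i: (best_score[i], best_len[i], -anchors[i][0]))
    chain = []
    i = end
    while i != -1:
        chain.append(i)
        i = parent[i]
    chain.reverse()
    return best_score[end], chain


def chain_collinear(
    hits: list[AnchorHit],
    idx_a: dict[str, tuple[str, int]],
    idx_b: dict[str, tuple[str, int]],
    species_a: str = "A",
    species_b: str = "B",
    params: ChainParams = ChainParams(),
) -> list[CollinearBlock]:
    """Detect collinear blocks between two rank-indexed genomes.

    Within each chromosome pair, the highest-scoring chain (plus or minus
    direction) is extracted repeatedly; chains of at least ``match_size``
    anchors with positive score become blocks, and unused anchors within
    ``overlap_window`` ranks of an emitted block are absorbed into it.
    For an intra-genome comparison pass the same index twice: mirror
    anchors and the self-diagonal are removed automatically.
    """
    intra = idx_a is idx_b or (species_a == species_b)
    missing = sorted({h.gene_a for h in hits if h.gene_a not in idx_a} |
                     {h.gene_b for h in hits if h.gene_b not in idx_b})
    if missing:
        raise KeyError(f"genes in hit table absent from rank index: {missing}")
    groups: dict[tuple[str, str], list] = {}
    for h in _prefilter(hits, params):
        ca, ra = idx_a[h.gene_a]
        cb, rb = idx_b[h.gene_b]
        if intra and (ca, ra) >= (cb, rb):
            continue  # keep one of each mirror pair; drop self-diagonal
        groups.setdefault((ca, cb), []).append((ra, rb, h.gene_a, h.gene_b))

    blocks: list[CollinearBlock] = []
    for (ca, cb), anchors in sorted(groups.items()):
        anchors = sorted(set(anchors))
        active = list(anchors)
        while True:
            best = None
            for direction, label in ((1, "plus"), (-1, "minus")):
                score, chain = _best_chain(active, direction, params)
                if score is None or len(chain) < params.match_size or score <= 0:
                    continue
                if best is None or score > best[0]:
                    best = (score, chain, label)
            if best is None:
                break
            score, chain, label = best
            chosen = [active[i] for i in chain]
            block = CollinearBlock(
                species_a, species_b, ca, cb,
                anchors=[(g_a, g_b) for _, _, g_a, g_b in chosen],
                orientation=label, score=score,
            )
            used = set(chain)
            ow = params.overlap_window
            for i, anc in enumerate(active):
                if i in used:
                    continue
                for ra, rb, _, _ in chosen:
                    if abs(anc[0] - ra) <= ow and abs(anc[1] - rb) <= ow:
                        block.merged.append((anc[2], anc[3]))
                        used.add(i)
                        break
            blocks.append(block)
            active = [a for i, a in enumerate(active) if i not in used]
    return blocks


def filter_family_blocks(
    blocks: list[CollinearBlock], family_ids: set[str]
) -> list[CollinearBlock]:
    """Blocks containing at least one family gene among their anchors."""
    fam = set(family_ids)
    return [b for b in blocks if b.genes() & fam]


def build_gcn(
    blocks: list[CollinearBlock],
    family_ids: set[str],
    include_co_membership: bool = False,
) -> nx.Graph:
    """Gene collinearity network over family genes.

    Nodes are family genes appearing in the given blocks; an edge joins two
    family genes that form an anchor pair in at least one block.  With
    ``include_co_membership=True``, family genes co-occurring in a block are
    also joined even without a direct anchor pair.
    """
    fam = set(family_ids)
    g = nx.Graph()
    for bi, b in enumerate(sorted(blocks, key=lambda b: (b.chrom_a, b.chrom_b, -b.score))):
        members = []
        for x, y in [*b.anchors, *b.merged]:
            for node in (x, y):
                if node in fam:
                    g.add_node(node)
                    g.nodes[node].setdefault("blocks", []).append(bi)
                    members.append(node)
            if x in fam and y in fam:
                g.add_edge(x, y)
        if include_co_membership:
            uniq = sorted(set(members))
            for i in range(len(uniq)):
                for j in range(i + 1, len(uniq)):
                    g.add_edge(uniq[i], uniq[j])
    return g


def gcn_components(g: nx.Graph) -> list[set[str]]:
    """Connected components, largest first (ties by smallest member id)."""
    comps = [set(c) for c in nx.connected_components(g)]
    return sorted(comps, key=lambda c: (-len(c), sorted(c)[0]))


# -- QTN proximity -------------------------------------------------------

_QTN_RE = re.compile(r"^(?P<chrom>.+)_(?P<pos>\d+)$")


def parse_qtn_id(locus_id: str) -> tuple[str, int]:
    """'<chromosome>_<position>' -> (chromosome, 1-based position)."""
    m = _QTN_RE.match(locus_id)
    if m is None:
        raise ValueError(f"malformed QTN locus id {locus_id!r}")
    pos = int(m.group("pos"))
    if pos < 1:
        raise ValueError(f"QTN position must be >= 1 in {locus_id!r}")
    return m.group("chrom"), pos


def qtn_proximity(
    genes: dict[str, GeneModel],
    loci: list[str],
    window_bp: int = 1_000_000,
) -> pd.DataFrame:
    """(gene, locus) pairs within ``window_bp`` (inclusive) of each other.

    Distance is 0 when the locus falls inside the gene span, else the gap to
    the nearest span boundary; also reported in Mb at two decimals.
    """
    rows = []
    for locus in loci:
        chrom, pos = parse_qtn_id(locus)
        for gid, g in genes.items():
            if g.chrom != chrom:
                continue
            if g.start <= pos <= g.end:
                d = 0
            else:
                d = min(abs(pos - g.start), abs(pos - g.end))
            if d <= window_bp:
                rows.append({"gene_id": gid, "locus_id": locus,
                             "distance_bp": d,
                             "distance_mb": round(d / 1e6, 2)})
    return pd.DataFrame(rows, columns=["gene_id", "locus_id",
                                       "distance_bp", "distance_mb"])


def csb_census(blocks: list[CollinearBlock]) -> pd.DataFrame:
    """Per species-pair block counts, size range, and orientation split."""
    rows: dict[tuple[str, str], dict] = {}
    for b in blocks:
        key = tuple(sorted((b.species_a, b.species_b)))
        d = rows.setdefault(key, {"species_a": key[0], "species_b": key[1],
                                  "n_blocks": 0, "min_size": None,
                                  "max_size": None, "plus": 0, "minus": 0})
        d["n_blocks"] += 1
        sz = b.size
        d["min_size"] = sz if d["min_size"] is None else min(d["min_size"], sz)
        d["max_size"] = sz if d["max_size"] is None else max(d["max_size"], sz)
        d[b.orientation] += 1
    cols = ["species_a", "species_b", "n_blocks", "min_size", "max_size",
            "plus", "minus"]
    return pd.DataFrame(sorted(rows.values(),
                               key=lambda d: (d["species_a"], d["species_b"])),
                        columns=cols)
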