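"""Synthetic genome bundles with planted ground truth.

The generator emulates every input the pipeline consumes — genome FASTA,
GFF3 gene models, protein FASTA, domain-hit and homolog-hit tables, a VCF of
phenotype-grouped accessions, a TPM expression matrix, and a PWM collection
— for a toy diploid-crop genome of ~1,000 genes carrying a planted
multi-paralog gene family.  Ground truth (family membership, paralog pairs,
trait-specific variant positions, planted motifs, duplicated-segment blocks,
expression modules) is recorded so every downstream stage can be checked for
exact recovery at zero noise.

Randomness discipline: one integer seed drives one named RNG stream per
output type (genome, variants, expression, motifs, hits), so adding an
output does not shift the others.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Data import CodonTable

from .genome import GeneModel, reverse_complement, write_fasta, write_gff3
from .promoters import PositionWeightMatrix, write_jaspar

__all__ = [
    "DuplicatedSegment",
    "PlantedMotif",
    "ExpressionModule",
    "SimConfig",
    "SimTruth",
    "SimulatedGenome",
    "simulate_genome",
    "simulate_variants",
    "simulate_expression",
    "generate_pwms",
    "plant_promoter_motifs",
    "simulate_bundle",
    "write_bundle",
]

_BASES = np.array(list("ACGT"))
_AA = "ACDEFGHIKLMNPQRSTVWY"

# 30-residue signature planted in every family protein; the domain-hit table
# reports the synthase and phosphatase-like domains over its two halves.
FAMILY_SIGNATURE = "WHDYHLMLVPKMLREEWRGAKVGFFLHTPF"
REQUIRED_DOMAINS = ("Glyco_transf_20", "Trehalose_PPase")

_STREAMS = ("genome", "variants", "expression", "motifs", "hits")


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([seed, _STREAMS.index(stream)])


# -- configuration -------------------------------------------------------


@dataclass(frozen=True)
class DuplicatedSegment:
    """One copy operation of a backbone gene-index range."""

    chrom: str
    start_idx: int  # inclusive backbone gene index on `chrom`
    end_idx: int    # inclusive
    orientation: str = "+"  # '-' copies the gene order reversed
    loss_rate: float = 0.0
    dest_chrom: str | None = None  # appended to this chromosome


@dataclass(frozen=True)
class PlantedMotif:
    motif_id: str
    family_rate: float
    background_rate: float


@dataclass(frozen=True)
class ExpressionModule:
    genes: tuple[str, ...]
    r_target: float
    noise_sd: float


@dataclass
class SimConfig:
    seed: int = 0
    n_chromosomes: int = 5
    genes_per_chromosome: int = 200
    family_size: int = 18
    n_paralog_pairs: int = 9
    promoter_length: int = 2000
    gc_content: float = 0.5
    planted_motifs: list[PlantedMotif] = field(
        default_factory=lambda: [PlantedMotif("M001", 1.0, 0.02)])
    group1: tuple[str, ...] = ("EC0115148", "EC0718827")   # late flowering
    group2: tuple[str, ...] = ("IC0523807", "IC0525939")   # early flowering
    n_trait_specific_variants: int = 3
    n_random_variants: int = 40
    missing_rate: float = 0.0
    gap_rate: float = 0.0
    expression_modules: list[ExpressionModule] | None = None
    duplicated_segments: list[DuplicatedSegment] | None = None
    n_pwms: int = 50
    pwm_width: int = 8
    protein_length: int = 120
    segment_size: int = 10
    intergenic_len: int = 2200
    tissues: tuple[str, ...] = ("bud1", "bud2", "flower", "leaf", "stem")

    def __post_init__(self) -> None:
        for r in (self.gc_content, self.missing_rate, self.gap_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        for pm in self.planted_motifs:
            if not (0 <= pm.family_rate <= 1 and 0 <= pm.background_rate <= 1):
                raise ValueError("motif insertion rates must lie in [0, 1]")
        if self.family_size < 1:
            raise ValueError("family_size must be >= 1")
        if set(self.group1) & set(self.group2):
            raise ValueError("accession groups must not overlap")
        if len(self.group1) < 2 or len(self.group2) < 2:
            raise ValueError("need >= 2 accessions per group")
        if self.duplicated_segments is not None:
            by_chrom: dict[str, list[tuple[int, int]]] = {}
            seen = set()
            for s in self.duplicated_segments:
                key = (s.chrom, s.start_idx, s.end_idx)
                if key not in seen:
                    for lo, hi in by_chrom.get(s.chrom, []):
                        if not (s.end_idx < lo or s.start_idx > hi):
                            raise ValueError(
                                f"duplicated segments overlap on {s.chrom}")
                    by_chrom.setdefault(s.chrom, []).append(
                        (s.start_idx, s.end_idx))
                    seen.add(key)

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]


def _default_layout(cfg: SimConfig) -> tuple[list[list[DuplicatedSegment]], list[int]]:
    """Default duplication layout: up to four source segments whose copy
    counts partition ``family_size`` (18 -> 6/4/4/4)."""
    n_groups = min(4, cfg.family_size)
    q = cfg.family_size // n_groups if n_groups else 0
    counts = [cfg.family_size - q * (n_groups - 1)] + [q] * (n_groups - 1)
    chroms = cfg.chrom_names
    groups = []
    for gi, total_copies in enumerate(counts):
        src = chroms[gi % len(chroms)]
        lo = 10 + (cfg.segment_size + 30) * (gi // len(chroms))
        if lo + cfg.segment_size - 1 >= cfg.genes_per_chromosome:
            raise ValueError(
                "genes_per_chromosome too small for the default duplication "
                "layout; provide duplicated_segments explicitly")
        seg = [DuplicatedSegment(src, lo, lo + cfg.segment_size - 1, "+", 0.0, src)]
        for ci in range(total_copies - 1):
            orient = "-" if (gi + ci) % 3 == 1 else "+"
            dest = chroms[(gi + ci + 1) % len(chroms)]
            seg.append(DuplicatedSegment(src, lo, lo + cfg.segment_size - 1,
                                         orient, 0.0, dest))
        groups.append(seg)
    return groups, counts


# -- truth ---------------------------------------------------------------


@dataclass
class SimTruth:
    family_ids: list[str] = field(default_factory=list)
    paralog_pairs: list[tuple[str, str]] = field(default_factory=list)
    reference_of: dict[str, str] = field(default_factory=dict)
    trait_specific: dict[str, list[int]] = field(default_factory=dict)
    filtered_positions: list[int] = field(default_factory=list)
    planted_motif_ids: list[str] = field(default_factory=list)
    motif_positions: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    blocks: list[dict] = field(default_factory=list)
    duplication_groups: list[list[str]] = field(default_factory=list)
    expression_modules: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=list)


# -- genome construction -------------------------------------------------

_BACK_TABLE: dict[str, list[str]] = {}
for _codon, _aa in CodonTable.standard_dna_table.forward_table.items():
    _BACK_TABLE.setdefault(_aa, []).append(_codon)
for _aa in _BACK_TABLE:
    _BACK_TABLE[_aa].sort()


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def _random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_AA), size=n))


def _reverse_translate(rng: np.random.Generator, protein: str) -> str:
    codons = [_BACK_TABLE[a][rng.integers(len(_BACK_TABLE[a]))] for a in protein]
    return "".join(codons) + "TAA"


@dataclass
class _GenePlan:
    gene_id: str
    protein: str
    strand: str
    is_family: bool = False
    group: int | None = None  # duplication-group index for family genes


@dataclass
class SimulatedGenome:
    genome: dict[str, str]
    genes: dict[str, GeneModel]
    proteins: dict[str, str]
    references: dict[str, str]  # reference-species family proteins
    domain_hits: list[tuple[str, str, float, int, int]]
    homolog_hits: list[tuple[str, str, float, float]]
    pwms: list[PositionWeightMatrix]
    truth: SimTruth
    config: SimConfig


def _mutate(rng: np.random.Generator, protein: str, n_mut: int,
            protect: int) -> str:
    """Apply ``n_mut`` random substitutions outside the first ``protect``
    residues."""
    seq = list(protein)
    sites = rng.choice(len(seq) - protect, size=n_mut, replace=False) + protect
    for s in sites:
        choices = [a for a in _AA if a != seq[s]]
        seq[s] = choices[rng.integers(len(choices))]
    return "".join(seq)


def simulate_genome(cfg: SimConfig) -> SimulatedGenome:
    """Build the toy genome, gene models, proteins and hit tables.

    Family members are planted inside duplicated segments; each duplication
    group descends from one ancestral family protein, and within a group the
    copies are paired (one private mutation inside a pair, several between
    pairs) so paralog pairs are mutual nearest neighbors.
    """
    rng = _rng(cfg.seed, "genome")
    if cfg.duplicated_segments is None:
        groups, counts = _default_layout(cfg)
    else:
        # group segment definitions by source range
        keyed: dict[tuple, list[DuplicatedSegment]] = {}
        for s in cfg.duplicated_segments:
            keyed.setdefault((s.chrom, s.start_idx, s.end_idx), []).append(s)
        groups = list(keyed.values())
        counts = [len(g) for g in groups]
    if sum(c // 2 for c in counts) != cfg.n_paralog_pairs:
        raise ValueError(
            f"duplication layout yields {sum(c // 2 for c in counts)} paralog "
            f"pairs, config says {cfg.n_paralog_pairs}")
    if sum(counts) != cfg.family_size:
        raise ValueError(
            f"duplication layout yields {sum(counts)} family members, "
            f"config says {cfg.family_size}")

    # ancestral family proteins, one per duplication group
    plen = cfg.protein_length
    ancestors = []
    for gi in range(len(groups)):
        core = _random_protein(rng, plen - len(FAMILY_SIGNATURE) - 1)
        ancestors.append("M" + FAMILY_SIGNATURE + core)
    references = {f"RefTPS{gi + 1}": _mutate(rng, anc, 4, len(FAMILY_SIGNATURE) + 1)
                  for gi, anc in enumerate(ancestors)}

    # per-copy family proteins with paired mutation structure
    family_variants: list[list[str]] = []
    for gi, (anc, c) in enumerate(zip(ancestors, counts)):
        protect = len(FAMILY_SIGNATURE) + 1
        variants = []
        for pair_i in range((c + 1) // 2):
            # increasing distance-to-ancestor per pair keeps suffix ranks of
            # a pair consecutive; one private mutation separates pair members
            shared = _mutate(rng, anc, 4 * (pair_i + 1), protect)
            variants.append(_mutate(rng, shared, 1, protect))
            if len(variants) < c:
                variants.append(_mutate(rng, shared, 1, protect))
        family_variants.append(variants[:c])

    # backbone gene plans
    plans: dict[str, list[_GenePlan]] = {c: [] for c in cfg.chrom_names}
    for ci, chrom in enumerate(cfg.chrom_names):
        for gi in range(cfg.genes_per_chromosome):
            gid = f"{chrom}g{gi + 1:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            n = int(rng.integers(80, 151))
            plans[chrom].append(_GenePlan(gid, _random_protein(rng, n), strand))

    # install family originals at segment midpoints and plan copies
    truth = SimTruth()
    copy_plans: dict[str, list[_GenePlan]] = {c: [] for c in cfg.chrom_names}
    homologs: set[tuple[str, str]] = set()  # all duplicate gene pairs
    n_spacers = 0
    group_members: list[list[str]] = [[] for _ in groups]
    block_specs = []
    for gi, segs in enumerate(groups):
        src = segs[0]
        slot = src.start_idx + (src.end_idx - src.start_idx) // 2
        fam_variants = family_variants[gi]
        copies_genes: list[list[str]] = []
        copies_orient: list[str] = []
        copies_chrom: list[str] = []
        # original segment: replace slot protein by family variant 0
        orig_ids = [plans[src.chrom][k].gene_id
                    for k in range(src.start_idx, src.end_idx + 1)]
        slot_plan = plans[src.chrom][slot]
        plans[src.chrom][slot] = _GenePlan(slot_plan.gene_id, fam_variants[0],
                                           slot_plan.strand, True, gi)
        group_members[gi].append(slot_plan.gene_id)
        copies_genes.append(orig_ids)
        copies_orient.append("+")
        copies_chrom.append(src.chrom)
        # copies
        for ci, seg in enumerate(segs[1:], start=1):
            dest = seg.dest_chrom or cfg.chrom_names[
                (cfg.chrom_names.index(seg.chrom) + ci) % cfg.n_chromosomes]
            idxs = list(range(seg.start_idx, seg.end_idx + 1))
            if seg.orientation == "-":
                idxs = idxs[::-1]
            if copy_plans[dest]:
                # spacer genes keep separately planted segment copies from
                # chaining into one block (spacer > the max_gaps default)
                for _ in range(30):
                    n_spacers += 1
                    n = int(rng.integers(80, 151))
                    copy_plans[dest].append(
                        _GenePlan(f"spacer{n_spacers:04d}",
                                  _random_protein(rng, n),
                                  "+" if rng.random() < 0.5 else "-"))
            new_ids = []
            for k in idxs:
                base = plans[seg.chrom][k]
                if seg.loss_rate > 0 and not base.is_family and \
                        rng.random() < seg.loss_rate:
                    continue
                nid = f"{base.gene_id}_c{ci}"
                strand = base.strand if seg.orientation == "+" else \
                    ("-" if base.strand == "+" else "+")
                if base.is_family:
                    prot = fam_variants[ci]
                    plan = _GenePlan(nid, prot, strand, True, gi)
                    group_members[gi].append(nid)
                else:
                    plan = _GenePlan(nid, base.protein, strand)
                new_ids.append(nid)
                copy_plans[dest].append(plan)
            copies_genes.append(new_ids)
            copies_orient.append(seg.orientation)
            copies_chrom.append(dest)
        # homology between every pair of copies of the same origin gene
        origin_maps = [{g.split("_c")[0]: g for g in ids} for ids in copies_genes]
        for i in range(len(origin_maps)):
            for j in range(i + 1, len(origin_maps)):
                for origin in sorted(set(origin_maps[i]) & set(origin_maps[j])):
                    homologs.add((origin_maps[i][origin], origin_maps[j][origin]))
        for i in range(len(copies_genes)):
            for j in range(i + 1, len(copies_genes)):
                n_shared = len(set(g.split("_c")[0] for g in copies_genes[i]) &
                               set(g.split("_c")[0] for g in copies_genes[j]))
                block_specs.append({
                    "group": gi,
                    "chrom_a": copies_chrom[i], "chrom_b": copies_chrom[j],
                    "size": n_shared,
                    "orientation": "plus" if copies_orient[i] == copies_orient[j]
                    else "minus",
                })
    truth.blocks = block_specs
    truth.duplication_groups = group_members
    truth.family_ids = sorted(g for grp in group_members for g in grp)
    truth.reference_of = {g: f"RefTPS{gi + 1}"
                          for gi, grp in enumerate(group_members) for g in grp}
    for gi, grp in enumerate(group_members):
        for k in range(0, len(grp) - 1, 2):
            truth.paralog_pairs.append((grp[k], grp[k + 1]))

    # assemble chromosomes
    genome: dict[str, str] = {}
    genes: dict[str, GeneModel] = {}
    proteins: dict[str, str] = {}
    for chrom in cfg.chrom_names:
        parts: list[str] = []
        offset = 0
        for plan in plans[chrom] + copy_plans[chrom]:
            inter = _random_dna(rng, cfg.intergenic_len, cfg.gc_content)
            cds = _reverse_translate(rng, plan.protein)
            # split coding sequence into 2-3 exons with random introns
            n_exons = int(rng.integers(2, 4))
            cuts = sorted(rng.choice(np.arange(3, len(cds) - 3, 3),
                                     size=n_exons - 1, replace=False))
            pieces = [cds[a:b] for a, b in
                      zip([0, *cuts], [*cuts, len(cds)])]
            exon_rel: list[tuple[int, int]] = []
            body = ""
            for pi, piece in enumerate(pieces):
                if pi:
                    body += _random_dna(rng, int(rng.integers(60, 91)),
                                        cfg.gc_content)
                exon_rel.append((len(body), len(body) + len(piece) - 1))
                body += piece
            if plan.strand == "-":
                L = len(body)
                exon_rel = [(L - 1 - e, L - 1 - s) for s, e in exon_rel][::-1]
                body = reverse_complement(body)
            parts.append(inter)
            offset += len(inter)
            gstart = offset + 1
            exons = [(gstart + s, gstart + e) for s, e in exon_rel]
            genes[plan.gene_id] = GeneModel(
                plan.gene_id, chrom, plan.strand,
                gstart, gstart + len(body) - 1, exons, list(exons))
            proteins[plan.gene_id] = plan.protein
            parts.append(body)
            offset += len(body)
        parts.append(_random_dna(rng, 500, cfg.gc_content))
        genome[chrom] = "".join(parts)

    # domain hits: both required domains for family proteins, decoys outside
    sig_len = len(FAMILY_SIGNATURE)
    domain_hits = []
    for fid in truth.family_ids:
        half = sig_len // 2
        domain_hits.append((fid, REQUIRED_DOMAINS[0], 1e-25, 2, 1 + half))
        domain_hits.append((fid, REQUIRED_DOMAINS[1], 1e-18, 2 + half, 1 + sig_len))
    non_family = sorted(set(proteins) - set(truth.family_ids))
    decoys = rng.choice(len(non_family), size=min(6, len(non_family)),
                        replace=False)
    for di, k in enumerate(decoys):
        pid = non_family[k]
        if di % 2 == 0:  # one required domain only
            domain_hits.append((pid, REQUIRED_DOMAINS[di % len(REQUIRED_DOMAINS)],
                                1e-12, 1, 30))
        else:  # both domains but above the e-value cutoff
            domain_hits.append((pid, REQUIRED_DOMAINS[0], 1e-3, 1, 15))
            domain_hits.append((pid, REQUIRED_DOMAINS[1], 5e-3, 16, 30))

    # homolog hit table (both directions) + deterministic noise hits
    hits_rng = _rng(cfg.seed, "hits")
    homolog_hits = []
    for a, b in sorted(homologs):
        homolog_hits.append((a, b, 1e-30, 200.0))
        homolog_hits.append((b, a, 1e-30, 200.0))
    # weak spurious hits above the e-value cutoff: exercise the filter
    # without perturbing the planted blocks
    all_ids = sorted(proteins)
    for _ in range(50):
        a, b = (all_ids[i] for i in hits_rng.choice(len(all_ids), 2,
                                                    replace=False))
        homolog_hits.append((a, b, 1e-3, 40.0))

    # PWM collection + motif planting into promoter windows
    motifs_rng = _rng(cfg.seed, "motifs")
    pwms = generate_pwms(cfg.n_pwms, cfg.pwm_width, motifs_rng)
    truth.planted_motif_ids = [pm.motif_id for pm in cfg.planted_motifs]
    _plant_in_genome(cfg, genome, genes, pwms, truth, motifs_rng)

    return SimulatedGenome(genome, genes, proteins, references, domain_hits,
                           homolog_hits, pwms, truth, cfg)


# -- promoter motif planting --------------------------------------------


def generate_pwms(n: int, width: int,
                  rng: np.random.Generator) -> list[PositionWeightMatrix]:
    """Random informative PWMs (one dominant base per position, p=0.85)."""
    out = []
    for i in range(n):
        probs = np.full((width, 4), 0.05)
        for k in range(width):
            probs[k, rng.integers(4)] = 0.85
        out.append(PositionWeightMatrix(f"M{i + 1:03d}", probs))
    return out


def plant_promoter_motifs(
    promoters: dict[str, str],
    family_ids: set[str],
    planted: list[PlantedMotif],
    pwms: dict[str, PositionWeightMatrix],
    rng: np.random.Generator,
) -> tuple[dict[str, str], dict[str, list[tuple[str, int]]]]:
    """Insert motif consensus sequences into promoters at the family or
    background rate; returns the modified promoters and insertion truth."""
    out = dict(promoters)
    positions: dict[str, list[tuple[str, int]]] = {}
    for gid in sorted(out):
        rate_key = "family" if gid in family_ids else "background"
        for pm in planted:
            rate = pm.family_rate if rate_key == "family" else pm.background_rate
            if rng.random() >= rate:
                continue
            cons = pwms[pm.motif_id].consensus()
            seq = out[gid]
            if len(cons) > len(seq):
                raise ValueError(
                    f"motif {pm.motif_id} longer than promoter of {gid}")
            pos = int(rng.integers(0, len(seq) - len(cons) + 1))
            out[gid] = seq[:pos] + cons + seq[pos + len(cons):]
            positions.setdefault(gid, []).append((pm.motif_id, pos))
    return out, positions


def _plant_in_genome(cfg, genome, genes, pwms, truth, rng) -> None:
    """Plant motif consensus copies inside the genomic promoter windows so
    downstream extraction recovers them."""
    pwm_by_id = {p.motif_id: p for p in pwms}
    windows = {}
    proms = {}
    for gid, g in genes.items():
        a = g.atg_pos
        chrom = genome[g.chrom]
        if g.strand == "+":
            lo = max(1, a - cfg.promoter_length)
            windows[gid] = (g.chrom, lo, a - 1, "+")
            proms[gid] = chrom[lo - 1: a - 1]
        else:
            hi = min(len(chrom), a + cfg.promoter_length)
            windows[gid] = (g.chrom, a + 1, hi, "-")
            proms[gid] = reverse_complement(chrom[a: hi])
    modified, positions = plant_promoter_motifs(
        proms, set(truth.family_ids), cfg.planted_motifs, pwm_by_id, rng)
    truth.motif_positions = positions
    chrom_lists = {c: list(s) for c, s in genome.items()}
    # write only the inserted consensus bases, so overlapping promoter
    # windows of neighboring genes cannot erase each other's insertions
    for gid, inserts in positions.items():
        chrom, lo, hi, strand = windows[gid]
        for motif_id, pos in inserts:
            cons = pwm_by_id[motif_id].consensus()
            w = len(cons)
            if strand == "+":
                gstart = lo + pos
                seg = cons
            else:
                gstart = hi - pos - w + 1
                seg = reverse_complement(cons)
            chrom_lists[chrom][gstart - 1: gstart - 1 + w] = list(seg)
    for c in chrom_lists:
        genome[c] = "".join(chrom_lists[c])


# -- variants ------------------------------------------------------------


def simulate_variants(cfg: SimConfig, sim: SimulatedGenome) -> list[dict]:
    """Plant trait-specific and rule-violating variants; returns VCF-style
    record dicts and fills ``truth.trait_specific``.

    Trait-specific records: alleles identical within each accession group
    and different between groups, QUAL/DP above the 30/5 filter.  Random
    records violate the rule; a few would-be trait-specific records are
    emitted below the QUAL or DP threshold to exercise both filter sides.
    """
    rng = _rng(cfg.seed, "variants")
    truth = sim.truth
    accs = [*cfg.group1, *cfg.group2]
    fam = truth.family_ids
    records: list[dict] = []
    used: set[tuple[str, int]] = set()

    def alt_of(base: str) -> str:
        return {"A": "G", "G": "A", "C": "T", "T": "C"}.get(base, "A")

    def genic_site(gene: GeneModel) -> tuple[int, int]:
        while True:
            gpos = int(rng.integers(gene.start, gene.end + 1))
            if (gene.chrom, gpos) not in used:
                used.add((gene.chrom, gpos))
                return gpos, gene.to_relative(gpos)

    # trait-specific, spread over family genes (genic, positive positions)
    host_ids = [fam[i % len(fam)] for i in range(cfg.n_trait_specific_variants)]
    for hid in host_ids:
        gene = sim.genes[hid]
        gpos, rel = genic_site(gene)
        ref = sim.genome[gene.chrom][gpos - 1]
        alt = alt_of(ref)
        g1_allele, g2_allele = (0, 1) if rng.random() < 0.5 else (1, 0)
        gts = {a: g1_allele for a in cfg.group1}
        gts.update({a: g2_allele for a in cfg.group2})
        records.append({"chrom": gene.chrom, "pos": gpos, "ref": ref,
                        "alt": alt, "qual": 60.0, "dp": 25, "gts": gts})
        truth.trait_specific.setdefault(hid, []).append(rel)

    # would-be trait-specific but failing QUAL or DP
    for i in range(2):
        gene = sim.genes[fam[(i + 1) % len(fam)]]
        gpos, rel = genic_site(gene)
        ref = sim.genome[gene.chrom][gpos - 1]
        gts = {a: 0 for a in cfg.group1}
        gts.update({a: 1 for a in cfg.group2})
        qual, dp = (10.0, 25) if i == 0 else (60.0, 2)
        records.append({"chrom": gene.chrom, "pos": gpos, "ref": ref,
                        "alt": alt_of(ref), "qual": qual, "dp": dp, "gts": gts})
        truth.filtered_positions.append(rel)

    # rule-violating variants, half inside family gene windows
    violating_patterns = [
        lambda: {**{cfg.group1[0]: 0}, **{a: 1 for a in cfg.group1[1:]},
                 **{a: 0 for a in cfg.group2}},
        lambda: {a: 0 for a in accs},          # all identical to each other
        lambda: {**{a: 1 for a in cfg.group1},
                 **{cfg.group2[0]: 1, cfg.group2[-1]: 0},
                 **{a: 1 for a in cfg.group2[1:-1]}},
    ]
    for i in range(cfg.n_random_variants):
        if i % 2 == 0:
            gene = sim.genes[fam[int(rng.integers(len(fam)))]]
            gpos, _ = genic_site(gene)
            chrom = gene.chrom
        else:
            chrom = cfg.chrom_names[int(rng.integers(cfg.n_chromosomes))]
            gpos = int(rng.integers(1, len(sim.genome[chrom]) + 1))
            if (chrom, gpos) in used:
                continue
            used.add((chrom, gpos))
        ref = sim.genome[chrom][gpos - 1]
        if ref not in "ACGT":
            continue
        gts = violating_patterns[int(rng.integers(len(violating_patterns)))]()
        if cfg.gap_rate > 0 and rng.random() < cfg.gap_rate:
            # deletion of the following base
            nxt = sim.genome[chrom][gpos: gpos + 1]
            rec = {"chrom": chrom, "pos": gpos, "ref": ref + nxt, "alt": ref,
                   "qual": 50.0, "dp": 20, "gts": gts}
        else:
            rec = {"chrom": chrom, "pos": gpos, "ref": ref, "alt": alt_of(ref),
                   "qual": 50.0, "dp": 20, "gts": gts}
        if cfg.missing_rate > 0:
            rec["gts"] = {a: (None if rng.random() < cfg.missing_rate else v)
                          for a, v in rec["gts"].items()}
        records.append(rec)
    records.sort(key=lambda r: (r["chrom"], r["pos"]))
    return records


def write_vcf(records: list[dict], cfg: SimConfig,
              genome: dict[str, str], path: str | Path) -> None:
    accs = [*cfg.group1, *cfg.group2]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c, s in genome.items():
            fh.write(f"##contig=<ID={c},length={len(s)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(accs) + "\n")
        for r in records:
            gts = []
            for a in accs:
                v = r["gts"].get(a)
                gts.append("./." if v is None else f"{v}/{v}")
            fh.write(f"{r['chrom']}\t{r['pos']}\t.\t{r['ref']}\t{r['alt']}\t"
                     f"{r['qual']:g}\tPASS\tDP={r['dp']}\tGT\t"
                     + "\t".join(gts) + "\n")


# -- expression ----------------------------------------------------------


def simulate_expression(cfg: SimConfig, truth: SimTruth,
                        extra_genes: list[str] | None = None):
    """TPM matrix over tissues x early-flowering accessions.

    Module genes are positive affine transforms of one shared latent profile
    plus Gaussian noise at the module's sd (so with sd 0 the within-module
    Pearson r is exactly 1); other genes are independent log-normal noise.
    """
    import pandas as pd

    rng = _rng(cfg.seed, "expression")
    samples = [f"{acc}_{t}" for acc in cfg.group2 for t in cfg.tissues]
    if len(samples) < 3:
        raise ValueError("need >= 3 samples for downstream correlation")
    panel = ["FT", "FUL1", "FUL2", "SOC1", "SPL9"]
    modules = cfg.expression_modules
    if modules is None:
        fam = truth.family_ids
        modules = [
            ExpressionModule((fam[0], fam[1], "FT"), 1.0, 0.0),
            ExpressionModule((fam[2], fam[3], "SOC1"), 1.0, 0.0),
        ]
    module_genes = {g for m in modules for g in m.genes}
    gene_ids = list(dict.fromkeys(
        [*truth.family_ids, *panel, *(extra_genes or []), *module_genes]))
    n = len(samples)
    data = {}
    for g in gene_ids:
        data[g] = np.round(rng.lognormal(2.0, 1.0, size=n), 3)
    for m in modules:
        latent = rng.lognormal(3.0, 1.0, size=n)
        for g in m.genes:
            a = float(rng.uniform(0.5, 2.0))
            b = float(rng.uniform(0.0, 5.0))
            noise = rng.normal(0.0, m.noise_sd, size=n) if m.noise_sd > 0 else 0.0
            data[g] = np.maximum(a * latent + b + noise, 0.0)
        truth.expression_modules.append(
            {"genes": list(m.genes), "r_target": m.r_target,
             "noise_sd": m.noise_sd})
    return pd.DataFrame(data, index=samples).T


# -- bundle writer -------------------------------------------------------


def simulate_bundle(cfg: SimConfig) -> tuple[SimulatedGenome, list[dict], "object"]:
    sim = simulate_genome(cfg)
    records = simulate_variants(cfg, sim)
    tpm = simulate_expression(cfg, sim.truth)
    return sim, records, tpm


def write_bundle(cfg: SimConfig, outdir: str | Path) -> SimulatedGenome:
    """Generate and write the complete input bundle to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim, records, tpm = simulate_bundle(cfg)
    write_fasta(sim.genome, outdir / "genome.fa")
    write_gff3(sorted(sim.genes.values(), key=lambda g: (g.chrom, g.start)),
               outdir / "genes.gff3")
    write_fasta(sim.proteins, outdir / "proteins.faa")
    write_fasta(sim.references, outdir / "references.faa")
    with open(outdir / "domain_hits.tsv", "w") as fh:
        fh.write("protein_id\tdomain_id\tevalue\tstart\tend\n")
        for row in sim.domain_hits:
            fh.write("\t".join(str(x) for x in row) + "\n")
    with open(outdir / "homolog_hits.tsv", "w") as fh:
        fh.write("query\tsubject\tevalue\tbitscore\n")
        for row in sim.homolog_hits:
            fh.write("\t".join(str(x) for x in row) + "\n")
    write_vcf(records, cfg, sim.genome, outdir / "variants.vcf")
    tpm.to_csv(outdir / "tpm.tsv", sep="\t", index_label="gene_id")
    write_jaspar(sim.pwms, outdir / "pwms.jaspar")
    with open(outdir / "family_ids.txt", "w") as fh:
        fh.write("\n".join(sim.truth.family_ids) + "\n")
    sim.truth.to_json(outdir / "truth.json")
    return sim
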