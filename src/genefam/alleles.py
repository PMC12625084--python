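"""Allele mining: variant filtering, gene-relative haplotype tables,
trait-specific classification, consequence annotation, and the
protein-stability delta report.

The haplotype table is the central object: rows are gene-relative positions
(+1 = first base of the start codon, negative = promoter), columns are the
reference plus the phenotype-grouped accessions.  A row is *trait-specific*
when the alleles are uniform within each phenotype group and the two group
alleles differ — the pattern that separates early- from late-flowering
accessions.  The deletion symbol ``-`` is a comparable allele in its own
right; the distinct missing code ``.`` disqualifies a row.

All alleles in a table are reported in coding-strand orientation; for
minus-strand genes single-base alleles are complemented during table
construction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .genome import GeneModel, reverse_complement

__all__ = [
    "DELETION",
    "MISSING",
    "VariantRecord",
    "HaplotypeTable",
    "ConsequenceCall",
    "read_vcf",
    "filter_variants",
    "build_haplotype_table",
    "classify_trait_specific",
    "classify_variant_type",
    "annotate_consequence",
    "stability_report",
    "load_haplotype_tsv",
]

DELETION = "-"  # a deletion allele: comparable
MISSING = "."   # a missing call: disqualifies trait-specific flagging

_COMP = str.maketrans("ACGTN", "TGCAN")


@dataclass
class VariantRecord:
    """One VCF-level variant with per-accession allele strings."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alleles: dict[str, str]  # accession -> allele string (VCF-style, or '.')
    qual: float | None = None
    dp: int | None = None

    def __post_init__(self) -> None:
        if self.qual is not None and self.qual < 0:
            raise ValueError("QUAL must be >= 0")
        if self.dp is not None and self.dp < 0:
            raise ValueError("DP must be >= 0")


def read_vcf(path: str | Path, het_policy: str = "iupac") -> list[VariantRecord]:
    """Read a VCF 4.x into VariantRecords.

    Genotypes are collapsed to one allele string per accession.  Heterozygous
    calls are collapsed to an IUPAC code (``het_policy='iupac'``, single-base
    genotypes only) or marked non-comparable (``het_policy='missing'``).
    Record-level DP is taken from INFO/DP.
    """
    from cyvcf2 import VCF

    iupac = {
        frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
        frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
    }
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    out = []
    for rec in vcf:
        allele_strs = [rec.REF] + list(rec.ALT)
        per_acc = {}
        for s, gt in zip(samples, rec.genotypes):
            calls = [a for a in gt[:-1] if a is not None and a >= 0]
            if not calls:
                per_acc[s] = MISSING
            elif len(set(calls)) == 1:
                per_acc[s] = allele_strs[calls[0]]
            else:
                pair = {allele_strs[c] for c in set(calls)}
                if het_policy == "iupac" and all(len(a) == 1 for a in pair):
                    per_acc[s] = iupac.get(frozenset("".join(sorted(pair))), MISSING)
                else:
                    per_acc[s] = MISSING
        dp = rec.INFO.get("DP")
        out.append(VariantRecord(rec.CHROM, rec.POS, rec.REF, per_acc,
                                 qual=rec.QUAL, dp=int(dp) if dp is not None else None))
    return out


def filter_variants(
    records: list[VariantRecord], qual_min: float = 30.0, dp_min: int = 5
) -> list[VariantRecord]:
    """Keep records with QUAL >= qual_min and DP >= dp_min (both inclusive).

    Records lacking QUAL or DP are dropped; a warning reports how many.
    """
    kept, n_missing = [], 0
    for r in records:
        if r.qual is None or r.dp is None:
            n_missing += 1
            continue
        if r.qual >= qual_min and r.dp >= dp_min:
            kept.append(r)
    if n_missing:
        warnings.warn(f"dropped {n_missing} record(s) lacking QUAL or DP")
    return kept


# -- haplotype tables ----------------------------------------------------


@dataclass
class HaplotypeTable:
    """Gene-relative positions x accessions allele matrix.

    ``df`` columns: position, reference, then one column per accession.
    """

    gene_id: str
    df: pd.DataFrame
    group1: list[str] = field(default_factory=list)  # e.g. late-flowering
    group2: list[str] = field(default_factory=list)  # e.g. early-flowering

    def __post_init__(self) -> None:
        if set(self.group1) & set(self.group2):
            raise ValueError("accession groups overlap")
        for acc in [*self.group1, *self.group2]:
            if acc not in self.df.columns:
                raise KeyError(f"accession {acc} not in table columns")
        if (self.df.position == 0).any():
            raise ValueError("gene-relative position 0 is not allowed")
        self.df = self.df.sort_values("position", kind="stable").reset_index(drop=True)

    @property
    def accessions(self) -> list[str]:
        return [*self.group1, *self.group2]

    def promoter_rows(self) -> pd.DataFrame:
        return self.df[self.df.position < 0].reset_index(drop=True)

    def genic_rows(self) -> pd.DataFrame:
        return self.df[self.df.position > 0].reset_index(drop=True)


def load_haplotype_tsv(
    path: str | Path, gene_id: str, group1: list[str], group2: list[str]
) -> HaplotypeTable:
    """Load a haplotype TSV (position, reference, one column per accession)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    df["position"] = df["position"].astype(int)
    return HaplotypeTable(gene_id=gene_id, df=df, group1=group1, group2=group2)


def _oriented_base(base: str, strand: str) -> str:
    return base if strand == "+" else base.translate(_COMP)


def _decompose(rec: VariantRecord, gene: GeneModel,
               accessions: list[str]) -> list[dict]:
    """Split a VCF-style record into per-base table rows (coding strand).

    SNPs give one row; left-anchored deletions one row per deleted base
    (carriers show ``-``); left-anchored insertions one row per inserted
    base at consecutive relative positions on the coding-strand side of the
    anchor (reference shows ``-``).
    """
    alleles = {a: rec.alleles.get(a, MISSING) for a in accessions}
    distinct = {v for v in alleles.values() if v != MISSING}
    lengths = {len(v) for v in distinct | {rec.ref}}
    rows: list[dict] = []

    if lengths == {1}:
        row = {"position": gene.to_relative(rec.pos),
               "reference": _oriented_base(rec.ref, gene.strand)}
        for a in accessions:
            v = alleles[a]
            row[a] = v if v == MISSING else _oriented_base(v, gene.strand)
        return [row]

    # Indel, VCF left-anchored: first base of REF shared with each ALT.
    for alt in sorted(distinct - {rec.ref}):
        carriers = [a for a in accessions if alleles[a] == alt]
        if len(rec.ref) > len(alt):  # deletion of ref[len(alt):]
            for i, base in enumerate(rec.ref[len(alt):], start=len(alt)):
                gpos = rec.pos + i
                row = {"position": gene.to_relative(gpos),
                       "reference": _oriented_base(base, gene.strand)}
                for a in accessions:
                    if alleles[a] == MISSING:
                        row[a] = MISSING
                    elif a in carriers:
                        row[a] = DELETION
                    else:
                        row[a] = _oriented_base(base, gene.strand)
                rows.append(row)
        elif len(alt) > len(rec.ref):  # insertion of alt[len(ref):]
            inserted = alt[len(rec.ref):]
            anchor = gene.to_relative(rec.pos)
            if gene.strand == "+":
                coding = inserted
                rel_positions = [anchor + k for k in range(1, len(inserted) + 1)]
            else:
                coding = reverse_complement(inserted)
                rel_positions = [anchor - len(inserted) + k
                                 for k in range(len(inserted))]
            for rel, base in zip(rel_positions, coding):
                row = {"position": rel, "reference": DELETION}
                for a in accessions:
                    if alleles[a] == MISSING:
                        row[a] = MISSING
                    else:
                        row[a] = base if a in carriers else DELETION
                rows.append(row)
        else:  # same-length multi-base substitution: one row per changed base
            for i, (rb, ab) in enumerate(zip(rec.ref, alt)):
                if rb == ab:
                    continue
                gpos = rec.pos + i
                row = {"position": gene.to_relative(gpos),
                       "reference": _oriented_base(rb, gene.strand)}
                for a in accessions:
                    if alleles[a] == MISSING:
                        row[a] = MISSING
                    else:
                        row[a] = _oriented_base(ab if a in carriers else rb,
                                                gene.strand)
                rows.append(row)
    return rows


def build_haplotype_table(
    records: list[VariantRecord],
    gene: GeneModel,
    group1: list[str],
    group2: list[str],
    promoter_len: int = 2000,
) -> HaplotypeTable:
    """Project variants onto gene-relative coordinates over gene + promoter.

    Rows outside ``[-promoter_len, 3'-end of the gene span]`` are excluded.
    """
    if not gene.cds:
        raise ValueError(f"gene {gene.gene_id} has no CDS")
    accessions = [*group1, *group2]
    _, rel_end = gene.relative_span()
    rows: list[dict] = []
    for rec in records:
        if rec.chrom != gene.chrom:
            continue
        for row in _decompose(rec, gene, accessions):
            if -promoter_len <= row["position"] <= rel_end and row["position"] != 0:
                rows.append(row)
    cols = ["position", "reference", *accessions]
    df = pd.DataFrame(rows, columns=cols)
    return HaplotypeTable(gene_id=gene.gene_id, df=df,
                          group1=group1, group2=group2)


def classify_trait_specific(t: HaplotypeTable) -> list[int]:
    """Positions whose alleles separate the two phenotype groups.

    A row qualifies iff all group-1 alleles are identical, all group-2
    alleles are identical, the two group alleles differ, and no call is
    missing (``.``).
    """
    if not t.group1 or not t.group2:
        raise ValueError("both accession groups must be non-empty")
    flagged = []
    for _, row in t.df.iterrows():
        g1 = {row[a] for a in t.group1}
        g2 = {row[a] for a in t.group2}
        if MISSING in g1 | g2:
            continue
        if len(g1) == 1 and len(g2) == 1 and g1 != g2:
            flagged.append(int(row.position))
    return flagged


def classify_variant_type(t: HaplotypeTable) -> pd.Series:
    """Per-row 'SNP' or 'indel'.

    A row is an indel iff any allele (reference included) is the deletion
    symbol or longer than one base; otherwise it is a SNP.  Missing calls
    are ignored for typing.
    """
    types = []
    for _, row in t.df.iterrows():
        vals = [row["reference"]] + [row[a] for a in t.accessions
                                     if row[a] != MISSING]
        indel = any(v == DELETION or len(v) != 1 for v in vals)
        types.append("indel" if indel else "SNP")
    return pd.Series(types, index=t.df.index, name="type")


# -- consequence annotation ---------------------------------------------


@dataclass
class ConsequenceCall:
    position: int  # gene-relative
    region: str    # promoter | exon | intron
    effect: str    # synonymous | nonsynonymous | frameshift | intronic | upstream
    protein_change: str | None = None  # e.g. "Gly782Val"

    def __post_init__(self) -> None:
        if (self.effect == "nonsynonymous") != (self.protein_change is not None):
            raise ValueError("protein change present iff effect is nonsynonymous")


def annotate_consequence(
    rel_pos: int,
    ref_allele: str,
    alt_allele: str,
    gene: GeneModel,
    chrom_seq: str,
) -> ConsequenceCall:
    """Classify a single table row's coding consequence.

    Alleles are given in coding-strand orientation (as stored in the
    haplotype table).  Single-base substitutions in the CDS are mapped
    through the spliced CDS to a codon and translated with the standard
    table; single-base indels in the CDS are frameshifts.
    """
    if rel_pos < 0:
        return ConsequenceCall(rel_pos, "promoter", "upstream")
    gpos = gene.to_genomic(rel_pos)
    if not gene.in_span(gpos):
        raise ValueError(f"position {rel_pos} is beyond the span of {gene.gene_id}")
    is_indel = DELETION in (ref_allele, alt_allele) or \
        len(ref_allele) != 1 or len(alt_allele) != 1
    if not gene.in_cds(gpos):
        return ConsequenceCall(rel_pos, "intron", "intronic")
    if is_indel:
        shift = abs(len(ref_allele.replace(DELETION, "")) -
                    len(alt_allele.replace(DELETION, "")))
        effect = "frameshift" if shift % 3 != 0 else "synonymous"
        return ConsequenceCall(rel_pos, "exon", effect)
    cds_seq = gene.spliced_cds(chrom_seq)
    off = gene.cds_offset(gpos)  # 1-based in spliced CDS
    codon_idx = math.ceil(off / 3)
    codon = cds_seq[3 * (codon_idx - 1): 3 * codon_idx]
    within = (off - 1) % 3
    if codon[within] != ref_allele:
        raise ValueError(
            f"reference allele {ref_allele} does not match CDS base "
            f"{codon[within]} at relative position {rel_pos} of {gene.gene_id}")
    new_codon = codon[:within] + alt_allele + codon[within + 1:]
    aa_old = str(Seq(codon).translate())
    aa_new = str(Seq(new_codon).translate())
    if aa_old == aa_new:
        return ConsequenceCall(rel_pos, "exon", "synonymous")
    change = f"{seq3(aa_old)}{codon_idx}{seq3(aa_new)}"
    return ConsequenceCall(rel_pos, "exon", "nonsynonymous", change)


# -- protein-stability report -------------------------------------------


def stability_report(
    e_wild: float, e_mut: float, neutral_band: float = 0.5
) -> tuple[float, str]:
    """Energy difference (mutant - wild type, kcal/mol) and its label.

    Deltas below ``-neutral_band`` are Stabilizing, above ``+neutral_band``
    Destabilizing, otherwise Neutral.
    """
    if not (math.isfinite(e_wild) and math.isfinite(e_mut)):
        raise ValueError("energies must be finite")
    delta = round(e_mut - e_wild, 10)
    if delta < -neutral_band:
        label = "Stabilizing"
    elif delta > neutral_band:
        label = "Destabilizing"
    else:
        label = "Neutral"
    return delta, label
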