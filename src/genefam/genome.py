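"""Gene models, coordinate transforms, and flat-file genome I/O.

The pipeline works with stranded gene models carrying ordered exon/CDS
intervals.  Two coordinate systems are used throughout:

* genomic — 1-based inclusive positions on a chromosome (GFF3/VCF convention);
* gene-relative — signed positions anchored on the start codon: +1 is the
  first base of the start codon on the coding strand, -1 the base immediately
  upstream, and there is no position 0.  This is the coordinate system of the
  published haplotype tables this pipeline reproduces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GeneModel",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneModel:
    """A stranded gene with ordered exon/CDS intervals (genomic, 1-based)."""

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        for name, ivals in (("exons", self.exons), ("cds", self.cds)):
            for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
                if s2 <= e1:
                    raise ValueError(f"{name} of {self.gene_id} overlap: "
                                     f"({s1},{e1}) vs ({s2},{e2})")

    # -- anchors ---------------------------------------------------------

    @property
    def atg_pos(self) -> int:
        """Genomic position of the first base of the start codon."""
        if not self.cds:
            raise ValueError(f"gene {self.gene_id} has no CDS")
        return self.cds[0][0] if self.strand == "+" else self.cds[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    # -- coordinate transforms ------------------------------------------

    def to_relative(self, genomic_pos: int) -> int:
        """Genomic position -> signed gene-relative position (no zero)."""
        a = self.atg_pos
        if self.strand == "+":
            d = genomic_pos - a
        else:
            d = a - genomic_pos
        return d + 1 if d >= 0 else d

    def to_genomic(self, rel_pos: int) -> int:
        """Signed gene-relative position -> genomic position."""
        if rel_pos == 0:
            raise ValueError("gene-relative position 0 does not exist")
        d = rel_pos - 1 if rel_pos > 0 else rel_pos
        a = self.atg_pos
        return a + d if self.strand == "+" else a - d

    def relative_span(self) -> tuple[int, int]:
        """Gene-relative positions of the gene span's two ends (5', 3')."""
        if self.strand == "+":
            return self.to_relative(self.start), self.to_relative(self.end)
        return self.to_relative(self.end), self.to_relative(self.start)

    # -- region queries --------------------------------------------------

    def in_span(self, genomic_pos: int) -> bool:
        return self.start <= genomic_pos <= self.end

    def in_cds(self, genomic_pos: int) -> bool:
        return any(s <= genomic_pos <= e for s, e in self.cds)

    def cds_offset(self, genomic_pos: int) -> int:
        """1-based position within the spliced CDS (coding-strand order)."""
        if not self.in_cds(genomic_pos):
            raise ValueError(f"{genomic_pos} is not in the CDS of {self.gene_id}")
        pieces = self.cds if self.strand == "+" else list(reversed(self.cds))
        offset = 0
        for s, e in pieces:
            if s <= genomic_pos <= e:
                within = (genomic_pos - s) if self.strand == "+" else (e - genomic_pos)
                return offset + within + 1
            offset += e - s + 1
        raise AssertionError("unreachable")

    def spliced_cds(self, chrom_seq: str) -> str:
        """Coding-strand CDS nucleotide sequence."""
        parts = [chrom_seq[s - 1 : e] for s, e in self.cds]
        seq = "".join(parts)
        return seq if self.strand == "+" else reverse_complement(seq)

    def codon_index(self, genomic_pos: int) -> int:
        """1-based codon number for a CDS genomic position."""
        return math.ceil(self.cds_offset(genomic_pos) / 3)


# -- FASTA ---------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# -- GFF3 ----------------------------------------------------------------


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.chrom}\tgenefam\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            mrna = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\tgenefam\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna};Parent={g.gene_id}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.chrom}\tgenefam\texon\t{s}\t{e}\t.\t{g.strand}\t.\tParent={mrna}\n"
                )
            for s, e in g.cds:
                fh.write(
                    f"{g.chrom}\tgenefam\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\tParent={mrna}\n"
                )


def _attr(attrs: str, key: str) -> str | None:
    for part in attrs.strip().split(";"):
        if part.startswith(key + "="):
            return part[len(key) + 1 :]
    return None


def read_gff3(path: str | Path) -> dict[str, GeneModel]:
    """Parse a flat GFF3 into gene models keyed by gene id.

    Handles the gene/mRNA/exon/CDS feature hierarchy written by this package
    and by typical genome-annotation GFF3 exports; only the first mRNA of a
    gene is used.
    """
    genes: dict[str, dict] = {}
    mrna_to_gene: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                continue
            chrom, _, ftype, start, end, _, strand, _, attrs = f[:9]
            start, end = int(start), int(end)
            if ftype == "gene":
                gid = _attr(attrs, "ID")
                genes[gid] = {
                    "chrom": chrom, "strand": strand, "start": start,
                    "end": end, "exons": [], "cds": [],
                }
            elif ftype == "mRNA":
                mid, parent = _attr(attrs, "ID"), _attr(attrs, "Parent")
                if parent in genes and parent not in mrna_to_gene.values():
                    mrna_to_gene[mid] = parent
            elif ftype in ("exon", "CDS"):
                parent = _attr(attrs, "Parent")
                gid = mrna_to_gene.get(parent, parent if parent in genes else None)
                if gid is None:
                    continue
                key = "exons" if ftype == "exon" else "cds"
                genes[gid][key].append((start, end))
    out = {}
    for gid, d in genes.items():
        if not d["exons"] and d["cds"]:
            d["exons"] = list(d["cds"])
        out[gid] = GeneModel(gene_id=gid, **d)
    return out
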