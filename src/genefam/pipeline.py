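"""End-to-end orchestration of the gene-family characterization stages.

One flat config carries every stage parameter with its standard default
(2 kb promoters filtered at 500 bp / 1,500 ambiguous bases; enrichment at
q <= 0.1; variant filter QUAL >= 30 and DP >= 5; collinear chaining with
match size 5, max gaps 25, match score 50, gap penalty -1, overlap window
5, top 5 hits at e <= 1e-5; QTN window 1.0 Mb).  The resolved config is
written next to the outputs of every run so a run is reproducible from its
output directory alone.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import alleles, census, expression, naming, promoters, synteny
from .genome import read_fasta, read_gff3, write_fasta

logger = logging.getLogger("genefam")

FLOWERING_PANEL = ["FT", "FUL1", "FUL2", "SOC1", "SPL9"]


@dataclass
class PipelineConfig:
    indir: str = "."
    outdir: str = "results"
    seed: int = 0
    # promoter stage
    promoter_length: int = 2000
    promoter_min_len: int = 500
    promoter_max_ambiguous: int = 1500
    q_threshold: float = 0.1
    # variant stage
    qual_min: float = 30.0
    dp_min: int = 5
    group1: list[str] = field(default_factory=lambda: ["EC0115148", "EC0718827"])
    group2: list[str] = field(default_factory=lambda: ["IC0523807", "IC0525939"])
    # synteny stage
    e_max: float = 1e-5
    top_k: int = 5
    match_size: int = 5
    max_gaps: int = 25
    match_score: float = 50.0
    gap_penalty: float = -1.0
    overlap_window: int = 5
    qtn_window_bp: int = 1_000_000
    # expression stage
    alpha: float = 0.05
    panel: list[str] = field(default_factory=lambda: list(FLOWERING_PANEL))
    # census stage
    domain_e_cutoff: float = 1e-5
    required_domains: list[str] = field(
        default_factory=lambda: sorted(census.DEFAULT_REQUIRED_DOMAINS))
    qtn_loci: list[str] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def chain_params(self) -> synteny.ChainParams:
        return synteny.ChainParams(
            e_max=self.e_max, top_k=self.top_k, match_size=self.match_size,
            max_gaps=self.max_gaps, match_score=self.match_score,
            gap_penalty=self.gap_penalty, overlap_window=self.overlap_window)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _need(stage: str, path: Path) -> Path:
    if not path.exists():
        raise StageError(stage, f"missing input file {path}")
    return path


def run_all(cfg: PipelineConfig, stages: list[str] | None = None) -> dict:
    """Run the stages in dependency order; returns per-stage outputs.

    Stage order: census -> naming -> correlate / alleles / enrich /
    synteny / qtl -> report.  A stage failure raises a stage-named error
    without touching later stages.
    """
    indir, outdir = Path(cfg.indir), Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "resolved_config.yaml")
    wanted = stages or ["census", "naming", "correlate", "alleles",
                        "enrich", "synteny", "qtl", "report"]
    if {"naming", "correlate", "alleles", "enrich", "synteny",
            "qtl"} & set(wanted):
        wanted = ["census", *[s for s in wanted if s != "census"]]
    out: dict = {}

    if "census" in wanted:
        proteins = read_fasta(_need("census", indir / "proteins.faa"))
        hits = census.read_domain_hits(_need("census", indir / "domain_hits.tsv"))
        fam = census.filter_by_domains(hits, set(cfg.required_domains),
                                       cfg.domain_e_cutoff)
        out["family_ids"] = sorted(fam)
        logger.info("census: %d proteins in, %d family members",
                    len(proteins), len(fam))
        out["proteins"] = proteins

    if "naming" in wanted:
        refs = read_fasta(_need("naming", indir / "references.faa"))
        fam_seqs = {g: out["proteins"][g] for g in out["family_ids"]}
        aligned = {**refs, **fam_seqs}
        if len({len(s) for s in aligned.values()}) != 1:
            raise StageError("naming", "sequences are not aligned "
                             "(unequal lengths); provide an aligned FASTA")
        d = naming.p_distance(aligned)
        nm = naming.assign_names(d, sorted(refs), sorted(fam_seqs))
        nm.table.to_csv(outdir / "names.tsv", sep="\t", index=False)
        tree = naming.nj_tree(d)
        (outdir / "tree.nwk").write_text(str(tree))
        out["names"] = nm
        logger.info("naming: %d queries named against %d references",
                    len(fam_seqs), len(refs))

    if "correlate" in wanted:
        tpm = expression.load_tpm(_need("correlate", indir / "tpm.tsv"))
        panel = [g for g in cfg.panel if g in tpm.index]
        fam_in = [g for g in out["family_ids"] if g in tpm.index]
        corr = expression.correlate_panels(tpm, fam_in, panel, alpha=cfg.alpha)
        corr.to_csv(outdir / "correlations.tsv", sep="\t", index=False)
        out["correlations"] = corr
        logger.info("correlate: %d family x %d panel pairs", len(fam_in),
                    len(panel))

    needs_genome = {"alleles", "enrich", "synteny", "qtl"} & set(wanted)
    if needs_genome:
        genes = read_gff3(_need("genome", indir / "genes.gff3"))
        genome = read_fasta(_need("genome", indir / "genome.fa")) \
            if {"alleles", "enrich"} & set(wanted) else {}

    if "alleles" in wanted:
        records = alleles.read_vcf(_need("alleles", indir / "variants.vcf"))
        kept = alleles.filter_variants(records, cfg.qual_min, cfg.dp_min)
        logger.info("alleles: %d records in, %d pass QUAL>=%g DP>=%d",
                    len(records), len(kept), cfg.qual_min, cfg.dp_min)
        tables = {}
        for gid in out["family_ids"]:
            t = alleles.build_haplotype_table(
                kept, genes[gid], cfg.group1, cfg.group2,
                promoter_len=cfg.promoter_length)
            if len(t.df) == 0:
                continue
            flagged = set(alleles.classify_trait_specific(t))
            t.df["trait_specific"] = t.df.position.isin(flagged)
            t.df["type"] = alleles.classify_variant_type(t)
            t.df.to_csv(outdir / f"haplotypes_{gid}.tsv", sep="\t", index=False)
            tables[gid] = t
        out["haplotypes"] = tables

    if "enrich" in wanted:
        pwms = promoters.read_pwms(_need("enrich", indir / "pwms.jaspar"))
        proms = promoters.extract_promoters(
            genome, genes, cfg.promoter_length, cfg.promoter_min_len,
            cfg.promoter_max_ambiguous)
        write_fasta(proms.seqs, outdir / "promoters.fa")
        enr = promoters.enrich(proms, out["family_ids"], pwms,
                               q_threshold=cfg.q_threshold)
        enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        out["enrichment"] = enr
        out["promoters"] = proms
        logger.info("enrich: %d promoters retained, %d excluded, "
                    "%d motifs enriched at q<=%g", len(proms.seqs),
                    len(proms.exclusions), int(enr.enriched.sum()),
                    cfg.q_threshold)

    if "synteny" in wanted:
        hits = synteny.read_hits(_need("synteny", indir / "homolog_hits.tsv"))
        idx = synteny.build_rank_index(genes)
        blocks = synteny.chain_collinear(hits, idx, idx, "self", "self",
                                         cfg.chain_params())
        fam_blocks = synteny.filter_family_blocks(blocks, set(out["family_ids"]))
        synteny.csb_census(blocks).to_csv(outdir / "csb_census.tsv",
                                          sep="\t", index=False)
        synteny.csb_census(fam_blocks).to_csv(
            outdir / "csb_family_census.tsv", sep="\t", index=False)
        gcn = synteny.build_gcn(fam_blocks, set(out["family_ids"]))
        with open(outdir / "gcn_edges.tsv", "w") as fh:
            fh.write("gene_a\tgene_b\n")
            for a, b in sorted(gcn.edges):
                fh.write(f"{a}\t{b}\n")
        out["blocks"], out["family_blocks"], out["gcn"] = blocks, fam_blocks, gcn
        logger.info("synteny: %d blocks, %d containing family genes, "
                    "%d GCN components", len(blocks), len(fam_blocks),
                    len(synteny.gcn_components(gcn)))

    if "qtl" in wanted and cfg.qtn_loci:
        fam_genes = {g: genes[g] for g in out["family_ids"] if g in genes}
        prox = synteny.qtn_proximity(fam_genes, cfg.qtn_loci, cfg.qtn_window_bp)
        prox.to_csv(outdir / "qtn_proximity.tsv", sep="\t", index=False)
        out["qtn"] = prox

    if "report" in wanted:
        render_report(out, outdir)
    return out


def render_report(out: dict, outdir: str | Path) -> list[str]:
    """Write the per-stage summary tables in the published table layouts.

    Emits whichever layouts have inputs available and notes the skipped
    ones; returns the list of files written.
    """
    outdir = Path(outdir)
    written = []
    notes = []
    if "family_ids" in out and "proteins" in out:
        names = out["names"].as_dict() if "names" in out else {}
        tab = census.census_table(out["proteins"], set(out["family_ids"]),
                                  names=names)
        tab.to_csv(outdir / "report_census.tsv", sep="\t", index=False)
        written.append("report_census.tsv")
    else:
        notes.append("census layout skipped: no census output")
    if "haplotypes" in out:
        for gid, t in out["haplotypes"].items():
            t.df.to_csv(outdir / f"report_haplotypes_{gid}.tsv", sep="\t",
                        index=False)
            written.append(f"report_haplotypes_{gid}.tsv")
    else:
        notes.append("haplotype layout skipped: no alleles output")
    if "enrichment" in out:
        enr = out["enrichment"].sort_values("q")
        enr.to_csv(outdir / "report_enrichment.tsv", sep="\t", index=False)
        written.append("report_enrichment.tsv")
    if "blocks" in out:
        written.append("csb_census.tsv")
    if notes:
        (outdir / "report_notes.txt").write_text("\n".join(notes) + "\n")
    return written


def setup_logging(logfile: str | Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(level=logging.INFO, handlers=handlers,
                        format="%(levelname)s %(name)s: %(message)s", force=True)
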