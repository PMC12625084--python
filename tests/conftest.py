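"""Shared fixtures: a zero-noise synthetic bundle and a full pipeline run.

The session-scoped bundle uses the default study-like configuration
(~1,000-gene backbone, 18-member family in four duplicated segment groups,
three planted trait-specific variants, one planted promoter motif).
"""

from __future__ import annotations

import numpy as np
import pytest

from genefam import pipeline
from genefam.genome import GeneModel
from genefam.simulate import SimConfig, _reverse_translate, write_bundle

GROUP1 = ["EC0115148", "EC0718827"]
GROUP2 = ["IC0523807", "IC0525939"]


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle")
    sim = write_bundle(SimConfig(seed=7), outdir)
    return sim, outdir


@pytest.fixture(scope="session")
def pipeline_out(bundle, tmp_path_factory):
    sim, indir = bundle
    outdir = tmp_path_factory.mktemp("pipeline")
    cfg = pipeline.PipelineConfig(indir=str(indir), outdir=str(outdir))
    out = pipeline.run_all(cfg)
    return sim, out, outdir


@pytest.fixture(scope="session")
def small_config():
    """A fast-to-generate configuration for determinism/CLI tests."""
    return SimConfig(seed=3, n_chromosomes=4, genes_per_chromosome=40,
                     family_size=8, n_paralog_pairs=4, n_pwms=5,
                     n_random_variants=10, intergenic_len=2100)


def random_gene(rng: np.random.Generator, chrom: str = "chrT",
                strand: str | None = None, n_aa: int = 40,
                pad: int = 50) -> tuple[GeneModel, str, str]:
    """Build one random spliced gene on a padded chromosome.

    Returns (gene model, chromosome sequence, protein sequence).
    """
    aa = "ACDEFGHIKLMNPQRSTVWY"
    protein = "M" + "".join(rng.choice(list(aa), size=n_aa - 1))
    cds = _reverse_translate(rng, protein)
    n_exons = int(rng.integers(1, 4))
    cut_space = np.arange(1, len(cds))
    cuts = sorted(rng.choice(cut_space, size=n_exons - 1, replace=False)) \
        if n_exons > 1 else []
    pieces = [cds[a:b] for a, b in zip([0, *cuts], [*cuts, len(cds)])]
    bases = np.array(list("ACGT"))
    body = ""
    exon_rel = []
    for pi, piece in enumerate(pieces):
        if pi:
            body += "".join(rng.choice(bases, size=int(rng.integers(20, 60))))
        exon_rel.append((len(body), len(body) + len(piece) - 1))
        body += piece
    if strand is None:
        strand = "+" if rng.random() < 0.5 else "-"
    if strand == "-":
        from genefam.genome import reverse_complement
        L = len(body)
        exon_rel = [(L - 1 - e, L - 1 - s) for s, e in exon_rel][::-1]
        body = reverse_complement(body)
    left = "".join(rng.choice(bases, size=pad))
    right = "".join(rng.choice(bases, size=pad))
    gstart = pad + 1
    exons = [(gstart + s, gstart + e) for s, e in exon_rel]
    gene = GeneModel("gT", chrom, strand, gstart, gstart + len(body) - 1,
                     exons, list(exons))
    return gene, left + body + right, protein
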