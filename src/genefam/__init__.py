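"""genefam: gene-family characterization from genome, variant, expression
and synteny data — family census, ortholog naming, expression correlation,
allele mining, promoter motif enrichment, and syntenic gene networks, with
a synthetic-data generator carrying planted ground truth."""

from importlib.resources import files as _files

__version__ = "0.1.0"


def data_path(name: str):
    """Path to a bundled data file (e.g. the published haplotype tables)."""
    return _files("genefam") / "data" / name
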