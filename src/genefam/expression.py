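"""TPM expression matrices and expression-expression correlation.

Correlations are plain Pearson r over shared samples with two-sided t-test
p-values; this mirrors the common practice of relating a gene family's
expression to a panel of flowering-time regulators (FT, FUL, SOC1, SPL9)
across tissues.  Raw TPM values are used by default; ``log2(TPM+1)`` is
available as an option since no transform is universally standard.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "load_tpm",
    "save_tpm",
    "correlate_panels",
    "top_expressed",
]


def load_tpm(path: str | Path) -> pd.DataFrame:
    """Read a TPM TSV (first column gene id, remaining columns samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dups}")
    if (df.values < 0).any():
        raise ValueError("TPM values must be >= 0")
    return df


def save_tpm(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def correlate_panels(
    m: pd.DataFrame,
    set_a: list[str],
    set_b: list[str],
    alpha: float = 0.05,
    log_transform: bool = False,
    bh: bool = False,
) -> pd.DataFrame:
    """Pearson correlation of every (a, b) gene pair over shared samples.

    Returns a table with columns gene_a, gene_b, r, n, p, significant.
    Constant expression vectors give an undefined r, reported as NaN with
    ``significant=False`` rather than silently as zero.  With ``bh=True`` a
    Benjamini-Hochberg ``q`` column is appended.
    """
    missing = [g for g in [*set_a, *set_b] if g not in m.index]
    if missing:
        raise KeyError(f"gene ids absent from matrix: {missing}")
    n = m.shape[1]
    if n < 3:
        raise ValueError(f"need >= 3 samples for correlation, got {n}")
    x = m.loc[:, :].astype(float)
    if log_transform:
        x = np.log2(x + 1.0)
    rows = []
    for a in set_a:
        va = x.loc[a].values
        for b in set_b:
            vb = x.loc[b].values
            if np.ptp(va) == 0 or np.ptp(vb) == 0:
                rows.append((a, b, np.nan, n, np.nan, False))
                continue
            r, p = stats.pearsonr(va, vb)
            rows.append((a, b, float(r), n, float(p), bool(p <= alpha)))
    out = pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "n", "p", "significant"])
    if bh:
        q = np.full(len(out), np.nan)
        ok = out.p.notna().values
        if ok.any():
            q[ok] = multipletests(out.p.values[ok], method="fdr_bh")[1]
        out["q"] = q
    return out


def top_expressed(m: pd.DataFrame, k: int) -> list[str]:
    """Top-k genes by mean TPM over all samples; ties broken by gene id."""
    if m.shape[0] == 0:
        raise ValueError("empty expression matrix")
    if k > m.shape[0]:
        raise ValueError(f"k={k} exceeds gene count {m.shape[0]}")
    means = m.mean(axis=1)
    order = sorted(m.index, key=lambda g: (-means[g], g))
    return order[:k]
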