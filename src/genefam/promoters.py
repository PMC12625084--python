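"""Promoter extraction, PWM affinity scoring, and set-level motif enrichment.

The enrichment model: for each motif, every promoter receives an *affinity*
score — the mean, over both strands and all start positions, of the odds
product ``prod_k M[k, base] / pi[base]``.  Log affinities over the
genome-wide promoter background are summarized by their mean ``mu`` and
standard deviation ``sigma`` (the log-normal background).  A gene set of
size n is tested per motif with ``z = (mean log affinity - mu) /
(sigma / sqrt(n))`` against the upper tail of the standard normal, and the
per-motif p-values are Benjamini-Hochberg adjusted; motifs at ``q <= 0.1``
are called enriched.

Promoters are the 2 kb upstream of the start codon on the coding strand,
truncated at chromosome edges; sequences shorter than 500 bp or with more
than 1,500 ambiguous bases are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GeneModel, reverse_complement

__all__ = [
    "PositionWeightMatrix",
    "PromoterSet",
    "BackgroundModel",
    "read_pwms",
    "write_jaspar",
    "extract_promoters",
    "pwm_affinity",
    "score_promoters",
    "fit_background",
    "group_enrichment",
    "bh_adjust",
    "presence_calls",
    "universal_motifs",
    "enrich",
]

_BASES = "ACGT"
UNIFORM_BG = np.full(4, 0.25)


@dataclass
class PositionWeightMatrix:
    """Per-position nucleotide probabilities over A, C, G, T."""

    motif_id: str
    probs: np.ndarray  # (w, 4), rows sum to 1
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("PWM must have shape (w, 4)")
        if (self.probs < 0).any() or (self.probs > 1).any():
            raise ValueError("PWM probabilities must lie in [0, 1]")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.probs.argmax(axis=1))

    @classmethod
    def from_counts(cls, motif_id: str, counts: np.ndarray,
                    pseudocount: float = 0.8) -> "PositionWeightMatrix":
        c = np.asarray(counts, dtype=float) + pseudocount / 4.0
        return cls(motif_id, c / c.sum(axis=1, keepdims=True), pseudocount)


# -- PWM collection I/O --------------------------------------------------


def read_pwms(path: str | Path, fmt: str = "jaspar",
              pseudocount: float = 0.8) -> list[PositionWeightMatrix]:
    """Read a JASPAR count-matrix or TRANSFAC-like PWM collection.

    JASPAR counts are converted to probabilities with a +0.8 pseudocount
    (split evenly over the four bases); TRANSFAC matrices are row-normalized.
    """
    from Bio import motifs as bio_motifs

    out = []
    with open(path) as fh:
        if fmt == "jaspar":
            for m in bio_motifs.parse(fh, "jaspar"):
                counts = np.array([m.counts[b] for b in _BASES]).T
                mid = m.matrix_id or m.name
                out.append(PositionWeightMatrix.from_counts(mid, counts, pseudocount))
        elif fmt == "transfac":
            for m in bio_motifs.parse(fh, "transfac"):
                counts = np.array([m.counts[b] for b in _BASES]).T
                mid = m.get("AC") or m.name
                rows = counts / counts.sum(axis=1, keepdims=True)
                out.append(PositionWeightMatrix(mid, rows))
        else:
            raise ValueError(f"unknown PWM format {fmt!r}")
    return out


def write_jaspar(pwms: list[PositionWeightMatrix], path: str | Path,
                 scale: int = 100) -> None:
    """Write PWMs as JASPAR count matrices (probabilities x scale)."""
    with open(path, "w") as fh:
        for p in pwms:
            fh.write(f">{p.motif_id} {p.motif_id}\n")
            counts = np.rint(p.probs * scale).astype(int)
            for bi, b in enumerate(_BASES):
                vals = " ".join(str(v) for v in counts[:, bi])
                fh.write(f"{b}  [ {vals} ]\n")


# -- promoter extraction -------------------------------------------------


@dataclass
class PromoterSet:
    seqs: dict[str, str] = field(default_factory=dict)
    exclusions: list[tuple[str, str]] = field(default_factory=list)


def extract_promoters(
    genome: dict[str, str],
    genes: dict[str, GeneModel],
    length: int = 2000,
    min_len: int = 500,
    max_ambiguous: int = 1500,
) -> PromoterSet:
    """Strand-aware upstream windows ending at the base before the start codon."""
    out = PromoterSet()
    for gid, g in genes.items():
        if not g.cds:
            out.exclusions.append((gid, "no CDS"))
            continue
        chrom = genome[g.chrom]
        a = g.atg_pos
        if g.strand == "+":
            lo = max(1, a - length)
            seq = chrom[lo - 1: a - 1]
        else:
            hi = min(len(chrom), a + length)
            seq = reverse_complement(chrom[a: hi])
        if len(seq) < min_len:
            out.exclusions.append((gid, f"shorter than {min_len} bp"))
            continue
        n_amb = sum(1 for c in seq.upper() if c not in _BASES)
        if n_amb > max_ambiguous:
            out.exclusions.append((gid, f"more than {max_ambiguous} ambiguous bases"))
            continue
        out.seqs[gid] = seq.upper()
    return out


# -- scoring -------------------------------------------------------------

_ENC = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(_BASES):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _odds_table(pwm: PositionWeightMatrix, background: np.ndarray) -> np.ndarray:
    """(w, 5) odds lookup; the 5th column (ambiguous base) contributes 1."""
    odds = np.empty((pwm.width, 5))
    odds[:, :4] = pwm.probs / background
    odds[:, 4] = 1.0
    return odds


def _scan_numpy(enc: np.ndarray, lengths: np.ndarray,
                odds: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    w = odds.shape[0]
    n = enc.shape[0]
    sums = np.zeros(n)
    counts = np.zeros(n, dtype=np.int64)
    maxima = np.zeros(n)
    for i in range(n):
        L = int(lengths[i])
        if L < w:
            continue
        nwin = L - w + 1
        acc = np.ones(nwin)
        for k in range(w):
            acc *= odds[k, enc[i, k: k + nwin]]
        sums[i] = acc.sum()
        counts[i] = nwin
        maxima[i] = acc.max()
    return sums, counts, maxima


try:  # numba kernel for the simulation-heavy calibration runs
    from numba import njit

    @njit(cache=False)
    def _scan_numba(enc, lengths, odds):  # pragma: no cover - numba
        w = odds.shape[0]
        n = enc.shape[0]
        sums = np.zeros(n)
        counts = np.zeros(n, dtype=np.int64)
        maxima = np.zeros(n)
        for i in range(n):
            L = lengths[i]
            if L < w:
                continue
            nwin = L - w + 1
            best = 0.0
            tot = 0.0
            for j in range(nwin):
                prod = 1.0
                for k in range(w):
                    prod *= odds[k, enc[i, j + k]]
                tot += prod
                if prod > best:
                    best = prod
            sums[i] = tot
            counts[i] = nwin
            maxima[i] = best
    # noqa: E501
            pass
        return sums, counts, maxima

    _SCAN = _scan_numba
except Exception:  # pragma: no cover
    _SCAN = _scan_numpy


def _encode_batch(seqs: list[str]) -> tuple[np.ndarray, np.ndarray]:
    lengths = np.array([len(s) for s in seqs], dtype=np.int64)
    enc = np.full((len(seqs), int(lengths.max()) if len(seqs) else 0), 4,
                  dtype=np.int8)
    for i, s in enumerate(seqs):
        enc[i, : len(s)] = _encode(s)
    return enc, lengths


def pwm_affinity(seq: str, pwm: PositionWeightMatrix,
                 background: np.ndarray = UNIFORM_BG) -> float:
    """Mean odds over both strands and all start positions of one sequence."""
    if len(seq) < pwm.width:
        raise ValueError(
            f"sequence ({len(seq)} bp) shorter than motif width {pwm.width}")
    return float(score_promoters([seq], [pwm], background)["affinity"][0, 0])


def score_promoters(
    seqs: list[str],
    pwms: list[PositionWeightMatrix],
    background: np.ndarray = UNIFORM_BG,
    use_numba: bool = True,
) -> dict[str, np.ndarray]:
    """Affinity and per-sequence maximum window odds for every motif.

    Returns ``{"affinity": (n_motifs, n_seqs), "max_odds": (n_motifs, n_seqs)}``.
    Both strands are scanned; the affinity is the mean window odds over the
    pooled forward and reverse windows.
    """
    scan = _SCAN if use_numba else _scan_numpy
    enc_f, lengths = _encode_batch(seqs)
    enc_r, _ = _encode_batch([reverse_complement(s) for s in seqs])
    n_m, n_s = len(pwms), len(seqs)
    affinity = np.zeros((n_m, n_s))
    max_odds = np.zeros((n_m, n_s))
    for mi, pwm in enumerate(pwms):
        odds = _odds_table(pwm, background)
        sf, cf, mf = scan(enc_f, lengths, odds)
        sr, cr, mr = scan(enc_r, lengths, odds)
        total = cf + cr
        if (total == 0).any():
            short = [seqs[i] for i in np.where(total == 0)[0]]
            raise ValueError(
                f"{len(short)} sequence(s) shorter than motif width {pwm.width}")
        affinity[mi] = (sf + sr) / total
        max_odds[mi] = np.maximum(mf, mr)
    return {"affinity": affinity, "max_odds": max_odds}


# -- background model & enrichment test ---------------------------------


@dataclass
class BackgroundModel:
    mu: dict[str, float]
    sigma: dict[str, float]
    epsilon: float


def fit_background(scores: dict[str, np.ndarray]) -> BackgroundModel:
    """Mean and sd of log affinity per motif over background promoters.

    Zero scores are floored at ``min positive score x 1e-3`` before the log
    so the fit stays defined without the floor dominating it.
    """
    all_vals = np.concatenate([np.asarray(v, dtype=float) for v in scores.values()])
    if any(len(np.asarray(v)) < 2 for v in scores.values()):
        raise ValueError("need >= 2 background promoters per motif")
    positive = all_vals[all_vals > 0]
    if positive.size == 0:
        raise ValueError("no positive background scores")
    eps = float(positive.min()) * 1e-3
    mu, sigma = {}, {}
    for motif, vals in scores.items():
        logs = np.log(np.maximum(np.asarray(vals, dtype=float), eps))
        mu[motif] = float(logs.mean())
        sigma[motif] = float(logs.std(ddof=1))
    return BackgroundModel(mu, sigma, eps)


def group_enrichment(
    target_scores: np.ndarray, mu: float, sigma: float, eps: float
) -> tuple[float, float, float]:
    """(mean log affinity, z, upper-tail p) for a target promoter set."""
    vals = np.asarray(target_scores, dtype=float)
    if vals.size < 1:
        raise ValueError("target set must be non-empty")
    mean_log = float(np.log(np.maximum(vals, eps)).mean())
    n = vals.size
    if sigma == 0:
        return mean_log, np.inf if mean_log > mu else -np.inf, \
            0.0 if mean_log > mu else 1.0
    z = (mean_log - mu) / (sigma / np.sqrt(n))
    return mean_log, float(z), float(stats.norm.sf(z))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(pvals, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# -- presence & universal motifs ----------------------------------------


def presence_calls(
    max_odds: np.ndarray,
    pwms: list[PositionWeightMatrix],
    background: np.ndarray = UNIFORM_BG,
    frac: float = 0.85,
) -> np.ndarray:
    """Hit calls (n_motifs, n_seqs): a promoter holds a motif when some
    window's log-odds reaches ``frac`` of the motif's maximum achievable
    log-odds."""
    calls = np.zeros_like(max_odds, dtype=bool)
    for mi, pwm in enumerate(pwms):
        best = float(np.log(pwm.probs / background).max(axis=1).sum())
        thr = np.exp(frac * best)
        calls[mi] = max_odds[mi] >= thr
    return calls


def universal_motifs(
    calls: np.ndarray, motif_ids: list[str], family_index: np.ndarray
) -> list[str]:
    """Motifs with >=1 hit in *every* family promoter."""
    if family_index.size == 0:
        raise ValueError("family promoter set is empty")
    fam = calls[:, family_index]
    return [motif_ids[i] for i in range(len(motif_ids)) if fam[i].all()]


# -- high-level enrichment -----------------------------------------------


def enrich(
    promoters: PromoterSet,
    family_ids: list[str],
    pwms: list[PositionWeightMatrix],
    background: np.ndarray = UNIFORM_BG,
    q_threshold: float = 0.1,
    presence_frac: float = 0.85,
) -> pd.DataFrame:
    """Per-motif enrichment of the family promoter set over the genome-wide
    background, with BH q-values and family presence counts."""
    gene_order = list(promoters.seqs)
    fam_present = [g for g in family_ids if g in promoters.seqs]
    if not fam_present:
        raise ValueError("no family gene has a retained promoter")
    seqs = [promoters.seqs[g] for g in gene_order]
    scored = score_promoters(seqs, pwms, background)
    fam_idx = np.array([gene_order.index(g) for g in fam_present])
    bg_model = fit_background(
        {p.motif_id: scored["affinity"][i] for i, p in enumerate(pwms)})
    calls = presence_calls(scored["max_odds"], pwms, background, presence_frac)
    rows = []
    for i, p in enumerate(pwms):
        mean_log, z, pval = group_enrichment(
            scored["affinity"][i, fam_idx],
            bg_model.mu[p.motif_id], bg_model.sigma[p.motif_id], bg_model.epsilon)
        rows.append({"motif_id": p.motif_id, "mean_log_affinity": mean_log,
                     "z": z, "p": pval,
                     "presence_n": int(calls[i, fam_idx].sum())})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out.p.values)
    out["enriched"] = out.q <= q_threshold
    return out
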