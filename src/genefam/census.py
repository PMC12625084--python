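"""Gene-family census: domain-based membership and protein characterization.

Family membership is decided from domain hits: a protein belongs to the
family iff it carries at least one hit, at or below an e-value cutoff, for
*every* required domain.  For the trehalose-6-phosphate synthase (TPS)
family the defaults are the glycosyltransferase (synthase) catalytic domain
plus the trehalose-phosphatase-like domain, both configurable.

Per-protein characterization mirrors the classical ProtParam/ScanProsite
outputs: average molecular weight, isoelectric point from the
Henderson-Hasselbalch net-charge equation, and occurrence counts of
PROSITE-syntax sequence patterns (phosphorylation, amidation and
N-glycosylation sites).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "AMINO_ACIDS",
    "RESIDUE_MASSES",
    "WATER_MASS",
    "PKA_TABLE",
    "DEFAULT_PATTERNS",
    "DEFAULT_REQUIRED_DOMAINS",
    "DomainHit",
    "read_domain_hits",
    "filter_by_domains",
    "molecular_weight",
    "isoelectric_point",
    "net_charge",
    "compile_prosite",
    "prosite_scan",
    "census_table",
    "family_summary",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Average residue (amino-acid minus water) masses in Da.
RESIDUE_MASSES = {
    "A": 71.0788, "C": 103.1388, "D": 115.0886, "E": 129.1155,
    "F": 147.1766, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "K": 128.1741, "L": 113.1594, "M": 131.1926, "N": 114.1038,
    "P": 97.1167, "Q": 128.1307, "R": 156.1875, "S": 87.0782,
    "T": 101.1051, "V": 99.1326, "W": 186.2132, "Y": 163.1760,
}
WATER_MASS = 18.0153

# Bjellqvist-style pKa set: termini plus ionizable side chains.
PKA_TABLE = {
    "Nterm": 9.094, "Cterm": 3.090,
    "D": 3.872, "E": 4.412, "C": 7.555, "Y": 10.85,
    "H": 5.637, "K": 9.052, "R": 11.84,
}
_ACIDIC = ("D", "E", "C", "Y")   # plus C-terminus
_BASIC = ("H", "K", "R")         # plus N-terminus

# Canonical PROSITE patterns for the six census site columns.
DEFAULT_PATTERNS = {
    "ck2": "[ST]-x(2)-[DE]",
    "pkc": "[ST]-x-[RK]",
    "tyr": "[RK]-x(2,3)-[DE]-x(2,3)-Y",
    "camp": "[RK](2)-x-[ST]",
    "amidation": "x-G-[RK]-[RK]",
    "asn_glycosylation": "N-{P}-[ST]-{P}",
}

DEFAULT_REQUIRED_DOMAINS = frozenset({"Glyco_transf_20", "Trehalose_PPase"})


def _check_sequence(seq: str, strict: bool = True) -> str:
    if not seq:
        raise ValueError("empty protein sequence")
    seq = seq.upper()
    bad = set(seq) - set(AMINO_ACIDS)
    if bad:
        if strict:
            raise ValueError(f"invalid residue letters: {sorted(bad)}")
        warnings.warn(f"skipping ambiguous residues {sorted(bad)}")
        seq = "".join(c for c in seq if c in AMINO_ACIDS)
        if not seq:
            raise ValueError("no valid residues after removing ambiguities")
    return seq


# -- domain filter -------------------------------------------------------


@dataclass(frozen=True)
class DomainHit:
    protein_id: str
    domain_id: str
    evalue: float
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("e-value must be >= 0")
        if not (1 <= self.start <= self.end):
            raise ValueError("envelope coordinates must satisfy 1 <= start <= end")


def read_domain_hits(path: str | Path) -> list[DomainHit]:
    """Read a (protein_id, domain_id, evalue, start, end) TSV of domain hits."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["protein_id", "domain_id", "evalue", "start", "end"],
                     header=0)
    return [DomainHit(r.protein_id, r.domain_id, float(r.evalue),
                      int(r.start), int(r.end))
            for r in df.itertuples(index=False)]


def filter_by_domains(
    hits: list[DomainHit],
    required: set[str] | frozenset[str] = DEFAULT_REQUIRED_DOMAINS,
    e_cutoff: float = 1e-5,
) -> set[str]:
    """Proteins holding >=1 hit at e <= e_cutoff for every required domain."""
    if not required:
        raise ValueError("required domain set must not be empty "
                         "(an empty set would retain everything)")
    found: dict[str, set[str]] = {}
    for h in hits:
        if h.domain_id in required and h.evalue <= e_cutoff:
            found.setdefault(h.protein_id, set()).add(h.domain_id)
    return {pid for pid, doms in found.items() if doms >= set(required)}


# -- physicochemical properties -----------------------------------------


def molecular_weight(sequence: str, strict: bool = True) -> float:
    """Average molecular weight in kDa (residue masses plus one water)."""
    seq = _check_sequence(sequence, strict=strict)
    return (sum(RESIDUE_MASSES[c] for c in seq) + WATER_MASS) / 1000.0


def net_charge(sequence: str, ph: float, pka: dict[str, float] = PKA_TABLE,
               strict: bool = True) -> float:
    """Net charge at a given pH from the Henderson-Hasselbalch sum."""
    seq = _check_sequence(sequence, strict=strict)
    pos = 1.0 / (1.0 + 10 ** (ph - pka["Nterm"]))
    neg = 1.0 / (1.0 + 10 ** (pka["Cterm"] - ph))
    for aa in _BASIC:
        n = seq.count(aa)
        if n:
            pos += n / (1.0 + 10 ** (ph - pka[aa]))
    for aa in _ACIDIC:
        n = seq.count(aa)
        if n:
            neg += n / (1.0 + 10 ** (pka[aa] - ph))
    return pos - neg


def isoelectric_point(sequence: str, pka: dict[str, float] = PKA_TABLE,
                      tol: float = 1e-4, strict: bool = True) -> float:
    """pH at which the net charge is zero, by bisection on [0, 14]."""
    seq = _check_sequence(sequence, strict=strict)
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if net_charge(seq, mid, pka=pka) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


# -- PROSITE pattern scanning -------------------------------------------

_ELEM_RE = re.compile(
    r"(?:\[(?P<set>[A-Z]+)\]|\{(?P<neg>[A-Z]+)\}|(?P<res>[A-Zx]))"
    r"(?:\((?P<lo>\d+)(?:,(?P<hi>\d+))?\))?"
)


def compile_prosite(pattern: str) -> re.Pattern:
    """Compile a PROSITE-syntax pattern into a Python regex.

    Supports residue letters, ``x`` wildcards, ``[..]`` alternatives,
    ``{..}`` exclusions, ``(n)``/``(n,m)`` repeats, and the ``<``/``>``
    anchors.  Raises ``ValueError`` on malformed input.
    """
    pat = pattern.strip().rstrip(".")
    anchored_start = pat.startswith("<")
    anchored_end = pat.endswith(">")
    pat = pat.lstrip("<").rstrip(">")
    out = []
    for elem in pat.split("-"):
        if not elem:
            raise ValueError(f"malformed PROSITE pattern: {pattern!r}")
        m = _ELEM_RE.fullmatch(elem)
        if m is None:
            raise ValueError(f"malformed PROSITE element {elem!r} in {pattern!r}")
        if m.group("set"):
            piece = f"[{m.group('set')}]"
        elif m.group("neg"):
            piece = f"[^{m.group('neg')}]"
        elif m.group("res") == "x":
            piece = "."
        else:
            piece = m.group("res")
        if m.group("lo"):
            lo = m.group("lo")
            hi = m.group("hi")
            piece += f"{{{lo},{hi}}}" if hi else f"{{{lo}}}"
        out.append(piece)
    body = "".join(out)
    if anchored_start:
        body = "^" + body
    if anchored_end:
        body += "$"
    return re.compile(body)


def prosite_scan(sequence: str, patterns: dict[str, str] | None = None) -> dict[str, int]:
    """Count pattern occurrences over all start positions (overlaps allowed)."""
    patterns = DEFAULT_PATTERNS if patterns is None else patterns
    counts = {}
    for name, pat in patterns.items():
        rx = compile_prosite(pat)
        counts[name] = len(re.findall(f"(?=({rx.pattern}))", sequence))
    return counts


# -- census table & summary ---------------------------------------------


def census_table(
    proteins: dict[str, str],
    family_ids: set[str],
    names: dict[str, str] | None = None,
    patterns: dict[str, str] | None = None,
    strict: bool = True,
) -> pd.DataFrame:
    """Per-member census: length, MW (kDa), pI, and pattern site counts."""
    patterns = DEFAULT_PATTERNS if patterns is None else patterns
    rows = []
    for pid in sorted(family_ids):
        if pid not in proteins:
            raise KeyError(f"family id {pid} not in protein set")
        seq = proteins[pid]
        row = {
            "gene_id": pid,
            "name": (names or {}).get(pid, pid),
            "length": len(seq),
            "mw_kda": round(molecular_weight(seq, strict=strict), 2),
            "pi": round(isoelectric_point(seq, strict=strict), 2),
        }
        row.update(prosite_scan(seq, patterns))
        rows.append(row)
    return pd.DataFrame(rows)


def family_summary(rows: pd.DataFrame) -> dict[str, float]:
    """Min/max/mean of length, molecular weight and pI (means at 2 dp)."""
    if len(rows) == 0:
        raise ValueError("empty census table")
    out = {}
    for col in ("length", "mw_kda", "pi"):
        vals = rows[col].astype(float)
        out[f"{col}_min"] = float(vals.min())
        out[f"{col}_max"] = float(vals.max())
        out[f"{col}_mean"] = round(float(vals.mean()), 2)
    return out
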