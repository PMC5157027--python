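"""Ka/Ks estimation, selection calls, divergence dating and Ks peaks.

Ka and Ks are computed by Nei-Gojobori-style counting on a codon
alignment: per-codon synonymous/non-synonymous site fractions under the
standard genetic code, differences averaged over all minimal
substitution pathways (pathways through stop codons excluded), and the
one-parameter multiple-hit correction K = -(3/4)·ln(1 - (4/3)·p).
Divergence times come from t = Ks / (2r) with a neutral per-site
per-year substitution rate r (default 2.6e-9), reported in MYA.
Ks-distribution peaks are the mode of a Gaussian kernel density
evaluated on a 1e-4-spaced grid.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.stats import gaussian_kde

from ._align import aligned_protein_strings
from .core_io import LtpMinerError

BASES = "ACGT"

_STANDARD_CODE = {}


def _codon_table() -> dict[str, str]:
    global _STANDARD_CODE
    if not _STANDARD_CODE:
        from Bio.Data.CodonTable import standard_dna_table

        table = dict(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            table[stop] = "*"
        _STANDARD_CODE = table
    return _STANDARD_CODE


def translate_codon(codon: str) -> Optional[str]:
    """Amino acid for a codon ('*' for stop), or None if ambiguous."""
    return _codon_table().get(codon)


@lru_cache(maxsize=None)
def codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, non-synonymous) site counts of one sense codon.

    Each of the three positions contributes the fraction of its three
    possible changes that are synonymous; changes to stop codons count
    as non-synonymous, so the two counts always sum to 3.
    """
    aa = translate_codon(codon)
    if aa is None or aa == "*":
        raise ValueError(f"not a sense codon: {codon!r}")
    syn = 0.0
    for i in range(3):
        for b in BASES:
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1:]
            if translate_codon(alt) == aa:
                syn += 1.0 / 3.0
    return (syn, 3.0 - syn)


@lru_cache(maxsize=None)
def codon_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, non-synonymous) differences between two sense codons.

    Codons differing at k positions are compared along all k! orderings
    of single-base steps; orderings passing through a stop codon are
    discarded (when every ordering is blocked, all are used and the
    stop-creating steps count as non-synonymous).  Each step is scored
    synonymous or not by the translation before/after, and the counts
    are averaged over the admissible orderings with equal weight.
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return (0.0, 0.0)

    def walk(order: Sequence[int]) -> Optional[tuple[float, float]]:
        cur = codon_a
        sd = nd = 0.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            aa_from, aa_to = translate_codon(cur), translate_codon(nxt)
            if aa_to == "*" and nxt != codon_b:
                blocked = True
            if aa_from == aa_to:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        return None if blocked else (sd, nd)

    paths = [walk(order) for order in itertools.permutations(diff_pos)]
    open_paths = [p for p in paths if p is not None]
    if not open_paths:  # all pathways pass a stop; fall back to all
        open_paths = []
        for order in itertools.permutations(diff_pos):
            cur = codon_a
            sd = nd = 0.0
            for pos in order:
                nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
                if translate_codon(cur) == translate_codon(nxt):
                    sd += 1.0
                else:
                    nd += 1.0
                cur = nxt
            open_paths.append((sd, nd))
    sd = sum(p[0] for p in open_paths) / len(open_paths)
    nd = sum(p[1] for p in open_paths) / len(open_paths)
    return (sd, nd)


@dataclass(frozen=True)
class CodonAlignment:
    """Two gapped codon sequences of equal length (gaps in whole codons)."""

    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise LtpMinerError("codon alignment sequences differ in length")
        if len(self.seq_a) % 3 != 0:
            raise LtpMinerError("codon alignment length not divisible by 3")
        for codon_a, codon_b in self.codon_pairs(include_gaps=True):
            for c in (codon_a, codon_b):
                if ("-" in c) and c != "---":
                    raise LtpMinerError(f"gap not in whole-codon units: {c!r}")
            if c_is_stop(codon_a) or c_is_stop(codon_b):
                raise LtpMinerError("internal stop codon in alignment")

    def codon_pairs(self, include_gaps: bool = False):
        for i in range(0, len(self.seq_a), 3):
            a, b = self.seq_a[i:i + 3], self.seq_b[i:i + 3]
            if include_gaps or ("-" not in a and "-" not in b):
                yield a, b

    @property
    def ungapped_codons(self) -> int:
        return sum(1 for _ in self.codon_pairs())


def c_is_stop(codon: str) -> bool:
    return translate_codon(codon) == "*"


def align_codons(protein_a: str, protein_b: str, cds_a: str, cds_b: str) -> CodonAlignment:
    """Back-translate a global protein alignment onto the two CDSs."""
    for name, prot, cds in (("a", protein_a, cds_a), ("b", protein_b, cds_b)):
        trimmed = cds[:-3] if c_is_stop(cds[-3:]) else cds
        if len(trimmed) != 3 * len(prot):
            raise LtpMinerError(
                f"sequence {name}: CDS length {len(trimmed)} does not match "
                f"protein length {len(prot)}"
            )
        for i, aa in enumerate(prot):
            trans = translate_codon(trimmed[3 * i:3 * i + 3])
            if trans != aa:
                raise LtpMinerError(
                    f"sequence {name}: translation mismatch at residue {i + 1} "
                    f"({trans} != {aa})"
                )
    aln_a, aln_b = aligned_protein_strings(protein_a, protein_b)
    out_a, out_b = [], []
    ia = ib = 0
    cds_a = cds_a[:-3] if c_is_stop(cds_a[-3:]) else cds_a
    cds_b = cds_b[:-3] if c_is_stop(cds_b[-3:]) else cds_b
    for ca, cb in zip(aln_a, aln_b):
        if ca == "-":
            out_a.append("---")
        else:
            out_a.append(cds_a[3 * ia:3 * ia + 3])
            ia += 1
        if cb == "-":
            out_b.append("---")
        else:
            out_b.append(cds_b[3 * ib:3 * ib + 3])
            ib += 1
    return CodonAlignment(seq_a="".join(out_a), seq_b="".join(out_b))


def jukes_cantor(p: float) -> float:
    """One-parameter multiple-hit correction; inf when saturated."""
    if p < 0:
        raise ValueError("negative proportion")
    if p == 0:
        return 0.0
    if p >= 0.75:
        return math.inf
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


@dataclass(frozen=True)
class KaKsResult:
    ka: float
    ks: float
    ratio: Optional[float]
    n_sites: float
    s_sites: float
    nd: float
    sd: float
    selection: str  # purifying | positive | neutral | undefined
    codons_used: int
    codons_skipped: int = 0

    @property
    def saturated(self) -> bool:
        return not (math.isfinite(self.ka) and math.isfinite(self.ks))


def selection_call(ka: float, ks: float) -> str:
    if ks == 0 or not math.isfinite(ks) or not math.isfinite(ka):
        return "undefined"
    ratio = ka / ks
    if ratio < 1:
        return "purifying"
    if ratio > 1:
        return "positive"
    return "neutral"


def ng86_kaks(aln: CodonAlignment) -> KaKsResult:
    """Nei-Gojobori counting Ka/Ks over the ungapped codon pairs.

    Codons containing ambiguous characters are dropped (tallied in
    ``codons_skipped``).  Saturated proportions (p >= 3/4) yield an
    infinite, flagged estimate rather than a silent number.
    """
    s_a = s_b = 0.0
    sd = nd = 0.0
    used = skipped = 0
    for codon_a, codon_b in aln.codon_pairs():
        if any(c not in BASES for c in codon_a + codon_b):
            skipped += 1
            continue
        sa, _ = codon_sites(codon_a)
        sb, _ = codon_sites(codon_b)
        s_a += sa
        s_b += sb
        d_s, d_n = codon_differences(codon_a, codon_b)
        sd += d_s
        nd += d_n
        used += 1
    if used == 0:
        raise LtpMinerError("no usable codon pairs in alignment")
    s_sites = (s_a + s_b) / 2.0
    n_sites = 3.0 * used - s_sites
    p_s = sd / s_sites if s_sites > 0 else 0.0
    p_n = nd / n_sites if n_sites > 0 else 0.0
    ks = jukes_cantor(p_s)
    ka = jukes_cantor(p_n)
    ratio = ka / ks if (math.isfinite(ka) and math.isfinite(ks) and ks > 0) else None
    return KaKsResult(
        ka=ka,
        ks=ks,
        ratio=ratio,
        n_sites=n_sites,
        s_sites=s_sites,
        nd=nd,
        sd=sd,
        selection=selection_call(ka, ks),
        codons_used=used,
        codons_skipped=skipped,
    )


@dataclass(frozen=True)
class DatingConfig:
    """Neutral substitution rate per site per year."""

    r: float = 2.6e-9

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("substitution rate must be positive")


def age_mya(ks: float, cfg: DatingConfig = DatingConfig()) -> float:
    """Divergence age in million years: t = Ks / (2r)."""
    if ks < 0:
        raise ValueError("Ks must be non-negative")
    return ks / (2.0 * cfg.r) / 1.0e6


@dataclass(frozen=True)
class KsPeak:
    mode: float
    bandwidth: float


def ks_peak(ks_values: Iterable[float], bandwidth: Optional[float] = None) -> KsPeak:
    """Mode of the Ks distribution by Gaussian KDE on a 1e-4 grid."""
    values = np.asarray([k for k in ks_values if math.isfinite(k)], dtype=float)
    if values.size < 5:
        raise LtpMinerError("need at least 5 finite Ks values for a peak")
    if np.ptp(values) == 0:
        return KsPeak(mode=float(values[0]), bandwidth=0.0)
    kde = gaussian_kde(values, bw_method=bandwidth)
    grid = np.arange(0.0, values.max() + 1e-4, 1e-4)
    density = kde(grid)
    mode = float(grid[int(np.argmax(density))])
    return KsPeak(mode=mode, bandwidth=float(kde.factor * values.std(ddof=1)))
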