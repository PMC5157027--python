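"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by exhaustive enumeration (and via
Biopython's translator rather than the package's codon table) so they
share no code path with the implementations they check.
"""

from __future__ import annotations

import itertools

from Bio.Seq import Seq

from ltpminer.motif8cm import ScanBounds, valid_assignment


def brute_scan(seq: str, bounds: ScanBounds) -> list[tuple[int, ...]]:
    """All valid 8 CM assignments by enumerating 8-subsets of cysteines."""
    cys = [i for i, a in enumerate(seq) if a == "C"]
    return sorted(
        combo
        for combo in itertools.combinations(cys, 8)
        if valid_assignment(seq, combo, bounds)
    )


def _tr(codon: str) -> str:
    return str(Seq(codon).translate())


def oracle_codon_sites(codon: str) -> tuple[float, float]:
    """Synonymous/non-synonymous site counts by direct enumeration."""
    aa = _tr(codon)
    syn = 0.0
    for i in range(3):
        for b in "ACGT":
            if b == codon[i]:
                continue
            if _tr(codon[:i] + b + codon[i + 1:]) == aa:
                syn += 1 / 3
    return syn, 3 - syn


def oracle_codon_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged differences by recursive enumeration of orders."""
    diffs = [i for i in range(3) if codon_a[i] != codon_b[i]]
    outcomes: list[tuple[float, float, bool]] = []

    def rec(cur: str, remaining: list[int], sd: float, nd: float, blocked: bool):
        if not remaining:
            outcomes.append((sd, nd, blocked))
            return
        for p in remaining:
            nxt = cur[:p] + codon_b[p] + cur[p + 1:]
            syn_step = _tr(cur) == _tr(nxt)
            rec(
                nxt,
                [q for q in remaining if q != p],
                sd + (1.0 if syn_step else 0.0),
                nd + (0.0 if syn_step else 1.0),
                blocked or (_tr(nxt) == "*" and nxt != codon_b),
            )

    rec(codon_a, diffs, 0.0, 0.0, False)
    usable = [o for o in outcomes if not o[2]] or outcomes
    sd = sum(o[0] for o in usable) / len(usable)
    nd = sum(o[1] for o in usable) / len(usable)
    return sd, nd


def maximal_monotone_chains(
    anchors: list[tuple[int, int]], max_gap: int, min_block: int
) -> set[frozenset[int]]:
    """All inclusion-maximal valid synteny chains by subset enumeration.

    A subset of anchor indices is valid when, ordered by the first
    genome's rank, ranks strictly increase there, strictly increase or
    strictly decrease on the second genome, and consecutive anchors
    differ by at most ``max_gap`` ranks on both sides.
    """
    n = len(anchors)
    valid: set[frozenset[int]] = set()
    for r in range(min_block, n + 1):
        for sub in itertools.combinations(range(n), r):
            ordered = sorted(sub, key=lambda i: anchors[i])
            ras = [anchors[i][0] for i in ordered]
            rbs = [anchors[i][1] for i in ordered]
            if any(ras[j + 1] <= ras[j] for j in range(len(ordered) - 1)):
                continue
            inc = all(rbs[j + 1] > rbs[j] for j in range(len(ordered) - 1))
            dec = all(rbs[j + 1] < rbs[j] for j in range(len(ordered) - 1))
            if not (inc or dec):
                continue
            if any(
                ras[j + 1] - ras[j] > max_gap or abs(rbs[j + 1] - rbs[j]) > max_gap
                for j in range(len(ordered) - 1)
            ):
                continue
            valid.add(frozenset(sub))
    return {s for s in valid if not any(s < o for o in valid)}
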