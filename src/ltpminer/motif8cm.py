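"""Scanner for the eight-cysteine motif (8 CM) of plant nsLTPs.

The backbone is ``C-Xn-C-Xn-CC-CXC-Xn-C-Xn-C``: eight cysteines with the
third and fourth adjacent (the CC dipeptide), the fifth and sixth
separated by exactly one non-cysteine residue (the CXC tripeptide), and
variable inter-cysteine spacers elsewhere.  Scanning enumerates every
assignment of eight cysteines of a mature sequence to the backbone,
anchored on CC and CXC occurrences, subject to per-gap bounds.

The default bounds are an envelope (padded by about two residues) of the
gap lengths observed across the eight Gossypium nsLTP subfamilies;
unconstrained spacers would make the backbone matchable in almost any
cysteine-rich sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

GAP_NAMES = ("head", "g12", "g23", "g45", "g67", "g78", "tail")


@dataclass(frozen=True)
class SpacingVector:
    """Inter-cysteine gap lengths of one 8 CM assignment.

    ``head``/``tail`` count residues before Cys1 / after Cys8; ``g45``
    is the gap between the CC block and the CXC block, ``g67`` between
    the CXC block and Cys7.  The gaps inside CC (0) and CXC (1) are
    fixed by the backbone and not stored.
    """

    head: int
    g12: int
    g23: int
    g45: int
    g67: int
    g78: int
    tail: int

    def __post_init__(self) -> None:
        for name in GAP_NAMES:
            if getattr(self, name) < 0:
                raise ValueError(f"negative gap {name}")

    def core(self) -> tuple[int, int, int, int, int]:
        """The five variable inter-cysteine gaps, excluding head/tail."""
        return (self.g12, self.g23, self.g45, self.g67, self.g78)

    def astuple(self) -> tuple[int, ...]:
        return tuple(getattr(self, n) for n in GAP_NAMES)


@dataclass(frozen=True)
class EightCMMatch:
    """One valid assignment of eight cysteines to the 8 CM backbone."""

    cys_pos: tuple[int, int, int, int, int, int, int, int]
    spacing: SpacingVector

    @property
    def span(self) -> tuple[int, int]:
        return (self.cys_pos[0], self.cys_pos[7])

    @property
    def cxc_center(self) -> int:
        """Index of the X residue of the CXC tripeptide."""
        return self.cys_pos[4] + 1


@dataclass(frozen=True)
class ScanBounds:
    """Per-gap (min, max) limits applied during scanning."""

    head: tuple[int, int] = (0, 16)
    g12: tuple[int, int] = (4, 16)
    g23: tuple[int, int] = (7, 19)
    g45: tuple[int, int] = (6, 22)
    g67: tuple[int, int] = (10, 29)
    g78: tuple[int, int] = (4, 17)
    tail: tuple[int, int] = (0, 40)

    def __post_init__(self) -> None:
        for name in GAP_NAMES:
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"invalid bound for {name}: ({lo}, {hi})")

    def contains(self, name: str, value: int) -> bool:
        lo, hi = getattr(self, name)
        return lo <= value <= hi


DEFAULT_BOUNDS = ScanBounds()


def _spacing_from_positions(pos: tuple[int, ...], seq_len: int) -> SpacingVector:
    c1, c2, c3, _c4, c5, c6, c7, c8 = pos
    return SpacingVector(
        head=c1,
        g12=c2 - c1 - 1,
        g23=c3 - c2 - 1,
        g45=c5 - (c3 + 1) - 1,
        g67=c7 - c6 - 1,
        g78=c8 - c7 - 1,
        tail=seq_len - 1 - c8,
    )


def valid_assignment(seq: str, pos: tuple[int, ...], bounds: ScanBounds) -> bool:
    """Check one strictly increasing 8-tuple of positions against the
    backbone invariants and the gap bounds."""
    if len(pos) != 8 or any(b <= a for a, b in zip(pos, pos[1:])):
        return False
    if any(seq[p] != "C" for p in pos):
        return False
    c1, c2, c3, c4, c5, c6, c7, c8 = pos
    if c4 != c3 + 1 or c6 != c5 + 2:
        return False
    if seq[c5 + 1] == "C":  # the X of CXC is never a cysteine
        return False
    sp = _spacing_from_positions(pos, len(seq))
    return all(bounds.contains(n, getattr(sp, n)) for n in GAP_NAMES)


def scan_8cm(mature_seq: str, bounds: ScanBounds = DEFAULT_BOUNDS) -> list[EightCMMatch]:
    """Enumerate all valid 8 CM assignments in ``mature_seq``.

    Backtracks over cysteine positions anchored on CC dipeptides and CXC
    tripeptides; results are deduplicated and sorted by (Cys1, Cys8).
    """
    if not mature_seq:
        raise ValueError("empty sequence")
    seq = mature_seq.upper()
    n = len(seq)
    cys = [i for i, a in enumerate(seq) if a == "C"]
    if len(cys) < 8:
        return []

    cc_anchors = [c for c in cys if c + 1 < n and seq[c + 1] == "C"]
    cxc_anchors = [
        c
        for c in cys
        if c + 2 < n and seq[c + 1] != "C" and seq[c + 2] == "C"
    ]

    found: set[tuple[int, ...]] = set()
    for c3 in cc_anchors:
        c4 = c3 + 1
        for c5 in cxc_anchors:
            if c5 <= c4 or not bounds.contains("g45", c5 - c4 - 1):
                continue
            c6 = c5 + 2
            for c2 in cys:
                if c2 >= c3 or not bounds.contains("g23", c3 - c2 - 1):
                    continue
                for c1 in cys:
                    if c1 >= c2:
                        continue
                    if not bounds.contains("g12", c2 - c1 - 1):
                        continue
                    if not bounds.contains("head", c1):
                        continue
                    for c7 in cys:
                        if c7 <= c6 or not bounds.contains("g67", c7 - c6 - 1):
                            continue
                        for c8 in cys:
                            if c8 <= c7:
                                continue
                            if not bounds.contains("g78", c8 - c7 - 1):
                                continue
                            if not bounds.contains("tail", n - 1 - c8):
                                continue
                            found.add((c1, c2, c3, c4, c5, c6, c7, c8))

    matches = [
        EightCMMatch(cys_pos=pos, spacing=_spacing_from_positions(pos, n))
        for pos in found
    ]
    matches.sort(key=lambda m: (m.cys_pos[0], m.cys_pos[7], m.cys_pos))
    return matches


def best_match(matches, rules=None):
    """Pick one representative match for a sequence.

    Matches that classify to a subfamily win, highest classification
    score first; ties break on smaller Cys1 position, then smaller span.
    When no match classifies, the match with the smallest Cys1 wins.
    Returns ``None`` for an empty list.
    """
    if not matches:
        return None
    from .classification import classify_type, load_rules

    if rules is None:
        rules = load_rules()

    def key(m: EightCMMatch):
        a = classify_type(m.spacing, rules)
        classified = a.label is not None
        score = a.score if classified else -1
        span = m.cys_pos[7] - m.cys_pos[0]
        return (not classified, -score, m.cys_pos[0], span)

    return min(matches, key=key)
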