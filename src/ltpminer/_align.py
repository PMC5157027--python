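"""Pairwise protein alignment helpers shared across modules.

Thin wrappers around Biopython's PairwiseAligner with BLOSUM62 and
affine gap penalties.  Identity is computed over aligned columns with
terminal gaps excluded; coverage is the trimmed aligned span relative to
a reference length.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices


@lru_cache(maxsize=None)
def _aligner(mode: str, open_gap: float, extend_gap: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    return aligner


@dataclass(frozen=True)
class AlignmentStats:
    score: float
    identity: float  # identical / aligned columns, terminal gaps excluded
    aligned_columns: int  # columns after trimming terminal gaps
    matches: int


def _column_strings(alignment) -> tuple[str, str]:
    text_a, text_b = str(alignment[0]), str(alignment[1])
    return text_a, text_b


def _trim_terminal_gaps(a: str, b: str) -> tuple[str, str]:
    start, end = 0, len(a)
    while start < end and (a[start] == "-" or b[start] == "-"):
        start += 1
    while end > start and (a[end - 1] == "-" or b[end - 1] == "-"):
        end -= 1
    return a[start:end], b[start:end]


def align_stats(
    seq_a: str,
    seq_b: str,
    mode: str = "global",
    open_gap: float = -10.0,
    extend_gap: float = -0.5,
) -> AlignmentStats:
    """Align two protein sequences and report score/identity statistics."""
    aligner = _aligner(mode, open_gap, extend_gap)
    alignment = next(iter(aligner.align(seq_a, seq_b)))
    a, b = _column_strings(alignment)
    if mode == "global":
        a, b = _trim_terminal_gaps(a, b)
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    cols = len(a)
    identity = matches / cols if cols else 0.0
    return AlignmentStats(
        score=float(alignment.score),
        identity=identity,
        aligned_columns=cols,
        matches=matches,
    )


def global_score(seq_a: str, seq_b: str) -> float:
    """Global alignment score only (cheaper than building the alignment)."""
    return float(_aligner("global", -10.0, -0.5).score(seq_a, seq_b))


def aligned_protein_strings(seq_a: str, seq_b: str) -> tuple[str, str]:
    """Gapped strings of the best global protein alignment."""
    aligner = _aligner("global", -10.0, -0.5)
    alignment = next(iter(aligner.align(seq_a, seq_b)))
    return _column_strings(alignment)
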