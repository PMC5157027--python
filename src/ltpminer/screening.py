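"""The nsLTP identification cascade.

Candidates must carry a valid eight-cysteine motif, must not be
proline-rich, must have an N-terminal secretory signal peptide, must not
carry a C-terminal GPI anchor, must not resemble 2S-albumin/amylase-
inhibitor storage proteins, and must be at most 120 residues at
maturity.  Every failing reason is recorded (in cascade order), not just
the first, so the output doubles as a per-candidate audit trail.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from ._align import align_stats
from .core_io import UNKNOWN, FlagTable, ProteinRecord, mature_sequence
from .motif8cm import DEFAULT_BOUNDS, EightCMMatch, ScanBounds, scan_8cm

REASON_CODES = (
    "NO_8CM",
    "MISSING_CYS",
    "PRO_RICH",
    "NO_SIGNAL",
    "GPI",
    "STORAGE_LIKE",
    "TOO_LONG",
    "UNKNOWN_FLAG",
)


@dataclass(frozen=True)
class ScreenConfig:
    max_mature_len: int = 120
    proline_fraction_max: float = 0.15
    require_signal: bool = True
    unknown_flag_policy: str = "reject"  # reject | keep-with-warning
    storage_min_identity: float = 0.40
    storage_min_coverage: float = 0.60

    def __post_init__(self) -> None:
        if not 0 < self.proline_fraction_max < 1:
            raise ValueError("proline_fraction_max must be in (0, 1)")
        if self.unknown_flag_policy not in ("reject", "keep-with-warning"):
            raise ValueError(f"unknown policy {self.unknown_flag_policy!r}")


@dataclass(frozen=True)
class ScreenResult:
    gene_id: str
    kept: bool
    reasons: tuple[str, ...]

    def __post_init__(self) -> None:
        assert self.kept == (len(self.reasons) == 0)


def is_proline_rich(mature_seq: str, cfg: ScreenConfig = ScreenConfig()) -> bool:
    """Proline fraction strictly above the configured threshold."""
    if not mature_seq:
        raise ValueError("empty mature sequence")
    return mature_seq.count("P") / len(mature_seq) > cfg.proline_fraction_max


def storage_like(
    candidate_seq: str,
    exclusion_set: Sequence[ProteinRecord],
    cfg: ScreenConfig = ScreenConfig(),
) -> bool:
    """Similarity to a storage-protein/inhibitor exclusion sequence.

    True when a local alignment to any exclusion sequence reaches the
    configured identity over the configured fraction of the shorter
    sequence.  An empty exclusion set never excludes anything.
    """
    if not exclusion_set:
        return False
    for excl in exclusion_set:
        shorter = min(len(candidate_seq), len(excl.seq))
        stats = align_stats(candidate_seq, excl.seq, mode="local")
        if stats.aligned_columns == 0:
            continue
        coverage = stats.aligned_columns / shorter
        if stats.identity >= cfg.storage_min_identity and coverage >= cfg.storage_min_coverage:
            return True
    return False


def screen_candidates(
    records: Sequence[ProteinRecord],
    flags: FlagTable,
    matches: Optional[Mapping[str, Sequence[EightCMMatch]]] = None,
    cfg: ScreenConfig = ScreenConfig(),
    exclusion_set: Sequence[ProteinRecord] = (),
    bounds: ScanBounds = DEFAULT_BOUNDS,
) -> list[ScreenResult]:
    """Apply the full identification cascade to every candidate.

    ``matches`` maps record id to pre-computed 8 CM matches on the
    mature sequence; records absent from the mapping are scanned here.
    Every input id appears exactly once in the output, in input order.
    """
    results: list[ScreenResult] = []
    for rec in records:
        f = flags.get(rec.id)
        reasons: list[str] = []
        if f is UNKNOWN:
            if cfg.unknown_flag_policy == "reject":
                results.append(
                    ScreenResult(gene_id=rec.id, kept=False, reasons=("UNKNOWN_FLAG",))
                )
                continue
            f = None  # keep-with-warning: treat predictors as absent

        mature = mature_sequence(rec, f if f is not None else UNKNOWN)

        if matches is not None and rec.id in matches:
            rec_matches = matches[rec.id]
        else:
            rec_matches = scan_8cm(mature, bounds)

        if not rec_matches:
            reasons.append("NO_8CM")
            if mature.count("C") < 8:
                reasons.append("MISSING_CYS")
        if is_proline_rich(mature, cfg):
            reasons.append("PRO_RICH")
        if cfg.require_signal and (f is None or not f.has_signal_peptide):
            reasons.append("NO_SIGNAL")
        if f is not None and f.has_gpi_anchor:
            reasons.append("GPI")
        if (f is not None and f.storage_like) or storage_like(rec.seq, exclusion_set, cfg):
            reasons.append("STORAGE_LIKE")
        if len(mature) > cfg.max_mature_len:
            reasons.append("TOO_LONG")

        results.append(
            ScreenResult(gene_id=rec.id, kept=not reasons, reasons=tuple(reasons))
        )
    return results


def results_table(results: Iterable[ScreenResult]) -> pd.DataFrame:
    rows = [
        {"gene_id": r.gene_id, "kept": int(r.kept), "reasons": ";".join(r.reasons)}
        for r in results
    ]
    return pd.DataFrame(rows, columns=["gene_id", "kept", "reasons"])
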