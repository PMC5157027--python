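"""Subfamily typing of nsLTPs from their 8 CM inter-cysteine spacing.

Eight subfamilies (Types I, II, III, IV, V, VI, VIII and IX — no Type
VII occurs in Gossypium) are each described by a finite set of permitted
gap lengths per spacer, shipped as versioned YAML.  A spacing vector is
scored per type by how many of its five core gaps (g12, g23, g45, g67,
g78) lie in the type's sets; a label is assigned only when one type is
the unique best with at least 4 of 5 core gaps matching.  Head and tail
lengths, which are far more variable, serve only to break exact-score
ties.  Near-misses stay UNCLASSIFIED rather than being silently typed.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Iterable, Mapping, Optional

import pandas as pd
import yaml

from .motif8cm import GAP_NAMES, EightCMMatch, SpacingVector

CORE_GAPS = ("g12", "g23", "g45", "g67", "g78")

TYPE_LABELS = ("I", "II", "III", "IV", "V", "VI", "VIII", "IX")

#: residues observed at the X of the CXC tripeptide, by hydropathy
HYDROPHILIC_CXC = frozenset("RGEDQSK")
HYDROPHOBIC_CXC = frozenset("YFLVM")


@dataclass(frozen=True)
class TypeRule:
    """Permitted gap-length sets for one subfamily."""

    label: str
    allowed: Mapping[str, frozenset[int]]  # keyed by GAP_NAMES
    members: int = 0  # family members of this type in the cotton survey

    def core_score(self, spacing: SpacingVector) -> int:
        return sum(1 for g in CORE_GAPS if getattr(spacing, g) in self.allowed[g])

    def flank_score(self, spacing: SpacingVector) -> int:
        return sum(1 for g in ("head", "tail") if getattr(spacing, g) in self.allowed[g])

    def is_exact(self, spacing: SpacingVector) -> bool:
        return all(getattr(spacing, g) in self.allowed[g] for g in GAP_NAMES)


@dataclass(frozen=True)
class TypeAssignment:
    label: Optional[str]  # None = UNCLASSIFIED
    score: int  # core gaps matched by the winning (or best) type, 0-5
    exact: bool
    best_label: Optional[str] = None  # best type even when unclassified

    @property
    def classified(self) -> bool:
        return self.label is not None


@lru_cache(maxsize=None)
def load_rules() -> tuple[TypeRule, ...]:
    """Load the shipped spacing-rule table."""
    with resources.files("ltpminer.data").joinpath("spacing_rules.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    rules = []
    for label, spec in raw["types"].items():
        allowed = {g: frozenset(spec[g]) for g in GAP_NAMES}
        rules.append(TypeRule(label=str(label), allowed=allowed, members=spec.get("members", 0)))
    return tuple(rules)


def classify_type(spacing: SpacingVector, rules: Iterable[TypeRule] = None) -> TypeAssignment:
    """Assign a spacing vector to a subfamily, or UNCLASSIFIED.

    The winner must match at least 4 of the 5 core gaps and be the
    unique best; exact-score ties are broken by head/tail membership and
    remain UNCLASSIFIED if still tied.
    """
    rules = tuple(rules) if rules is not None else load_rules()
    scores = {r.label: r.core_score(spacing) for r in rules}
    by_label = {r.label: r for r in rules}
    top = max(scores.values())
    leaders = [lab for lab, s in scores.items() if s == top]
    best_label = leaders[0] if len(leaders) == 1 else None
    if top < 4:
        return TypeAssignment(label=None, score=top, exact=False, best_label=best_label)
    if len(leaders) > 1:
        flank = {lab: by_label[lab].flank_score(spacing) for lab in leaders}
        fmax = max(flank.values())
        leaders = [lab for lab in leaders if flank[lab] == fmax]
        if len(leaders) > 1:
            return TypeAssignment(label=None, score=top, exact=False, best_label=None)
    winner = leaders[0]
    return TypeAssignment(
        label=winner,
        score=top,
        exact=by_label[winner].is_exact(spacing),
        best_label=winner,
    )


@dataclass(frozen=True)
class CxcClass:
    residue: str
    klass: str  # hydrophilic | hydrophobic | other


def cxc_center_class(match: EightCMMatch, mature_seq: str) -> CxcClass:
    """Hydropathy class of the residue at the X of the CXC tripeptide."""
    residue = mature_seq[match.cxc_center]
    if residue in HYDROPHILIC_CXC:
        klass = "hydrophilic"
    elif residue in HYDROPHOBIC_CXC:
        klass = "hydrophobic"
    else:
        klass = "other"
    return CxcClass(residue=residue, klass=klass)


def summarize_family(assignments: Iterable[TypeAssignment], total: int) -> pd.DataFrame:
    """Per-subfamily counts and percentages of the whole family.

    ``total`` is the full family size used as the denominator (it may
    exceed the sum of classified counts, e.g. when some members were
    typed by other evidence).
    """
    if total <= 0:
        raise ValueError("total must be positive")
    counts = {label: 0 for label in TYPE_LABELS}
    unclassified = 0
    n_classified = 0
    for a in assignments:
        if a.classified:
            counts.setdefault(a.label, 0)
            counts[a.label] += 1
            n_classified += 1
        else:
            unclassified += 1
    if n_classified > total:
        raise ValueError("total smaller than the number of classified members")
    rows = [
        {"type": label, "count": c, "percent": round(100.0 * c / total, 2)}
        for label, c in counts.items()
    ]
    rows.append(
        {
            "type": "UNCLASSIFIED",
            "count": unclassified,
            "percent": round(100.0 * unclassified / total, 2),
        }
    )
    return pd.DataFrame(rows, columns=["type", "count", "percent"])


def cxc_frequency(classes: Iterable[CxcClass]) -> pd.DataFrame:
    """Residue frequencies at the CXC centre, as percent within each
    hydropathy class (so e.g. Leu's share is among hydrophobic-centred
    proteins only)."""
    classes = list(classes)
    if not classes:
        raise ValueError("no CXC classes to summarize")
    df = pd.DataFrame([{"residue": c.residue, "klass": c.klass} for c in classes])
    counts = df.groupby(["klass", "residue"]).size().rename("count").reset_index()
    totals = counts.groupby("klass")["count"].transform("sum")
    counts["percent"] = (100.0 * counts["count"] / totals).round(2)
    return counts[["residue", "klass", "count", "percent"]]
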