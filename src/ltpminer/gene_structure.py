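"""Intron counts and intron position relative to the Cys8 codon.

Cotton nsLTP genes carry 0-2 introns, and where present the introns
cluster a few tens of bp downstream of the codon encoding the eighth
cysteine of the 8 CM.  This module measures that offset: each intron's
genomic position is projected into CDS coordinates on the coding
strand, and the offset is the signed bp distance from the end of the
Cys8 codon (the first bp after the codon is +1; negative values are
upstream of the codon end).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

from .core_io import GeneModel, LtpMinerError
from .motif8cm import EightCMMatch

OUTSIDE = "outside-CDS-projection"


@dataclass(frozen=True)
class IntronReport:
    gene_id: str
    intron_count: int
    offsets: tuple[Union[int, str], ...]  # bp from end of Cys8 codon, or OUTSIDE


def _intron_cds_positions(model: GeneModel) -> list[int]:
    """CDS coordinate at which each intron interrupts, coding strand.

    Exons are stored in genomic order; on the minus strand the coding
    order is reversed, so cumulative exon lengths are taken from the
    rightmost exon.  The returned position q means: q bases of CDS lie
    before the intron.
    """
    lengths = [e - s for s, e in model.exons]
    if model.strand == "-":
        lengths = lengths[::-1]
    positions = []
    cum = 0
    for length in lengths[:-1]:
        cum += length
        positions.append(cum)
    return positions


def intron_report(
    model: GeneModel,
    match: EightCMMatch,
    cleavage_pos: Optional[int] = None,
) -> IntronReport:
    """Offsets of each intron from the end of the Cys8 codon.

    ``match`` was found on the mature peptide; ``cleavage_pos`` (1-based
    residue count of the signal peptide) converts the match's Cys8 index
    back to full-protein coordinates.
    """
    protein = model.protein()
    cys8_res = (cleavage_pos or 0) + match.cys_pos[7]
    if cys8_res >= len(protein):
        raise LtpMinerError(
            f"{model.gene_id}: Cys8 residue index {cys8_res} beyond protein"
        )
    if protein[cys8_res] != "C":
        raise LtpMinerError(
            f"{model.gene_id}: residue {cys8_res + 1} is {protein[cys8_res]}, not C"
        )
    codon_end = 3 * cys8_res + 3  # CDS coordinate just past the Cys8 codon
    offsets: list[Union[int, str]] = []
    for q in _intron_cds_positions(model):
        if q <= 0 or q >= len(model.cds):
            offsets.append(OUTSIDE)
        else:
            offsets.append(q - codon_end)
    return IntronReport(
        gene_id=model.gene_id,
        intron_count=model.intron_count,
        offsets=tuple(offsets),
    )
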