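"""Domain records and file I/O for the nsLTP mining pipeline.

External files use 1-based inclusive coordinates throughout; they are
converted exactly once, at the parsing boundary, to 0-based half-open
coordinates held by :class:`GeneModel`. Annotation flags coming from
external predictors (signal peptide, GPI anchor, storage-protein
similarity) are tri-state: absent genes query as *unknown*, never as
``False``, because this pipeline must not fabricate predictor output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger("ltpminer")

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


class LtpMinerError(ValueError):
    """Base class for pipeline input/consistency errors."""


@dataclass(frozen=True)
class ProteinRecord:
    """A candidate protein entering the identification cascade."""

    id: str
    seq: str
    species: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise LtpMinerError(f"invalid protein id {self.id!r}")
        if len(self.seq) < 1:
            raise LtpMinerError(f"empty sequence for {self.id}")
        bad = set(self.seq) - AA_ALPHABET
        if bad:
            raise LtpMinerError(
                f"{self.id}: non amino-acid characters {sorted(bad)} in sequence"
            )


@dataclass(frozen=True)
class GeneModel:
    """Genomic structure of one gene.

    ``start``/``end`` and exon coordinates are 0-based half-open
    internally (converted from the 1-based inclusive external format).
    ``cds`` is the spliced coding sequence on the coding strand.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]
    cds: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise LtpMinerError(f"{self.gene_id}: strand must be + or -")
        if not (0 <= self.start <= self.end):
            raise LtpMinerError(
                f"{self.gene_id}: start > end ({self.start} > {self.end})"
            )
        prev_end = -1
        for s, e in self.exons:
            if s >= e:
                raise LtpMinerError(f"{self.gene_id}: empty or inverted exon {s}-{e}")
            if s < prev_end:
                raise LtpMinerError(f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = e
        if len(self.cds) % 3 != 0:
            raise LtpMinerError(
                f"{self.gene_id}: CDS length {len(self.cds)} not divisible by 3"
            )

    @property
    def intron_count(self) -> int:
        return max(len(self.exons) - 1, 0)

    def protein(self) -> str:
        """Translate the CDS with the standard code, trimming a final stop."""
        aa = str(Seq(self.cds).translate())
        return aa[:-1] if aa.endswith("*") else aa


#: sentinel returned when a gene has no row in the flags table
UNKNOWN = "unknown"


@dataclass(frozen=True)
class AnnotationFlags:
    """Externally predicted per-gene annotations, consumed as flags."""

    gene_id: str
    has_signal_peptide: bool
    cleavage_pos: Optional[int] = None  # 1-based residue after which mature starts
    has_gpi_anchor: bool = False
    storage_like: bool = False

    def __post_init__(self) -> None:
        if self.has_signal_peptide:
            if self.cleavage_pos is None:
                raise LtpMinerError(
                    f"{self.gene_id}: signal peptide without cleavage position"
                )
            if self.cleavage_pos < 1:
                raise LtpMinerError(f"{self.gene_id}: cleavage_pos must be >= 1")
        elif self.cleavage_pos is not None:
            raise LtpMinerError(
                f"{self.gene_id}: cleavage_pos given but has_signal_peptide is false"
            )


class FlagTable:
    """Mapping gene_id -> AnnotationFlags; missing genes are *unknown*."""

    def __init__(self, flags: Iterable[AnnotationFlags] = ()):
        self._flags: dict[str, AnnotationFlags] = {}
        for f in flags:
            if f.gene_id in self._flags:
                raise LtpMinerError(f"duplicate flags row for {f.gene_id}")
            self._flags[f.gene_id] = f

    def get(self, gene_id: str):
        """Return the flags for ``gene_id``, or the :data:`UNKNOWN` marker."""
        return self._flags.get(gene_id, UNKNOWN)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._flags

    def __len__(self) -> int:
        return len(self._flags)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_fasta(path, species: str = "") -> list[ProteinRecord]:
    """Read a protein FASTA into :class:`ProteinRecord` objects.

    Sequences are uppercased; record order is preserved; duplicate ids
    raise an error naming the id.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise LtpMinerError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(
            ProteinRecord(
                id=rec.id,
                seq=str(rec.seq).upper(),
                species=species,
                description=rec.description,
            )
        )
    if not records:
        logger.warning("no records found in %s", path)
    return records


def write_fasta(records: Sequence[ProteinRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n{r.seq}\n")


def read_cds_fasta(path) -> dict[str, str]:
    """Read a nucleotide FASTA as a gene_id -> CDS mapping."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise LtpMinerError(f"duplicate FASTA id {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq).upper()
    return out


GENE_TABLE_COLUMNS = ["gene_id", "chrom", "strand", "start", "end", "exons", "cds"]


def _parse_exons(text: str, gene_id: str) -> tuple[tuple[int, int], ...]:
    exons = []
    for chunk in str(text).split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        try:
            s, e = chunk.split("-")
            s1, e1 = int(s), int(e)
        except ValueError as exc:
            raise LtpMinerError(f"{gene_id}: malformed exon field {chunk!r}") from exc
        if s1 > e1:
            raise LtpMinerError(f"{gene_id}: exon start > end ({chunk})")
        exons.append((s1 - 1, e1))  # 1-based inclusive -> 0-based half-open
    return tuple(exons)


def read_gene_table(path) -> list[GeneModel]:
    """Read the tab-separated gene-coordinate table (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", comment=None, dtype=str)
    missing = [c for c in GENE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise LtpMinerError(f"gene table {path} lacks columns {missing}")
    models = []
    for row in df.itertuples(index=False):
        start1, end1 = int(row.start), int(row.end)
        if start1 > end1:
            raise LtpMinerError(
                f"{row.gene_id}: start > end ({start1} > {end1}) in {path}"
            )
        models.append(
            GeneModel(
                gene_id=row.gene_id,
                chrom=row.chrom,
                strand=row.strand,
                start=start1 - 1,
                end=end1,
                exons=_parse_exons(row.exons, row.gene_id),
                cds=str(row.cds).upper(),
            )
        )
    return models


def write_gene_table(models: Sequence[GeneModel], path) -> None:
    """Write gene models back to the 1-based inclusive external format."""
    rows = []
    for m in models:
        rows.append(
            {
                "gene_id": m.gene_id,
                "chrom": m.chrom,
                "strand": m.strand,
                "start": m.start + 1,
                "end": m.end,
                "exons": ";".join(f"{s + 1}-{e}" for s, e in m.exons),
                "cds": m.cds,
            }
        )
    pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


FLAGS_COLUMNS = [
    "gene_id",
    "has_signal_peptide",
    "cleavage_pos",
    "has_gpi_anchor",
    "storage_like",
]


def read_flags(path) -> FlagTable:
    """Read the annotation-flags TSV (booleans as 0/1, cleavage_pos or '.')."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in FLAGS_COLUMNS if c not in df.columns]
    if missing:
        raise LtpMinerError(f"flags table {path} lacks columns {missing}")
    flags = []
    for row in df.itertuples(index=False):
        has_sig = bool(int(row.has_signal_peptide))
        cleave_raw = str(row.cleavage_pos).strip()
        cleave = None if cleave_raw in {".", "", "nan"} else int(float(cleave_raw))
        if cleave is not None and not has_sig:
            raise LtpMinerError(
                f"{row.gene_id}: cleavage_pos given with has_signal_peptide=0"
            )
        flags.append(
            AnnotationFlags(
                gene_id=row.gene_id,
                has_signal_peptide=has_sig,
                cleavage_pos=cleave,
                has_gpi_anchor=bool(int(row.has_gpi_anchor)),
                storage_like=bool(int(row.storage_like)),
            )
        )
    return FlagTable(flags)


def write_flags(flags: Iterable[AnnotationFlags], path) -> None:
    rows = []
    for f in flags:
        rows.append(
            {
                "gene_id": f.gene_id,
                "has_signal_peptide": int(f.has_signal_peptide),
                "cleavage_pos": f.cleavage_pos if f.cleavage_pos is not None else ".",
                "has_gpi_anchor": int(f.has_gpi_anchor),
                "storage_like": int(f.storage_like),
            }
        )
    pd.DataFrame(rows, columns=FLAGS_COLUMNS).to_csv(path, sep="\t", index=False)


def mature_sequence(record: ProteinRecord, flags) -> str:
    """Mature peptide of ``record``: the part after the signal-peptide
    cleavage site when that is known, else the full sequence."""
    if flags is not UNKNOWN and isinstance(flags, AnnotationFlags):
        if flags.has_signal_peptide and flags.cleavage_pos is not None:
            if flags.cleavage_pos >= len(record.seq):
                raise LtpMinerError(
                    f"{record.id}: cleavage_pos {flags.cleavage_pos} >= length"
                )
            return record.seq[flags.cleavage_pos:]
    return record.seq


def load_duplicated_pair_table() -> pd.DataFrame:
    """Curated Ka/Ks/age estimates for the 18 duplicated nsLTP gene pairs
    reported across G. arboreum, G. raimondii and G. hirsutum."""
    with resources.files("ltpminer.data").joinpath("duplicated_pairs_kaks.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"ka": str, "ks": str, "ratio": str})
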