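"""Synthetic genomes, proteomes and codon pairs with known ground truth.

Everything the pipeline consumes can be generated here: typed nsLTP
proteins built from the subfamily spacing rules, decoy proteins that
each violate exactly one screening filter, chromosome layouts with
planted tandem clusters and dispersed segmental copies, codon-sequence
pairs evolved to controlled Ka and Ks, and an allotetraploid merge with
per-subfamily ortholog losses (emulating the A/D diploid cotton genomes
and their allotetraploid descendant).  All randomness flows from one
seed; regenerated datasets are byte-identical.  Every generator records
its ground truth so tests can check recovery exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core_io import AnnotationFlags, FlagTable, GeneModel, LtpMinerError, ProteinRecord
from .classification import HYDROPHILIC_CXC, HYDROPHOBIC_CXC, TypeRule, load_rules
from .molecular_evolution import (
    BASES,
    CodonAlignment,
    codon_sites,
    ng86_kaks,
    translate_codon,
)
from .motif8cm import SpacingVector

NON_CYS = "ADEFGHIKLMNPQRSTVWY"  # the 19 spacer residues (never C)
HYDROPHOBIC = "AFILMVW"
STOP_CODONS = ("TAA", "TAG", "TGA")


def _codons_for_aa() -> dict[str, tuple[str, ...]]:
    table: dict[str, list[str]] = {}
    for b1 in BASES:
        for b2 in BASES:
            for b3 in BASES:
                codon = b1 + b2 + b3
                aa = translate_codon(codon)
                if aa and aa != "*":
                    table.setdefault(aa, []).append(codon)
    return {aa: tuple(sorted(cs)) for aa, cs in table.items()}


CODONS_FOR_AA = _codons_for_aa()


# ---------------------------------------------------------------------------
# proteins
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimProtein:
    """A generated protein plus its planted ground truth."""

    record: ProteinRecord
    kind: str  # "nsltp" or a decoy kind
    signal_len: int  # 0 = no signal peptide
    type_label: Optional[str] = None
    spacing: Optional[SpacingVector] = None
    cxc_residue: Optional[str] = None
    source_id: Optional[str] = None  # for duplicate/ortholog copies

    @property
    def mature(self) -> str:
        return self.record.seq[self.signal_len:]

    def flags(self, gpi: bool = False) -> AnnotationFlags:
        has_sig = self.signal_len > 0
        return AnnotationFlags(
            gene_id=self.record.id,
            has_signal_peptide=has_sig,
            cleavage_pos=self.signal_len if has_sig else None,
            has_gpi_anchor=gpi,
        )


def _spacer(rng: np.random.Generator, length: int, alphabet: str = NON_CYS) -> str:
    return "".join(rng.choice(list(alphabet), size=length)) if length else ""


def generate_signal_peptide(rng: np.random.Generator) -> str:
    """A 21-27 residue, hydrophobic-biased N-terminal signal peptide."""
    length = int(rng.integers(21, 28))
    body = [
        str(rng.choice(list(HYDROPHOBIC)))
        if rng.random() < 0.7
        else str(rng.choice(list(NON_CYS)))
        for _ in range(length - 1)
    ]
    return "M" + "".join(body)


def _pick_cxc_residue(type_label: str, rng: np.random.Generator) -> str:
    """Type I centres are hydrophilic; the other subfamilies carry a
    hydrophobic centre with leucine strongly preferred."""
    if type_label == "I":
        return str(rng.choice(sorted(HYDROPHILIC_CXC)))
    if rng.random() < 0.754:
        return "L"
    return str(rng.choice(sorted(HYDROPHOBIC_CXC - {"L"})))


def _assemble_mature(
    spacing: SpacingVector, cxc: str, rng: np.random.Generator, spacer_alphabet: str = NON_CYS
) -> str:
    return (
        _spacer(rng, spacing.head, spacer_alphabet)
        + "C"
        + _spacer(rng, spacing.g12, spacer_alphabet)
        + "C"
        + _spacer(rng, spacing.g23, spacer_alphabet)
        + "CC"
        + _spacer(rng, spacing.g45, spacer_alphabet)
        + "C"
        + cxc
        + "C"
        + _spacer(rng, spacing.g67, spacer_alphabet)
        + "C"
        + _spacer(rng, spacing.g78, spacer_alphabet)
        + "C"
        + _spacer(rng, spacing.tail, spacer_alphabet)
    )


def _sample_spacing(rule: TypeRule, rng: np.random.Generator) -> SpacingVector:
    gaps = {g: int(rng.choice(sorted(rule.allowed[g]))) for g in
            ("head", "g12", "g23", "g45", "g67", "g78", "tail")}
    return SpacingVector(**gaps)


def generate_nsltp(
    type_label: str,
    rules: Sequence[TypeRule],
    rng: np.random.Generator,
    gene_id: str = "sim1",
    species: str = "",
    max_mature_len: int = 120,
) -> SimProtein:
    """One nsLTP of the requested subfamily with planted spacing.

    Gap lengths are drawn uniformly from the subfamily's permitted sets
    (resampled if the mature sequence would exceed ``max_mature_len``),
    spacers from the 19 non-cysteine residues, and a signal peptide of
    21-27 hydrophobic-biased residues is prepended.
    """
    rule = next((r for r in rules if r.label == type_label), None)
    if rule is None:
        raise LtpMinerError(f"unknown subfamily {type_label!r}")
    for _ in range(100):
        spacing = _sample_spacing(rule, rng)
        if spacing.head + spacing.tail + sum(spacing.core()) + 9 <= max_mature_len:
            break
    else:  # pragma: no cover - rule sets always admit a short combination
        raise LtpMinerError(f"cannot fit a type {type_label} motif in {max_mature_len} aa")
    cxc = _pick_cxc_residue(type_label, rng)
    mature = _assemble_mature(spacing, cxc, rng)
    signal = generate_signal_peptide(rng)
    return SimProtein(
        record=ProteinRecord(id=gene_id, seq=signal + mature, species=species),
        kind="nsltp",
        signal_len=len(signal),
        type_label=type_label,
        spacing=spacing,
        cxc_residue=cxc,
    )


DECOY_KINDS = ("missing_cys", "proline_rich", "no_signal", "gpi", "too_long", "storage_like")


def make_exclusion_record(
    rng: np.random.Generator, excl_id: str = "storage_excl"
) -> ProteinRecord:
    """A synthetic stand-in for one storage-protein exclusion sequence.

    Built on an nsLTP-like scaffold so that a mutated copy of it (the
    ``storage_like`` decoy) still carries a valid 8 CM and fails *only*
    the similarity filter.  Real 2S-albumin/amylase-inhibitor sequences
    are not shipped; this record exercises the rule, not the biology.
    """
    prot = generate_nsltp("I", load_rules(), rng, gene_id=excl_id)
    return ProteinRecord(id=excl_id, seq=prot.mature, description="synthetic exclusion")


def generate_decoy(
    kind: str,
    rng: np.random.Generator,
    rules: Sequence[TypeRule] = None,
    gene_id: str = "decoy1",
    species: str = "",
    exclusion: Optional[ProteinRecord] = None,
) -> SimProtein:
    """A decoy protein violating exactly one screening filter."""
    if kind not in DECOY_KINDS:
        raise LtpMinerError(f"unknown decoy kind {kind!r}")
    rules = tuple(rules) if rules is not None else load_rules()

    if kind == "missing_cys":
        base = generate_nsltp("IV", rules, rng, gene_id=gene_id, species=species)
        seq = base.record.seq
        c1 = base.signal_len + base.spacing.head  # first motif cysteine
        seq = seq[:c1] + "A" + seq[c1 + 1:]
        return replace(
            base,
            record=ProteinRecord(id=gene_id, seq=seq, species=species),
            kind=kind,
            type_label=None,
            spacing=None,
        )

    if kind == "proline_rich":
        rule = next(r for r in rules if r.label == "II")
        spacing = _sample_spacing(rule, rng)
        cxc = "L"
        mature = _assemble_mature(spacing, cxc, rng, spacer_alphabet="PPPPPPAGST")
        signal = generate_signal_peptide(rng)
        return SimProtein(
            record=ProteinRecord(id=gene_id, seq=signal + mature, species=species),
            kind=kind,
            signal_len=len(signal),
            spacing=spacing,
            cxc_residue=cxc,
        )

    if kind == "no_signal":
        base = generate_nsltp("V", rules, rng, gene_id=gene_id, species=species)
        return replace(
            base,
            record=ProteinRecord(id=gene_id, seq=base.mature, species=species),
            kind=kind,
            signal_len=0,
        )

    if kind == "gpi":
        base = generate_nsltp("II", rules, rng, gene_id=gene_id, species=species)
        return replace(base, kind=kind)

    if kind == "too_long":
        # a valid Type V motif padded with the longest in-bounds tail so
        # the mature peptide exceeds 120 aa while the scan still matches
        rule = next(r for r in rules if r.label == "V")
        spacing = _sample_spacing(rule, rng)
        spacing = SpacingVector(
            head=7,
            g12=spacing.g12,
            g23=spacing.g23,
            g45=12,
            g67=spacing.g67,
            g78=spacing.g78,
            tail=40,
        )
        cxc = _pick_cxc_residue("V", rng)
        mature = _assemble_mature(spacing, cxc, rng)
        assert len(mature) > 120
        signal = generate_signal_peptide(rng)
        return SimProtein(
            record=ProteinRecord(id=gene_id, seq=signal + mature, species=species),
            kind=kind,
            signal_len=len(signal),
            spacing=spacing,
            cxc_residue=cxc,
        )

    # storage_like: mutate ~40% of the spacer residues of the exclusion
    # sequence, leaving the motif cysteines in place (~60% identity)
    if exclusion is None:
        raise LtpMinerError("storage_like decoy needs the exclusion record")
    seq = list(exclusion.seq)
    for i, aa in enumerate(seq):
        if aa != "C" and rng.random() < 0.40:
            seq[i] = str(rng.choice([a for a in NON_CYS if a != aa]))
    mature = "".join(seq)
    signal = generate_signal_peptide(rng)
    return SimProtein(
        record=ProteinRecord(id=gene_id, seq=signal + mature, species=species),
        kind="storage_like",
        signal_len=len(signal),
        source_id=exclusion.id,
    )


EXPECTED_DECOY_REASONS = {
    "missing_cys": ("NO_8CM", "MISSING_CYS"),
    "proline_rich": ("PRO_RICH",),
    "no_signal": ("NO_SIGNAL",),
    "gpi": ("GPI",),
    "too_long": ("TOO_LONG",),
    "storage_like": ("STORAGE_LIKE",),
}


# ---------------------------------------------------------------------------
# codon evolution
# ---------------------------------------------------------------------------

def back_translate(protein: str, rng: np.random.Generator, add_stop: bool = True) -> str:
    """CDS for a protein with uniform synonymous codon choice."""
    codons = [str(rng.choice(CODONS_FOR_AA[aa])) for aa in protein]
    if add_stop:
        codons.append(str(rng.choice(STOP_CODONS)))
    return "".join(codons)


def _substitution_choices(codon: str, synonymous: bool) -> list[tuple[int, str]]:
    """Single-base changes of ``codon`` that are (non)synonymous and
    never create a stop codon."""
    aa = translate_codon(codon)
    out = []
    for i in range(3):
        for b in BASES:
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1:]
            alt_aa = translate_codon(alt)
            if alt_aa == "*":
                continue
            if (alt_aa == aa) == synonymous:
                out.append((i, b))
    return out


def evolve_pair(
    cds: str,
    target_ks: float,
    target_ratio: float,
    rng: np.random.Generator,
    protected_codons: frozenset[int] | set[int] = frozenset(),
    max_tries: int = 40,
) -> str:
    """Mutate a CDS so the pair (original, mutant) has controlled Ka/Ks.

    Substitution counts are integers, so the exact targets S*pS and
    N*pN are generally unreachable on a single short pair; the
    fractional part of each expected count is resolved by a Bernoulli
    draw (stochastic rounding), which keeps every pair within one
    substitution of its target while the mean divergence over many
    pairs equals the target exactly.  The realised divergence is
    re-measured with NG86 and the draw is rejected when it falls
    outside a quantisation-aware window of max(35% of target, 2.5
    substitutions' worth); unreachable targets raise after
    ``max_tries``.  Stop codons are never introduced, and
    codons listed in ``protected_codons`` (protein coordinates) receive
    no non-synonymous change - used to keep motif cysteines intact.
    """
    if target_ks < 0 or target_ratio < 0:
        raise LtpMinerError("targets must be non-negative")
    if target_ks > 0.5:
        raise LtpMinerError("target_ks above 0.5 would be near saturation")
    if target_ks == 0:
        return cds

    has_stop = translate_codon(cds[-3:]) == "*"
    core = cds[:-3] if has_stop else cds
    n_codons = len(core) // 3
    codons0 = [core[3 * i:3 * i + 3] for i in range(n_codons)]
    s_sites = sum(codon_sites(c)[0] for c in codons0)
    n_sites = 3.0 * n_codons - s_sites
    target_ka = target_ks * target_ratio

    tol_ks = max(0.35 * target_ks, 2.5 / s_sites)
    tol_ka = max(0.35 * target_ka, 2.5 / n_sites)

    def _expected_count(sites: float, target: float) -> float:
        return sites * 0.75 * (1.0 - math.exp(-4.0 / 3.0 * target))

    def _stochastic_round(x: float) -> int:
        lo = math.floor(x)
        return int(lo) + (1 if rng.random() < x - lo else 0)

    for _ in range(max_tries):
        codons = list(codons0)
        n_syn = _stochastic_round(_expected_count(s_sites, target_ks))
        n_non = _stochastic_round(_expected_count(n_sites, target_ka))
        placed = 0
        guard = 0
        while placed < n_syn and guard < 10_000:
            guard += 1
            i = int(rng.integers(n_codons))
            choices = _substitution_choices(codons[i], synonymous=True)
            if not choices:
                continue
            pos, base = choices[int(rng.integers(len(choices)))]
            codons[i] = codons[i][:pos] + base + codons[i][pos + 1:]
            placed += 1
        placed = 0
        while placed < n_non and guard < 10_000:
            guard += 1
            i = int(rng.integers(n_codons))
            if i in protected_codons:
                continue
            choices = _substitution_choices(codons[i], synonymous=False)
            if not choices:
                continue
            pos, base = choices[int(rng.integers(len(choices)))]
            codons[i] = codons[i][:pos] + base + codons[i][pos + 1:]
            placed += 1
        mutant = "".join(codons)
        res = ng86_kaks(CodonAlignment(seq_a=core, seq_b=mutant))
        if not math.isfinite(res.ks) or not math.isfinite(res.ka):
            continue
        if abs(res.ks - target_ks) <= tol_ks and abs(res.ka - target_ka) <= tol_ka:
            return mutant + (cds[-3:] if has_stop else "")
    raise LtpMinerError(
        f"could not reach Ks={target_ks}, Ka/Ks={target_ratio} in {max_tries} draws"
    )


# ---------------------------------------------------------------------------
# genomes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimPlan:
    """Study conditions for one synthetic dataset.

    Defaults mirror the cotton survey at desk scale: two diploid
    proteomes of 51 and 47 nsLTPs with the observed subfamily mix,
    tandem-dominated duplication, a handful of decoys per class, and
    subgenome divergence around Ks 0.018 with complementary per-type
    ortholog losses in the allotetraploid.
    """

    seed: int = 0
    type_counts_a: Mapping[str, int] = field(
        default_factory=lambda: {"I": 18, "II": 12, "IV": 6, "V": 10, "VI": 3, "VIII": 2}
    )
    type_counts_b: Mapping[str, int] = field(
        default_factory=lambda: {
            "I": 18, "II": 9, "III": 2, "IV": 5, "V": 8, "VI": 1, "VIII": 2, "IX": 2
        }
    )
    decoy_counts: Mapping[str, int] = field(
        default_factory=lambda: {k: 2 for k in DECOY_KINDS}
    )
    n_chromosomes: int = 13
    gene_spacing_bp: int = 12_000
    tandem_spacing_bp: int = 2_500
    tandem_pairs_a: int = 5
    segmental_pairs_a: int = 2
    tandem_pairs_b: int = 5
    segmental_pairs_b: int = 0
    duplicate_ks: float = 0.13
    duplicate_ratio: float = 0.45
    subgenome_ks: float = 0.018
    subgenome_ratio: float = 0.2
    loss_fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "I": 0.6667, "II": 0.5, "III": 0.5, "IV": 0.5,
            "V": 0.3333, "VI": 0.5, "VIII": 0.5, "IX": 0.5,
        }
    )

    def __post_init__(self) -> None:
        for frac in self.loss_fractions.values():
            if not 0.0 <= frac <= 1.0:
                raise LtpMinerError("loss fractions must lie in [0, 1]")
        for counts in (self.type_counts_a, self.type_counts_b, self.decoy_counts):
            if any(c < 0 for c in counts.values()):
                raise LtpMinerError("counts must be non-negative")


@dataclass
class SimGenome:
    """One synthetic species: proteins, CDSs, gene models, ground truth."""

    species: str
    proteins: list[SimProtein]
    cds: dict[str, str]
    models: dict[str, GeneModel]
    duplicate_pairs: list[tuple[str, str, str]] = field(default_factory=list)

    def protein_records(self) -> list[ProteinRecord]:
        return [p.record for p in self.proteins]

    def by_id(self) -> dict[str, SimProtein]:
        return {p.record.id: p for p in self.proteins}

    def types(self) -> dict[str, str]:
        return {
            p.record.id: p.type_label
            for p in self.proteins
            if p.type_label is not None
        }


def _motif_codon_indices(p: SimProtein) -> frozenset[int]:
    """Protein-coordinate codons that must stay intact under evolution:
    the eight motif cysteines and the CXC centre."""
    if p.spacing is None:
        return frozenset()
    s = p.spacing
    c1 = p.signal_len + s.head
    c2 = c1 + s.g12 + 1
    c3 = c2 + s.g23 + 1
    c4 = c3 + 1
    c5 = c4 + s.g45 + 1
    c6 = c5 + 2
    c7 = c6 + s.g67 + 1
    c8 = c7 + s.g78 + 1
    return frozenset({c1, c2, c3, c4, c5, c5 + 1, c6, c7, c8})


def _insert_introns(
    cds_len: int,
    p: SimProtein,
    rng: np.random.Generator,
) -> list[int]:
    """CDS positions at which to interrupt the gene with an intron.

    Subfamilies II and III are intronless; other types carry 0-2
    introns, the first preferentially 15-78 bp downstream of the end of
    the Cys8 codon (matching where cotton nsLTP introns sit)."""
    if p.type_label in ("II", "III") or p.spacing is None:
        return []
    n_introns = int(rng.choice([0, 1, 2], p=[0.3, 0.5, 0.2]))
    if n_introns == 0:
        return []
    s = p.spacing
    cys8_res = p.signal_len + s.head + s.g12 + s.g23 + s.g45 + s.g67 + s.g78 + 7
    codon_end = 3 * cys8_res + 3
    positions = []
    offset = int(rng.integers(15, 79))
    if codon_end + offset < cds_len:
        positions.append(codon_end + offset)
    else:
        positions.append(int(rng.integers(1, cds_len)))
    if n_introns == 2:
        early = int(rng.integers(1, max(codon_end - 3, 2)))
        positions.append(early)
    return sorted(set(positions))


def _build_gene_model(
    gene_id: str,
    cds: str,
    chrom: str,
    start: int,
    strand: str,
    intron_positions: Sequence[int],
    rng: np.random.Generator,
) -> GeneModel:
    """Lay the CDS on the chromosome split by introns of 80-300 bp."""
    pieces = []
    prev = 0
    for q in list(intron_positions) + [len(cds)]:
        pieces.append(cds[prev:q])
        prev = q
    if strand == "-":
        genomic_pieces = pieces[::-1]
    else:
        genomic_pieces = pieces
    exons = []
    cursor = start
    for i, piece in enumerate(genomic_pieces):
        exons.append((cursor, cursor + len(piece)))
        if i < len(genomic_pieces) - 1:
            cursor += len(piece) + int(rng.integers(80, 301))
        else:
            cursor += len(piece)
    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        start=exons[0][0],
        end=exons[-1][1],
        exons=tuple(exons),
        cds=cds,
    )


def generate_genome(
    plan: SimPlan,
    proteins: Sequence[SimProtein],
    rng: np.random.Generator,
    species: str = "Ga",
    tandem_pairs: int = 0,
    segmental_pairs: int = 0,
) -> SimGenome:
    """Place proteins on chromosomes and plant duplication events.

    Tandem copies sit adjacent to their source (within the plan's
    tandem spacing); segmental copies land on a different chromosome.
    Duplicate genes are diverged copies (``evolve_pair`` at the plan's
    duplicate Ks) so downstream alignment sees realistic paralogs.
    """
    proteins = list(proteins)
    sims: list[SimProtein] = []
    cds_map: dict[str, str] = {}
    for p in proteins:
        cds_map[p.record.id] = back_translate(p.record.seq, rng)
        sims.append(p)

    # duplicates, cloned from distinct nsLTP sources
    nsltps = [p for p in proteins if p.kind == "nsltp"]
    n_dups = tandem_pairs + segmental_pairs
    if n_dups > len(nsltps):
        raise LtpMinerError("more duplicate pairs requested than source genes")
    source_idx = rng.choice(len(nsltps), size=n_dups, replace=False)
    dup_specs: list[tuple[SimProtein, str, str]] = []  # (copy, source_id, mode)
    for k, idx in enumerate(source_idx):
        src = nsltps[int(idx)]
        mode = "tandem" if k < tandem_pairs else "segmental"
        copy_id = f"{src.record.id}d"
        evolved = evolve_pair(
            cds_map[src.record.id],
            plan.duplicate_ks,
            plan.duplicate_ratio,
            rng,
            protected_codons=_motif_codon_indices(src),
        )
        prot = "".join(
            translate_codon(evolved[3 * i:3 * i + 3]) for i in range(len(evolved) // 3 - 1)
        )
        copy = replace(
            src,
            record=ProteinRecord(id=copy_id, seq=prot, species=species),
            source_id=src.record.id,
        )
        cds_map[copy_id] = evolved
        sims.append(copy)
        dup_specs.append((copy, src.record.id, mode))

    # layout: walk the chromosomes, keeping tandem copies next to their
    # source and pushing segmental copies to another chromosome
    dup_by_source = {s: (c, m) for c, s, m in dup_specs}
    models: dict[str, GeneModel] = {}
    chroms = [f"Chr{i + 1}" for i in range(plan.n_chromosomes)]
    cursors = {c: 10_000 for c in chroms}
    order = list(proteins)
    chrom_cycle = 0
    for p in order:
        chrom = chroms[chrom_cycle % len(chroms)]
        chrom_cycle += 1
        strand = "+" if rng.random() < 0.5 else "-"
        gid = p.record.id
        intr = _insert_introns(len(cds_map[gid]), p, rng)
        models[gid] = _build_gene_model(
            gid, cds_map[gid], chrom, cursors[chrom], strand, intr, rng
        )
        cursors[chrom] = models[gid].end + plan.gene_spacing_bp
        if gid in dup_by_source:
            copy, mode = dup_by_source[gid]
            cid = copy.record.id
            intr_c = _insert_introns(len(cds_map[cid]), copy, rng)
            if mode == "tandem":
                c_chrom = chrom
                c_start = models[gid].end + plan.tandem_spacing_bp
            else:
                c_chrom = chroms[(chrom_cycle + 3) % len(chroms)]
                c_start = cursors[c_chrom]
            models[cid] = _build_gene_model(
                cid, cds_map[cid], c_chrom, c_start, strand, intr_c, rng
            )
            cursors[c_chrom] = max(
                cursors[c_chrom], models[cid].end + plan.gene_spacing_bp
            )

    return SimGenome(
        species=species,
        proteins=sims,
        cds=cds_map,
        models=models,
        duplicate_pairs=[(s, c.record.id, m) for c, s, m in dup_specs],
    )


def generate_tetraploid(
    diploid_a: SimGenome,
    diploid_b: SimGenome,
    loss_fractions: Mapping[str, float],
    rng: np.random.Generator,
    subgenome_ks: float = 0.018,
    subgenome_ratio: float = 0.2,
) -> tuple[SimGenome, SimGenome, pd.DataFrame]:
    """Merge two diploids into an allotetraploid with planted losses.

    Each diploid nsLTP gets a slightly diverged subgenome copy
    (``evolve_pair`` at the subgenome Ks target); then, per subfamily,
    a planned fraction of copies is deleted (count = fraction rounded
    to the nearest integer, genes chosen by seeded draw).  Returns the
    two subgenomes and the ground-truth ortholog map (diploid gene ->
    tetraploid gene or lost).
    """
    truth_rows = []
    subgenomes = []
    for diploid, tag in ((diploid_a, "At"), (diploid_b, "Dt")):
        sims, cds_map, models = [], {}, {}
        ns = [p for p in diploid.proteins if p.kind == "nsltp"]
        by_type: dict[str, list[SimProtein]] = {}
        for p in ns:
            by_type.setdefault(p.type_label, []).append(p)
        lost: set[str] = set()
        for type_label, members in sorted(by_type.items()):
            frac = float(loss_fractions.get(type_label, 0.0))
            n_lost = int(math.floor(frac * len(members) + 0.5))
            if n_lost:
                idx = rng.choice(len(members), size=n_lost, replace=False)
                lost |= {members[int(i)].record.id for i in idx}
        for p in ns:
            src_id = p.record.id
            if src_id in lost:
                truth_rows.append(
                    {"subgenome": tag, "diploid_gene": src_id,
                     "tetraploid_gene": None, "type": p.type_label}
                )
                continue
            new_id = f"{tag}_{src_id}"
            evolved = evolve_pair(
                diploid.cds[src_id],
                subgenome_ks,
                subgenome_ratio,
                rng,
                protected_codons=_motif_codon_indices(p),
            )
            prot = "".join(
                translate_codon(evolved[3 * i:3 * i + 3])
                for i in range(len(evolved) // 3 - 1)
            )
            copy = replace(
                p,
                record=ProteinRecord(id=new_id, seq=prot, species="Gh"),
                source_id=src_id,
            )
            cds_map[new_id] = evolved
            old = diploid.models[src_id]
            models[new_id] = GeneModel(
                gene_id=new_id,
                chrom=f"{tag}_{old.chrom}",
                strand=old.strand,
                start=old.start,
                end=old.end,
                exons=old.exons,
                cds=evolved,
            )
            sims.append(copy)
            truth_rows.append(
                {"subgenome": tag, "diploid_gene": src_id,
                 "tetraploid_gene": new_id, "type": p.type_label}
            )
        subgenomes.append(
            SimGenome(species=f"Gh_{tag}", proteins=sims, cds=cds_map, models=models)
        )
    truth = pd.DataFrame(
        truth_rows, columns=["subgenome", "diploid_gene", "tetraploid_gene", "type"]
    )
    return subgenomes[0], subgenomes[1], truth


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------

@dataclass
class SimDataset:
    plan: SimPlan
    diploid_a: SimGenome
    diploid_b: SimGenome
    tetraploid_at: SimGenome
    tetraploid_dt: SimGenome
    ortholog_truth: pd.DataFrame
    exclusion: ProteinRecord
    flags_a: FlagTable
    flags_b: FlagTable

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for genome in (self.diploid_a, self.diploid_b):
            for p in genome.proteins:
                rows.append(
                    {
                        "gene_id": p.record.id,
                        "species": genome.species,
                        "kind": p.kind,
                        "type": p.type_label,
                        "spacing": ",".join(map(str, p.spacing.astuple()))
                        if p.spacing
                        else "",
                        "cxc_residue": p.cxc_residue or "",
                        "source": p.source_id or "",
                        "expected_reasons": ";".join(
                            EXPECTED_DECOY_REASONS.get(p.kind, ())
                        ),
                    }
                )
        return pd.DataFrame(rows)


def _flags_for(genome: SimGenome) -> FlagTable:
    return FlagTable(p.flags(gpi=(p.kind == "gpi")) for p in genome.proteins)


def simulate_dataset(plan: SimPlan) -> SimDataset:
    """Generate the full study: two diploids (with decoys and planted
    duplications) and their allotetraploid with planted ortholog losses."""
    rng = np.random.default_rng(plan.seed)
    rules = load_rules()
    exclusion = make_exclusion_record(rng)

    def build_proteins(counts: Mapping[str, int], species: str) -> list[SimProtein]:
        out = []
        i = 1
        for type_label in sorted(counts):
            for _ in range(counts[type_label]):
                out.append(
                    generate_nsltp(
                        type_label, rules, rng,
                        gene_id=f"{species}LTP{i}", species=species,
                    )
                )
                i += 1
        j = 1
        for kind in DECOY_KINDS:
            for _ in range(plan.decoy_counts.get(kind, 0)):
                out.append(
                    generate_decoy(
                        kind, rng, rules,
                        gene_id=f"{species}DEC{j}", species=species,
                        exclusion=exclusion,
                    )
                )
                j += 1
        return out

    prot_a = build_proteins(plan.type_counts_a, "Ga")
    prot_b = build_proteins(plan.type_counts_b, "Gr")
    genome_a = generate_genome(
        plan, prot_a, rng, species="Ga",
        tandem_pairs=plan.tandem_pairs_a, segmental_pairs=plan.segmental_pairs_a,
    )
    genome_b = generate_genome(
        plan, prot_b, rng, species="Gr",
        tandem_pairs=plan.tandem_pairs_b, segmental_pairs=plan.segmental_pairs_b,
    )
    sub_at, sub_dt, ortho_truth = generate_tetraploid(
        genome_a, genome_b, plan.loss_fractions, rng,
        subgenome_ks=plan.subgenome_ks, subgenome_ratio=plan.subgenome_ratio,
    )
    return SimDataset(
        plan=plan,
        diploid_a=genome_a,
        diploid_b=genome_b,
        tetraploid_at=sub_at,
        tetraploid_dt=sub_dt,
        ortholog_truth=ortho_truth,
        exclusion=exclusion,
        flags_a=_flags_for(genome_a),
        flags_b=_flags_for(genome_b),
    )
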