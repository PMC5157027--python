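"""Paralog detection, tandem/segmental classification, reciprocal-best-
hit orthologs and collinear synteny blocks for a gene family.

Within-species paralog pairs come from global protein alignment
(identity and coverage thresholds).  A pair is *tandem* when both genes
sit on the same chromosome with few intervening genes or a short
physical distance, and *segmental* otherwise.  Cross-species 1:1
orthologs are reciprocal best hits (RBH) by global alignment score, with
tied best scores emitting no pair.  Synteny blocks are inclusion-maximal
chains of ortholog anchors whose gene order is strictly monotone on both
chromosomes, with bounded gene-rank gaps between consecutive anchors.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from ._align import align_stats, global_score
from .core_io import GeneModel, LtpMinerError, ProteinRecord

logger = logging.getLogger("ltpminer")


@dataclass(frozen=True)
class DuplicatePair:
    gene_a: str
    gene_b: str
    identity: float
    mode: str  # tandem | segmental
    intervening: Optional[int] = None  # annotated genes between, same chrom only
    distance_bp: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must lie in [0, 1]")
        if self.mode not in ("tandem", "segmental"):
            raise ValueError(f"bad duplication mode {self.mode!r}")


@dataclass(frozen=True)
class OrthologPair:
    gene_a: str
    gene_b: str
    identity: float
    bidirectional_best: bool = True


@dataclass(frozen=True)
class SyntenyBlock:
    chrom_a: str
    chrom_b: str
    pairs: tuple[OrthologPair, ...]
    orientation: str  # same | inverted

    def __post_init__(self) -> None:
        if len(self.pairs) < 2:
            raise ValueError("a synteny block needs at least 2 anchors")
        if self.orientation not in ("same", "inverted"):
            raise ValueError(f"bad orientation {self.orientation!r}")


def find_paralog_pairs(
    family_proteins: Sequence[ProteinRecord],
    min_identity: float = 0.7,
    min_coverage: float = 0.75,
) -> list[tuple[str, str, float]]:
    """All unordered within-species pairs passing identity/coverage.

    Coverage is the terminal-gap-trimmed aligned span over the longer
    sequence.  A gene may appear in several pairs.
    """
    pairs = []
    for a, b in itertools.combinations(family_proteins, 2):
        stats = align_stats(a.seq, b.seq, mode="global")
        longer = max(len(a.seq), len(b.seq))
        coverage = stats.aligned_columns / longer
        if stats.identity >= min_identity and coverage >= min_coverage:
            pairs.append((a.id, b.id, stats.identity))
    return pairs


def _gene_midpoint(m: GeneModel) -> float:
    return (m.start + m.end) / 2.0


def classify_duplication(
    pair: tuple[str, str, float],
    gene_models: Mapping[str, GeneModel],
    all_genes_on_chrom: Mapping[str, Sequence[str]],
    max_intervening: int = 5,
    max_distance: int = 100_000,
) -> DuplicatePair:
    """Tandem vs segmental call for one paralog pair.

    Tandem requires the same chromosome and either at most
    ``max_intervening`` annotated genes between the two, or midpoints at
    most ``max_distance`` bp apart.  ``all_genes_on_chrom`` maps a
    chromosome to its gene ids ordered by position.
    """
    gene_a, gene_b, identity = pair
    for g in (gene_a, gene_b):
        if g not in gene_models:
            raise LtpMinerError(f"no gene model for {g}")
    ma, mb = gene_models[gene_a], gene_models[gene_b]
    if ma.chrom != mb.chrom:
        return DuplicatePair(gene_a=gene_a, gene_b=gene_b, identity=identity, mode="segmental")
    order = list(all_genes_on_chrom.get(ma.chrom, ()))
    try:
        ia, ib = order.index(gene_a), order.index(gene_b)
        intervening = abs(ia - ib) - 1
    except ValueError:
        intervening = None
    distance = int(abs(_gene_midpoint(ma) - _gene_midpoint(mb)))
    tandem = (intervening is not None and intervening <= max_intervening) or (
        distance <= max_distance
    )
    return DuplicatePair(
        gene_a=gene_a,
        gene_b=gene_b,
        identity=identity,
        mode="tandem" if tandem else "segmental",
        intervening=intervening,
        distance_bp=distance,
    )


def rbh_orthologs(
    proteins_a: Sequence[ProteinRecord],
    proteins_b: Sequence[ProteinRecord],
) -> list[OrthologPair]:
    """Reciprocal unique-best-hit ortholog pairs by global alignment score."""
    if not proteins_a or not proteins_b:
        raise LtpMinerError("both protein sets must be non-empty")
    scores: dict[tuple[str, str], float] = {}
    for a in proteins_a:
        for b in proteins_b:
            scores[(a.id, b.id)] = global_score(a.seq, b.seq)

    def unique_best(query_id: str, subjects: Sequence[ProteinRecord], forward: bool):
        best_ids, best_score = [], None
        for s in subjects:
            sc = scores[(query_id, s.id)] if forward else scores[(s.id, query_id)]
            if best_score is None or sc > best_score:
                best_ids, best_score = [s.id], sc
            elif sc == best_score:
                best_ids.append(s.id)
        if len(best_ids) > 1:
            logger.warning("tied best hits for %s; no RBH pair emitted", query_id)
            return None
        return best_ids[0]

    best_in_b = {a.id: unique_best(a.id, proteins_b, True) for a in proteins_a}
    best_in_a = {b.id: unique_best(b.id, proteins_a, False) for b in proteins_b}
    seqs_a = {p.id: p.seq for p in proteins_a}
    seqs_b = {p.id: p.seq for p in proteins_b}
    pairs = []
    for a in proteins_a:
        b_id = best_in_b[a.id]
        if b_id is not None and best_in_a.get(b_id) == a.id:
            identity = align_stats(seqs_a[a.id], seqs_b[b_id], mode="global").identity
            pairs.append(OrthologPair(gene_a=a.id, gene_b=b_id, identity=identity))
    return pairs


def _chrom_ranks(models: Mapping[str, GeneModel]) -> dict[str, tuple[str, int]]:
    """gene_id -> (chrom, rank of the gene on that chromosome by start)."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in models.values():
        by_chrom.setdefault(m.chrom, []).append(m)
    ranks = {}
    for chrom, genes in by_chrom.items():
        for rank, m in enumerate(sorted(genes, key=lambda g: (g.start, g.gene_id))):
            ranks[m.gene_id] = (chrom, rank)
    return ranks


def _maximal_chains(anchors: list[tuple[int, int, int]], max_gap: int) -> list[tuple[int, ...]]:
    """Inclusion-maximal monotone chains over (rank_a, rank_b, index).

    An edge joins two anchors when rank_a strictly increases, rank_b
    moves strictly in the chain's direction, and the rank gaps on both
    sides are at most ``max_gap``.  All chains are enumerated by DFS and
    filtered to those whose anchor set is not contained in another's.
    """
    chains: list[tuple[int, ...]] = []
    n = len(anchors)

    def ok(i: int, j: int, direction: int) -> bool:
        ra_i, rb_i, _ = anchors[i]
        ra_j, rb_j, _ = anchors[j]
        if ra_j <= ra_i:
            return False
        if direction * (rb_j - rb_i) <= 0:
            return False
        return ra_j - ra_i <= max_gap and abs(rb_j - rb_i) <= max_gap

    def extend(path: list[int], direction: int) -> None:
        extended = False
        for j in range(n):
            if j in path:
                continue
            if ok(path[-1], j, direction):
                extend(path + [j], direction)
                extended = True
        if not extended:
            chains.append(tuple(path))

    for direction in (1, -1):
        for i in range(n):
            extend([i], direction)

    sets = [frozenset(c) for c in chains]
    maximal = []
    seen = set()
    for idx, c in enumerate(chains):
        s = sets[idx]
        if s in seen:
            continue
        if any(s < other for other in sets):
            continue
        seen.add(s)
        maximal.append(c)
    return maximal


def chain_synteny(
    ortholog_pairs: Sequence[OrthologPair],
    gene_models_a: Mapping[str, GeneModel],
    gene_models_b: Mapping[str, GeneModel],
    min_block: int = 2,
    max_gap_genes: int = 10,
) -> list[SyntenyBlock]:
    """Chain ortholog anchors into collinear synteny blocks.

    Per chromosome pair, anchors are sorted by position on the first
    genome and maximal runs strictly monotone on the second genome are
    extracted, requiring consecutive anchors to be separated by at most
    ``max_gap_genes`` gene ranks on both sides.
    """
    ranks_a = _chrom_ranks(gene_models_a)
    ranks_b = _chrom_ranks(gene_models_b)
    grouped: dict[tuple[str, str], list[tuple[int, int, OrthologPair]]] = {}
    for pair in ortholog_pairs:
        if pair.gene_a not in ranks_a or pair.gene_b not in ranks_b:
            raise LtpMinerError(f"no gene model for anchor {pair.gene_a}/{pair.gene_b}")
        chrom_a, ra = ranks_a[pair.gene_a]
        chrom_b, rb = ranks_b[pair.gene_b]
        grouped.setdefault((chrom_a, chrom_b), []).append((ra, rb, pair))

    blocks = []
    for (chrom_a, chrom_b), anchors in sorted(grouped.items()):
        anchors.sort(key=lambda t: (t[0], t[1]))
        triples = [(ra, rb, i) for i, (ra, rb, _) in enumerate(anchors)]
        for chain in _maximal_chains(triples, max_gap_genes):
            if len(chain) < min_block:
                continue
            chain_pairs = tuple(anchors[triples[i][2]][2] for i in chain)
            rb_seq = [triples[i][1] for i in chain]
            orientation = "same" if rb_seq[1] > rb_seq[0] else "inverted"
            blocks.append(
                SyntenyBlock(
                    chrom_a=chrom_a,
                    chrom_b=chrom_b,
                    pairs=chain_pairs,
                    orientation=orientation,
                )
            )
    return blocks


def loss_retention_table(
    orthologs: Sequence[OrthologPair],
    family_types_a: Mapping[str, str],
    family_types_b: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-subfamily counts of genes with vs without an ortholog.

    ``family_types_a`` maps every gene of the focal species to its
    subfamily label; genes of that species appearing in ``orthologs``
    (as ``gene_a``) count as retained, the rest as lost.
    """
    paired = {p.gene_a for p in orthologs}
    rows: dict[str, dict[str, int]] = {}
    for gene, type_label in family_types_a.items():
        row = rows.setdefault(type_label, {"paired": 0, "unpaired": 0})
        row["paired" if gene in paired else "unpaired"] += 1
    out = []
    for type_label in sorted(rows):
        r = rows[type_label]
        total = r["paired"] + r["unpaired"]
        out.append(
            {
                "type": type_label,
                "paired": r["paired"],
                "unpaired": r["unpaired"],
                "percent_lost": round(100.0 * r["unpaired"] / total, 2),
            }
        )
    return pd.DataFrame(out, columns=["type", "paired", "unpaired", "percent_lost"])
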