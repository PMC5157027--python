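import numpy as np
import pytest

from _oracles import maximal_monotone_chains
from ltpminer.core_io import GeneModel, LtpMinerError, ProteinRecord
from ltpminer.duplication_synteny import (
    OrthologPair,
    chain_synteny,
    classify_duplication,
    find_paralog_pairs,
    loss_retention_table,
    rbh_orthologs,
)

AA = list("ACDEFGHIKLMNPQRSTVWY")


def _random_protein(rng, gene_id, length=100):
    return ProteinRecord(id=gene_id, seq="".join(rng.choice(AA, size=length)))


def _model(gene_id, chrom, start, length=300):
    return GeneModel(
        gene_id=gene_id, chrom=chrom, strand="+", start=start, end=start + length,
        exons=((start, start + length),), cds="ATG",
    )


class TestParalogs:
    def test_identical_sequences_pair_at_identity_one(self, rng):
        a = _random_protein(rng, "a")
        b = ProteinRecord(id="b", seq=a.seq)
        (pair,) = find_paralog_pairs([a, b])
        assert pair[2] == 1.0

    def test_unrelated_random_pairs_never_pass_defaults(self, rng):
        hits = 0
        for i in range(100):
            a = _random_protein(rng, "a")
            b = _random_protein(rng, "b")
            hits += len(find_paralog_pairs([a, b]))
        assert hits == 0

    def test_tandem_cluster_of_three_yields_three_pairs(self, dataset, rng):
        base = next(
            p for p in dataset.diploid_a.proteins if p.kind == "nsltp"
        ).record
        # three near-identical copies: every unordered pair passes
        seqs = [base.seq]
        for k in range(2):
            s = list(base.seq)
            for i in rng.choice(len(s), size=5, replace=False):
                s[int(i)] = str(rng.choice([a for a in AA if a != s[int(i)]]))
            seqs.append("".join(s))
        prots = [ProteinRecord(id=f"t{i}", seq=s) for i, s in enumerate(seqs)]
        assert len(find_paralog_pairs(prots)) == 3


class TestClassifyDuplication:
    MODELS = {
        "a": _model("a", "Chr1", 1_000),
        "b": _model("b", "Chr1", 2_000),
        "c": _model("c", "Chr5", 1_000),
        "d": _model("d", "Chr1", 5_000_000),
    }
    ORDER = {"Chr1": ["a", "b", "d"], "Chr5": ["c"]}

    def test_adjacent_same_chromosome_is_tandem(self):
        dp = classify_duplication(("a", "b", 0.9), self.MODELS, self.ORDER)
        assert dp.mode == "tandem" and dp.intervening == 0

    def test_different_chromosomes_is_segmental(self):
        dp = classify_duplication(("a", "c", 0.9), self.MODELS, self.ORDER)
        assert dp.mode == "segmental"

    def test_far_apart_same_chromosome_is_segmental(self):
        models = dict(self.MODELS)
        order = {"Chr1": ["a", "b"] + [f"x{i}" for i in range(40)] + ["d"]}
        dp = classify_duplication(("a", "d", 0.9), models, order)
        assert dp.mode == "segmental"

    def test_symmetric_in_pair_order(self):
        d1 = classify_duplication(("a", "b", 0.9), self.MODELS, self.ORDER)
        d2 = classify_duplication(("b", "a", 0.9), self.MODELS, self.ORDER)
        assert d1.mode == d2.mode and d1.distance_bp == d2.distance_bp

    def test_missing_model_names_the_gene(self):
        with pytest.raises(LtpMinerError, match="zz"):
            classify_duplication(("a", "zz", 0.9), self.MODELS, self.ORDER)

    def test_planted_duplications_recovered(self, dataset):
        genome = dataset.diploid_a
        order: dict[str, list[str]] = {}
        for m in sorted(genome.models.values(), key=lambda g: (g.chrom, g.start)):
            order.setdefault(m.chrom, []).append(m.gene_id)
        for a, b, mode in genome.duplicate_pairs:
            dp = classify_duplication((a, b, 1.0), genome.models, order)
            assert dp.mode == mode, (a, b)


class TestRbh:
    def test_identity_case_pairs_everything(self, rng):
        prots = [_random_protein(rng, f"g{i}") for i in range(5)]
        mirror = [ProteinRecord(id=f"m{i}", seq=p.seq) for i, p in enumerate(prots)]
        pairs = rbh_orthologs(prots, mirror)
        assert {(p.gene_a, p.gene_b) for p in pairs} == {
            (f"g{i}", f"m{i}") for i in range(5)
        }

    def test_tied_best_hits_emit_no_pair(self, rng):
        a = _random_protein(rng, "a")
        twin1 = ProteinRecord(id="t1", seq=a.seq)
        twin2 = ProteinRecord(id="t2", seq=a.seq)
        pairs = rbh_orthologs([a], [twin1, twin2])
        assert pairs == []

    def test_symmetry_under_role_swap(self, dataset):
        ns_a = [p.record for p in dataset.diploid_a.proteins if p.kind == "nsltp"][:15]
        ns_t = dataset.tetraploid_at.protein_records()[:15]
        fwd = {(p.gene_a, p.gene_b) for p in rbh_orthologs(ns_a, ns_t)}
        rev = {(p.gene_b, p.gene_a) for p in rbh_orthologs(ns_t, ns_a)}
        assert fwd == rev

    def test_planted_losses_recovered(self, dataset):
        truth = dataset.ortholog_truth
        for tag, dip, tet in (
            ("At", dataset.diploid_a, dataset.tetraploid_at),
            ("Dt", dataset.diploid_b, dataset.tetraploid_dt),
        ):
            sub = truth[truth.subgenome == tag]
            expected = {
                (r.diploid_gene, r.tetraploid_gene)
                for r in sub.itertuples()
                if r.tetraploid_gene is not None
            }
            pairs = rbh_orthologs(
                [p.record for p in dip.proteins if p.kind == "nsltp"],
                tet.protein_records(),
            )
            assert {(p.gene_a, p.gene_b) for p in pairs} == expected


class TestSynteny:
    @staticmethod
    def _setup(anchors):
        """anchors: list of (rank_a, rank_b); build models + pairs."""
        models_a, models_b, pairs = {}, {}, []
        n = max(max(a for a, _ in anchors), max(b for _, b in anchors)) + 1
        for r in range(n):
            models_a[f"a{r}"] = _model(f"a{r}", "A1", 1000 * (r + 1))
            models_b[f"b{r}"] = _model(f"b{r}", "B1", 1000 * (r + 1))
        for ra, rb in anchors:
            pairs.append(OrthologPair(gene_a=f"a{ra}", gene_b=f"b{rb}", identity=1.0))
        return pairs, models_a, models_b

    def test_collinear_anchors_form_one_same_orientation_block(self):
        pairs, ma, mb = self._setup([(0, 0), (1, 1), (2, 2)])
        (block,) = chain_synteny(pairs, ma, mb)
        assert len(block.pairs) == 3 and block.orientation == "same"

    def test_reversed_anchors_form_inverted_block(self):
        pairs, ma, mb = self._setup([(0, 2), (1, 1), (2, 0)])
        (block,) = chain_synteny(pairs, ma, mb)
        assert block.orientation == "inverted"

    def test_large_gap_splits_chains(self):
        # middle anchor jumps far away on B: with a small gap limit the
        # only 2-anchor chain skips it
        pairs, ma, mb = self._setup([(0, 0), (1, 20), (2, 1)])
        blocks = chain_synteny(pairs, ma, mb, max_gap_genes=3)
        assert len(blocks) == 1
        assert {p.gene_a for p in blocks[0].pairs} == {"a0", "a2"}

    def test_blocks_strictly_monotone_on_both_sides(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 9))
            anchors = list(zip(range(n), (int(x) for x in rng.permutation(n))))
            pairs, ma, mb = self._setup(anchors)
            for block in chain_synteny(pairs, ma, mb, max_gap_genes=4):
                ras = [int(p.gene_a[1:]) for p in block.pairs]
                rbs = [int(p.gene_b[1:]) for p in block.pairs]
                assert ras == sorted(ras)
                assert rbs == sorted(rbs) or rbs == sorted(rbs, reverse=True)

    @pytest.mark.parametrize("max_gap", [2, 3, 10])
    def test_chaining_equals_subset_oracle(self, max_gap):
        rng = np.random.default_rng(max_gap)
        for _ in range(25):
            n = int(rng.integers(3, 10))
            anchors = sorted(
                zip(
                    (int(x) for x in rng.permutation(2 * n)[:n]),
                    (int(x) for x in rng.permutation(2 * n)[:n]),
                )
            )
            pairs, ma, mb = self._setup(anchors)
            blocks = chain_synteny(pairs, ma, mb, max_gap_genes=max_gap)
            got = {
                frozenset(
                    anchors.index((int(p.gene_a[1:]), int(p.gene_b[1:])))
                    for p in b.pairs
                )
                for b in blocks
            }
            expected = maximal_monotone_chains(anchors, max_gap, min_block=2)
            assert got == expected, anchors


class TestLossRetention:
    def test_two_of_six_paired_is_66_percent_lost(self):
        types = {f"g{i}": "I" for i in range(6)}
        orthologs = [
            OrthologPair(gene_a="g0", gene_b="x0", identity=1.0),
            OrthologPair(gene_a="g1", gene_b="x1", identity=1.0),
        ]
        table = loss_retention_table(orthologs, types)
        assert float(table[table.type == "I"].percent_lost.iloc[0]) == 66.67

    def test_everything_paired_means_zero_loss(self):
        types = {"g0": "I", "g1": "V"}
        orthologs = [
            OrthologPair(gene_a="g0", gene_b="x0", identity=1.0),
            OrthologPair(gene_a="g1", gene_b="x1", identity=1.0),
        ]
        table = loss_retention_table(orthologs, types)
        assert set(table.percent_lost) == {0.0}

    def test_planted_loss_pattern_recovered(self, dataset):
        truth = dataset.ortholog_truth
        sub = truth[truth.subgenome == "At"]
        types = dict(zip(sub.diploid_gene, sub.type))
        orthologs = [
            OrthologPair(gene_a=r.diploid_gene, gene_b=r.tetraploid_gene, identity=1.0)
            for r in sub.itertuples()
            if r.tetraploid_gene is not None
        ]
        table = loss_retention_table(orthologs, types)
        for row in table.itertuples():
            planted_lost = len(
                sub[(sub.type == row.type) & (sub.tetraploid_gene.isna())]
            )
            assert row.unpaired == planted_lost
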