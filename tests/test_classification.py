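import itertools

import pytest

from ltpminer.classification import (
    CORE_GAPS,
    HYDROPHILIC_CXC,
    HYDROPHOBIC_CXC,
    CxcClass,
    classify_type,
    cxc_center_class,
    cxc_frequency,
    summarize_family,
    TypeAssignment,
)
from ltpminer.motif8cm import GAP_NAMES, SpacingVector, scan_8cm
from ltpminer.synthetic_data import generate_nsltp

# Frozen transcription of the subfamily spacing table; any drift in the
# shipped YAML rules fails here.
EXPECTED_RULES = {
    "I": {
        "head": {2, 3, 4, 5, 7, 9},
        "g12": {9},
        "g23": {13, 14, 15, 16},
        "g45": {19, 20},
        "g67": {19, 21, 22, 23, 24},
        "g78": {13, 14, 15},
        "tail": {2, 3, 4, 5, 7, 8, 10, 19, 20, 21, 23, 25},
    },
    "II": {
        "head": {2, 5, 6, 8, 9, 10, 11, 13, 14},
        "g12": {7, 8},
        "g23": {12, 13, 14},
        "g45": {8},
        "g67": {23},
        "g78": {6, 7, 9},
        "tail": {0},
    },
    "III": {
        "head": {2, 8}, "g12": {9}, "g23": {16}, "g45": {9},
        "g67": {12}, "g78": {6}, "tail": {1, 2, 4},
    },
    "IV": {
        "head": {3, 6}, "g12": {9}, "g23": {15, 17}, "g45": {9},
        "g67": {22, 24}, "g78": {7, 9}, "tail": {0, 2, 7, 11, 12},
    },
    "V": {
        "head": {3, 7}, "g12": {14}, "g23": {14}, "g45": {11, 12},
        "g67": {24}, "g78": {10},
        "tail": {3, 4, 6, 7, 12, 14, 17, 19, 23},
    },
    "VI": {
        "head": {1, 5, 6, 9}, "g12": {10}, "g23": {12, 16}, "g45": {9},
        "g67": {22}, "g78": {9}, "tail": {6, 8, 9, 10, 11},
    },
    "VIII": {
        "head": {3, 4, 8}, "g12": {6}, "g23": {14}, "g45": {12},
        "g67": {25, 27}, "g78": {8},
        "tail": {6, 13, 16, 20, 21, 24, 37},
    },
    "IX": {
        "head": {2}, "g12": {13}, "g23": {15}, "g45": {9},
        "g67": {22}, "g78": {6}, "tail": {4},
    },
}

EXPECTED_MEMBERS = {
    "I": 63, "II": 44, "III": 4, "IV": 22, "V": 32, "VI": 7, "VIII": 11, "IX": 3,
}


def test_shipped_rules_match_frozen_table(rules):
    assert {r.label for r in rules} == set(EXPECTED_RULES)
    for r in rules:
        for gap in GAP_NAMES:
            assert set(r.allowed[gap]) == EXPECTED_RULES[r.label][gap], (r.label, gap)
        assert r.members == EXPECTED_MEMBERS[r.label]


class TestClassifyType:
    @pytest.mark.parametrize(
        "spacing,label",
        [
            (SpacingVector(3, 9, 14, 19, 21, 13, 7), "I"),
            (SpacingVector(3, 14, 14, 11, 24, 10, 6), "V"),
            (SpacingVector(2, 9, 16, 9, 12, 6, 1), "III"),
            (SpacingVector(2, 13, 15, 9, 22, 6, 4), "IX"),
        ],
    )
    def test_exact_table_rows_classify(self, rules, spacing, label):
        a = classify_type(spacing, rules)
        assert a.label == label and a.exact

    def test_degenerate_spacing_is_unclassified(self, rules):
        a = classify_type(SpacingVector(0, 0, 0, 0, 0, 0, 0), rules)
        assert not a.classified

    def test_three_of_five_core_gaps_is_not_enough(self, rules):
        # Type IX core with two gaps perturbed out of every set
        a = classify_type(SpacingVector(2, 13, 15, 10, 20, 6, 4), rules)
        assert not a.classified
        assert a.score == 3

    def test_near_miss_reports_best_label_without_claiming_it(self, rules):
        a = classify_type(SpacingVector(2, 13, 15, 9, 22, 7, 4), rules)
        assert a.label == "IX" and not a.exact

    def test_round_trip_on_planted_types(self, rules, rng):
        labels = [r.label for r in rules]
        for i in range(800):
            label = labels[i % len(labels)]
            p = generate_nsltp(label, rules, rng)
            assert classify_type(p.spacing, rules).label == label

    def test_rule_rows_pairwise_separable_on_core_gaps(self, rules):
        # every fully rule-conformant core spacing must classify to its
        # own type: no other type may reach a tying score
        for r in rules:
            combos = itertools.product(*(sorted(r.allowed[g]) for g in CORE_GAPS))
            for core in combos:
                spacing = SpacingVector(
                    head=min(r.allowed["head"]),
                    g12=core[0], g23=core[1], g45=core[2],
                    g67=core[3], g78=core[4],
                    tail=min(r.allowed["tail"]),
                )
                assert classify_type(spacing, rules).label == r.label, (r.label, core)


class TestCxc:
    def _match_for(self, seq):
        (m,) = scan_8cm(seq)
        return m

    @pytest.mark.parametrize("x,klass", [("L", "hydrophobic"), ("R", "hydrophilic"), ("A", "other")])
    def test_center_residue_classes(self, x, klass):
        seq = (
            "AA" + "C" + "A" * 9 + "C" + "A" * 16 + "CC" + "A" * 9
            + "C" + x + "C" + "A" * 12 + "C" + "A" * 6 + "C" + "A"
        )
        m = self._match_for(seq)
        c = cxc_center_class(m, seq)
        assert c.residue == x and c.klass == klass

    def test_sets_are_disjoint(self):
        assert not HYDROPHILIC_CXC & HYDROPHOBIC_CXC

    def test_frequency_within_class(self):
        classes = [CxcClass("L", "hydrophobic")] * 3 + [CxcClass("V", "hydrophobic")]
        table = cxc_frequency(classes)
        row = table[table.residue == "L"].iloc[0]
        assert row["percent"] == 75.0

    def test_single_class_is_100_percent(self):
        table = cxc_frequency([CxcClass("R", "hydrophilic")] * 4)
        assert list(table["percent"]) == [100.0]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cxc_frequency([])

    def test_planted_cxc_frequencies_recovered(self, dataset):
        from collections import Counter

        planted = Counter(
            p.cxc_residue
            for p in dataset.diploid_a.proteins
            if p.kind == "nsltp" and p.cxc_residue
        )
        matches = {}
        classes = []
        for p in dataset.diploid_a.proteins:
            if p.kind != "nsltp" or not p.cxc_residue:
                continue
            for m in scan_8cm(p.mature):
                if m.spacing == p.spacing:
                    classes.append(cxc_center_class(m, p.mature))
                    break
        recovered = Counter(c.residue for c in classes)
        assert recovered == planted


class TestSummarize:
    @staticmethod
    def _assignments(counts):
        out = []
        for label, n in counts.items():
            out.extend([TypeAssignment(label=label, score=5, exact=True)] * n)
        return out

    def test_type_i_share_of_189(self):
        table = summarize_family(self._assignments({"I": 63}), total=189)
        assert float(table[table.type == "I"].percent.iloc[0]) == 33.33

    def test_type_ix_share_of_189(self):
        table = summarize_family(self._assignments({"IX": 3}), total=189)
        assert float(table[table.type == "IX"].percent.iloc[0]) == 1.59

    def test_empty_counts_give_zero_table(self):
        table = summarize_family([], total=10)
        assert set(table["count"]) == {0}
        assert "UNCLASSIFIED" in set(table["type"])

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            summarize_family([], total=0)
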