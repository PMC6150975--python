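import numpy as np
import pytest

from enzyclass.datasets import (
    build_negative_pool,
    pairwise_identity,
    propagate_annotations,
    reduce_redundancy,
    sample_balanced_negatives,
    select_nonenzymes,
    select_trainable_classes,
    split_train_validation,
)
from enzyclass.ec import parse_ec
from enzyclass.records import ProteinRecord

from conftest import random_protein


def make_enzyme(pid, ec_strings, seq="ACDEFGHIKL", score=5):
    return ProteinRecord(
        pid, seq, {parse_ec(s) for s in ec_strings}, score, bool(ec_strings)
    )


class TestPropagation:
    def test_leaf_listed_under_all_ancestors(self):
        cmap = propagate_annotations([make_enzyme("p", ["1.1.2.4"])])
        assert {str(ec) for ec in cmap} == {"1.1.2.4", "1.1.2.-", "1.1.-.-", "1.-.-.-"}
        assert all(members == {"p"} for members in cmap.values())

    def test_main_class_only(self):
        cmap = propagate_annotations([make_enzyme("p", ["2.-.-.-"])])
        assert {str(ec) for ec in cmap} == {"2.-.-.-"}

    def test_multi_ec_discarded(self):
        cmap = propagate_annotations([make_enzyme("p", ["1.1.2.4", "3.1.3.16"])])
        assert cmap == {}

    def test_monotone_parent_counts(self, rng):
        records = []
        for i in range(60):
            ec = f"{rng.integers(1, 4)}.{rng.integers(1, 3)}.{rng.integers(1, 3)}.{rng.integers(1, 4)}"
            records.append(make_enzyme(f"p{i}", [ec]))
        cmap = propagate_annotations(records)
        for ec, members in cmap.items():
            parent = ec.parent()
            if parent is not None:
                assert len(cmap[parent]) >= len(members)


class TestEligibility:
    def test_boundary(self):
        cmap = {
            parse_ec("1.-.-.-"): {f"p{i}" for i in range(50)},
            parse_ec("2.-.-.-"): {f"q{i}" for i in range(49)},
        }
        chosen = select_trainable_classes(cmap, min_count=50)
        assert [str(ec) for ec in chosen] == ["1.-.-.-"]

    def test_empty(self):
        assert select_trainable_classes({}) == []

    def test_sorted_by_level_then_components(self):
        cmap = {
            parse_ec(s): {f"{s}_{i}" for i in range(60)}
            for s in ["2.1.-.-", "1.-.-.-", "1.2.-.-", "2.-.-.-"]
        }
        assert [str(e) for e in select_trainable_classes(cmap)] == [
            "1.-.-.-", "2.-.-.-", "1.2.-.-", "2.1.-.-",
        ]


class TestNonEnzymes:
    def test_annotation_score_filter(self):
        records = [
            ProteinRecord("hi5", "ACDEF", set(), 5, False),
            ProteinRecord("hi4", "ACDEF", set(), 4, False),
            ProteinRecord("lo2", "ACDEF", set(), 2, False),
            ProteinRecord("noscore", "ACDEF", set(), None, False),
            make_enzyme("enz5", ["1.1.1.1"], score=5),
        ]
        assert select_nonenzymes(records) == ["hi5", "hi4"]


class TestNegativePool:
    @pytest.fixture()
    def class_map(self):
        records = [
            make_enzyme("own_leaf", ["1.1.1.2"]),
            make_enzyme("own_sub", ["1.1.2.4"]),
            make_enzyme("sib_child", ["1.2.1.3"]),
            make_enzyme("sib", ["1.3.1.1"]),
            make_enzyme("other", ["2.3.1.1"]),
            make_enzyme("other2", ["3.1.3.16"]),
        ]
        return propagate_annotations(records)

    def test_partition_assignment(self, class_map):
        pool = build_negative_pool(parse_ec("1.1.-.-"), class_map, ["ne1", "ne2"])
        assert set(pool["sibling_branch"]) == {"sib_child", "sib"}
        assert set(pool["other_main"]) == {"other", "other2"}
        assert pool["nonenzyme"] == ["ne1", "ne2"]

    def test_own_descendants_in_no_partition(self, class_map):
        pool = build_negative_pool(parse_ec("1.1.-.-"), class_map, [])
        all_negatives = {pid for ids in pool.values() for pid in ids}
        assert not {"own_leaf", "own_sub"} & all_negatives

    def test_partitions_disjoint(self, class_map):
        pool = build_negative_pool(parse_ec("1.1.-.-"), class_map, ["ne1"])
        ids = [pid for ids in pool.values() for pid in ids]
        assert len(ids) == len(set(ids))


class TestBalancedSampling:
    def test_table_balanced_counts(self):
        # an oxidoreductase-sized positive set: half enzymes, half non-enzymes
        pool = {
            "sibling_branch": [],
            "other_main": [f"e{i}" for i in range(20000)],
            "nonenzyme": [f"n{i}" for i in range(20000)],
        }
        chosen = sample_balanced_negatives(pool, 7417, seed=1)
        assert len(chosen) == 7417
        n_enz = sum(c.startswith("e") for c in chosen)
        n_non = sum(c.startswith("n") for c in chosen)
        assert {n_enz, n_non} == {3709, 3708}

    def test_pure_enzyme_mix(self):
        pool = {"sibling_branch": [], "other_main": [f"e{i}" for i in range(30)],
                "nonenzyme": [f"n{i}" for i in range(30)]}
        chosen = sample_balanced_negatives(pool, 10, mix=(0.0, 1.0, 0.0), seed=0)
        assert len(chosen) == 10 and all(c.startswith("e") for c in chosen)

    def test_deterministic_under_seed(self):
        pool = {"sibling_branch": [f"s{i}" for i in range(40)],
                "other_main": [f"e{i}" for i in range(40)],
                "nonenzyme": [f"n{i}" for i in range(40)]}
        a = sample_balanced_negatives(pool, 30, mix=(0.5, 0.25, 0.25), seed=9)
        b = sample_balanced_negatives(pool, 30, mix=(0.5, 0.25, 0.25), seed=9)
        assert a == b

    def test_exhausted_partition_refilled_with_warning(self):
        pool = {"sibling_branch": ["s1"], "other_main": [f"e{i}" for i in range(20)],
                "nonenzyme": [f"n{i}" for i in range(20)]}
        with pytest.warns(UserWarning, match="exhausted"):
            chosen = sample_balanced_negatives(pool, 12, mix=(0.5, 0.25, 0.25), seed=0)
        assert len(chosen) == 12

    def test_pool_too_small_errors(self):
        with pytest.raises(ValueError, match="smaller"):
            sample_balanced_negatives(
                {"sibling_branch": [], "other_main": ["e1"], "nonenzyme": []}, 5
            )


class TestRedundancy:
    def test_identical_sequences_cluster(self):
        recs = [ProteinRecord("a", "ACDEFGHIKLMNPQRSTVWY"),
                ProteinRecord("b", "ACDEFGHIKLMNPQRSTVWY")]
        clustering = reduce_redundancy(recs)
        assert len(clustering.clusters) == 1
        assert sorted(clustering.clusters[0][1]) == ["a", "b"]

    def test_dissimilar_sequences_split(self):
        recs = [ProteinRecord("a", "ACDEFGHIKLACDEFGHIKL"),
                ProteinRecord("b", "WYWYWYWYWYWYWYWYWYWY")]
        assert len(reduce_redundancy(recs).clusters) == 2

    def test_transitive_grouping_matches_pairwise_oracle(self):
        # A~B 60% identity, A~C and B~C low: expect {A, B}, {C}
        a = "AAAAACCCCCDDDDDEEEEE"
        b = "AAAAACCCCCDD" + "WWWWWWWW"     # 12/20 identical to A
        c = "GGGGGGGGGGGGGGGGGGGG"
        assert pairwise_identity(a, b) == pytest.approx(0.6)
        assert pairwise_identity(a, c) < 0.5 and pairwise_identity(b, c) < 0.5
        clustering = reduce_redundancy(
            [ProteinRecord("A", a), ProteinRecord("B", b), ProteinRecord("C", c)]
        )
        groups = sorted(sorted(m) for _, m in clustering.clusters)
        assert groups == [["A", "B"], ["C"]]

    def test_every_id_in_exactly_one_cluster(self, rng):
        recs = [ProteinRecord(f"p{i}", random_protein(rng, 40)) for i in range(15)]
        clustering = reduce_redundancy(recs)
        ids = clustering.member_ids()
        assert sorted(ids) == sorted(r.id for r in recs)


class TestSplit:
    def _clustering(self, n):
        recs = [ProteinRecord(f"p{i}", random_protein(np.random.default_rng(i), 40))
                for i in range(n)]
        return reduce_redundancy(recs)

    def test_ten_clusters_one_to_validation(self):
        clustering = self._clustering(10)
        assert len(clustering.clusters) == 10
        train, val = split_train_validation(clustering, val_fraction=0.1, seed=3)
        assert len(val) == 1 and len(train) == 9

    def test_deterministic(self):
        clustering = self._clustering(8)
        assert split_train_validation(clustering, seed=5) == split_train_validation(
            clustering, seed=5
        )

    def test_single_cluster_warns(self):
        recs = [ProteinRecord("a", "ACDEFGHIKLMNPQRSTVWY"),
                ProteinRecord("b", "ACDEFGHIKLMNPQRSTVWY")]
        clustering = reduce_redundancy(recs)
        with pytest.warns(UserWarning, match="single cluster"):
            train, val = split_train_validation(clustering)
        assert val == []

    def test_no_near_duplicates_across_split(self):
        rng = np.random.default_rng(0)
        base = random_protein(rng, 60)
        recs = [ProteinRecord("orig", base), ProteinRecord("dup", base[:-1] + "A")]
        recs += [ProteinRecord(f"r{i}", random_protein(rng, 60)) for i in range(8)]
        clustering = reduce_redundancy(recs)
        train, val = split_train_validation(
            clustering, val_fraction=0.3, seed=1, representatives_only=False
        )
        assert ("orig" in train) == ("dup" in train)  # whole-cluster atomicity
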