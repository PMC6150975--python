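import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enzyclass.records import ProteinRecord
from enzyclass.spmap import (
    ProfileMap,
    SubsequenceCluster,
    build_profiles,
    cluster_subsequences,
    extract_subsequences,
    featurize,
    fit_profile_map,
    subsequence_log_prob,
    subsequence_similarity,
)

from conftest import AAS

windows5 = st.text(alphabet=AAS, min_size=5, max_size=5)


def blosum62_lookup(a, b):
    from Bio.Align import substitution_matrices

    return substitution_matrices.load("BLOSUM62")[a][b]


class TestExtraction:
    @pytest.mark.parametrize(
        "seq, l, expected",
        [
            ("ACDEF", 5, ["ACDEF"]),
            ("ACDEFG", 5, ["ACDEF", "CDEFG"]),
            ("ACD", 5, []),
            ("ACXEFG", 3, ["EFG"]),  # X-containing windows skipped
        ],
    )
    def test_sliding_windows(self, seq, l, expected):
        assert extract_subsequences(seq, l) == expected

    def test_invalid_length(self):
        with pytest.raises(ValueError):
            extract_subsequences("ACDEF", 0)


class TestWindowSimilarity:
    def test_hand_scores(self):
        assert subsequence_similarity("AAAAA", "AAAAA") == 20  # 5 x B62(A,A)=4
        assert subsequence_similarity("AAAAA", "WWWWW") == -15  # 5 x B62(A,W)=-3

    @given(windows5, windows5)
    @settings(max_examples=100, derandomize=True)
    def test_matches_matrix_lookup_and_symmetry(self, x, y):
        expected = sum(blosum62_lookup(a, b) for a, b in zip(x, y))
        assert subsequence_similarity(x, y) == expected
        assert subsequence_similarity(x, y) == subsequence_similarity(y, x)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            subsequence_similarity("AAAA", "AAAAA")


def brute_force_clusters(subsequences, t=8):
    """Naive re-implementation: rescan every cluster representative per step."""
    clusters = []  # (representative, members)
    for ss in subsequences:
        best_idx, best_score = -1, None
        for idx, (rep, _members) in enumerate(clusters):
            score = subsequence_similarity(rep, ss)
            if score >= t and (best_score is None or score > best_score):
                best_idx, best_score = idx, score
        if best_idx >= 0:
            clusters[best_idx][1].append(ss)
        else:
            clusters.append((ss, [ss]))
    return clusters


class TestClustering:
    def test_singleton(self):
        clusters = cluster_subsequences(["AAAAA"])
        assert len(clusters) == 1 and clusters[0].size == 1

    def test_identical_windows_join(self):
        clusters = cluster_subsequences(["AAAAA", "AAAAA"], t=8)
        assert len(clusters) == 1 and clusters[0].size == 2

    def test_dissimilar_windows_split(self):
        assert len(cluster_subsequences(["AAAAA", "WWWWW"], t=8)) == 2

    @given(st.lists(windows5, min_size=1, max_size=20))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_matches_brute_force_oracle(self, subsequences):
        ours = cluster_subsequences(subsequences, t=8)
        oracle = brute_force_clusters(subsequences, t=8)
        assert [(c.representative, c.size) for c in ours] == [
            (rep, len(members)) for rep, members in oracle
        ]

    @given(st.lists(windows5, min_size=1, max_size=25))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_count_conservation(self, subsequences):
        for cluster in cluster_subsequences(subsequences):
            assert (cluster.counts.sum(axis=1) == cluster.size).all()

    def test_deterministic(self):
        windows = ["AAAAA", "AAAAC", "WWWWW", "WWWWY", "CCCCC"] * 3
        a = cluster_subsequences(windows)
        b = cluster_subsequences(windows)
        assert [(c.representative, c.size) for c in a] == [
            (c.representative, c.size) for c in b
        ]


class TestProfiles:
    def test_small_clusters_discarded(self):
        clusters = cluster_subsequences(["AAAAA"] * 5 + ["WWWWW"] * 15)
        pmap = build_profiles(clusters, n_positive=100, discard_fraction=0.10)
        assert pmap.n_features == 1
        assert pmap.clusters[0].representative == "WWWWW"

    def test_all_discarded_errors(self):
        clusters = cluster_subsequences(["AAAAA"])
        with pytest.raises(ValueError, match="no profiles retained"):
            build_profiles(clusters, n_positive=100)

    def test_zero_count_pseudocount_value(self):
        counts = np.zeros((5, 20), dtype=np.int64)
        counts[:, 0] = 100  # 100 members, all "AAAAA"
        cluster = SubsequenceCluster("AAAAA", 100, counts)
        pmap = build_profiles([cluster], n_positive=100)
        # an unseen residue: ln((0 + 0.01)/100) = ln(0.0001)
        assert pmap.profiles[0][0, 1] == pytest.approx(math.log(1e-4), abs=1e-9)
        # the consensus residue: ln((100 + 0.01)/100)
        assert pmap.profiles[0][0, 0] == pytest.approx(math.log(100.01 / 100), abs=1e-9)

    def test_single_member_profile_value(self):
        pmap = build_profiles(cluster_subsequences(["AAAAA"]), n_positive=1)
        assert pmap.profiles[0][0, 0] == pytest.approx(math.log(1.01), abs=1e-9)

    def test_json_roundtrip(self, tmp_path):
        pmap = fit_profile_map(
            [ProteinRecord(f"p{i}", "AAAAACAAAAA") for i in range(4)], l=5
        )
        path = tmp_path / "pmap.json"
        pmap.to_json(path)
        loaded = ProfileMap.from_json(path)
        assert loaded.n_features == pmap.n_features
        np.testing.assert_allclose(loaded.profiles, pmap.profiles)


class TestScoring:
    @pytest.fixture()
    def single_profile_map(self):
        return build_profiles(cluster_subsequences(["AAAAA"]), n_positive=1)

    def test_log_prob_values(self, single_profile_map):
        profile = single_profile_map.profiles[0]
        assert subsequence_log_prob("AAAAA", profile) == pytest.approx(
            5 * math.log(1.01), abs=1e-9
        )
        assert subsequence_log_prob("WWWWW", profile) == pytest.approx(
            5 * math.log(0.01), abs=1e-9
        )

    def test_monotone_in_residue_counts(self, single_profile_map):
        profile = single_profile_map.profiles[0]
        assert subsequence_log_prob("AAAAW", profile) < subsequence_log_prob(
            "AAAAA", profile
        )

    def test_featurize_clips_to_one(self, single_profile_map):
        # exp(5 ln 1.01) = 1.0510... exceeds 1 via the pseudo-count; clipped
        value = featurize("AAAAA", single_profile_map)[0]
        assert value == 1.0

    def test_featurize_dissimilar_tiny(self, single_profile_map):
        value = featurize("WWWWW", single_profile_map)[0]
        assert value == pytest.approx(math.exp(5 * math.log(0.01)), rel=1e-6)

    def test_dimension_matches_profiles(self):
        pmap = fit_profile_map(
            [ProteinRecord(f"p{i}", "AAAAAWWWWWCCCCC") for i in range(3)], l=5
        )
        assert featurize("AAAAAWWWWW", pmap).shape == (pmap.n_features,)

    def test_short_protein_zero_vector_with_warning(self, single_profile_map):
        with pytest.warns(UserWarning, match="no length-5 window"):
            vec = featurize("ACD", single_profile_map)
        assert (vec == 0).all()

    def test_positive_wherever_windows_exist(self, single_profile_map):
        assert (featurize("MNPQRSTVWY", single_profile_map) > 0).all()
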