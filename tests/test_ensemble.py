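import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enzyclass.ensemble import (
    auroc,
    combine_weights,
    select_positive_cutoff,
    train_binary_classifier,
    weighted_score,
)


def brute_force_auroc(pos, neg):
    """Exhaustive pairwise counting with 0.5 credit for ties."""
    wins = sum(
        1.0 if p > n else (0.5 if p == n else 0.0)
        for p, n in itertools.product(pos, neg)
    )
    return wins / (len(pos) * len(neg))


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0.9, 0.8], [0.2, 0.1]) == 1.0

    def test_constant_scorer_is_half(self):
        assert auroc([0.5] * 4, [0.5] * 6) == 0.5

    def test_hand_example(self):
        # 8 of 9 pos-neg pairs ranked correctly
        assert auroc([0.9, 0.8, 0.4], [0.7, 0.3, 0.2]) == pytest.approx(8 / 9)

    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=10),
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=10),
    )
    @settings(max_examples=100, derandomize=True)
    def test_matches_pairwise_oracle(self, pos, neg):
        assert auroc(pos, neg) == pytest.approx(brute_force_auroc(pos, neg))

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError):
            auroc([], [0.5])


class TestWeighting:
    def test_equal_aurocs_give_equal_weights(self):
        np.testing.assert_allclose(combine_weights([0.8, 0.8, 0.8]), [1 / 3] * 3)

    def test_fourth_power_example(self):
        w = combine_weights([0.9, 0.8, 0.7])
        np.testing.assert_allclose(w, [0.5025, 0.3137, 0.1839], atol=5e-4)

    @given(st.lists(st.floats(0.01, 1.0, allow_nan=False), min_size=3, max_size=3))
    @settings(max_examples=100, derandomize=True)
    def test_normalized_and_order_preserving(self, r):
        w = combine_weights(r)
        assert w.sum() == pytest.approx(1.0)
        order = np.argsort(r)
        assert (np.argsort(w) == order).all()

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            combine_weights([0.0, 0.0, 0.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            combine_weights([1.2, 0.5, 0.5])


class TestWeightedScore:
    def test_endpoints(self):
        w = combine_weights([0.9, 0.8, 0.7])
        assert weighted_score([1, 1, 1], w) == pytest.approx(1.0)
        assert weighted_score([0, 0, 0], w) == 0.0

    def test_single_active_component(self):
        w = combine_weights([0.9, 0.8, 0.7])
        assert weighted_score([1, 0, 0], w) == pytest.approx(w[0])

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=3, max_size=3))
    @settings(max_examples=100, derandomize=True)
    def test_bounded_by_component_range(self, scores):
        w = combine_weights([0.9, 0.8, 0.7])
        s = weighted_score(scores, w)
        assert min(scores) - 1e-12 <= s <= max(scores) + 1e-12


class TestCutoffSweep:
    def test_tie_break_toward_largest_cutoff(self):
        pairs = [(0.9, True), (0.8, True), (0.2, False), (0.1, False)]
        assert select_positive_cutoff(pairs) == pytest.approx(0.79)

    def test_permutation_invariant(self):
        pairs = [(0.9, True), (0.3, False), (0.7, True), (0.5, False)]
        assert select_positive_cutoff(pairs) == select_positive_cutoff(pairs[::-1])

    def test_inverted_scores_warn(self):
        pairs = [(0.1, True), (0.2, True), (0.8, False), (0.9, False)]
        with pytest.warns(UserWarning):
            select_positive_cutoff(pairs)

    def test_clamped_above_negative_cutoff(self):
        pairs = [(0.25, True), (0.2, True), (0.05, False), (0.02, False)]
        with pytest.warns(UserWarning, match="clamping"):
            cutoff = select_positive_cutoff(pairs, negative_cutoff=0.3)
        assert cutoff > 0.3

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            select_positive_cutoff([(0.9, True), (0.8, True)])


class TestBinaryClassifier:
    @pytest.fixture()
    def separable(self, rng):
        X_pos = rng.normal(1.0, 0.1, size=(12, 3))
        X_neg = rng.normal(-1.0, 0.1, size=(12, 3))
        X = np.vstack([X_pos, X_neg])
        y = np.array([1] * 12 + [0] * 12)
        return X, y

    def test_separable_training_scores(self, separable):
        X, y = separable
        model = train_binary_classifier(X, y, seed=0)
        proba = model.predict_proba(X)[:, 1]
        assert (proba[y == 1] > 0.5).all()
        assert (proba[y == 0] < 0.5).all()

    def test_deterministic_under_seed(self, separable):
        X, y = separable
        a = train_binary_classifier(X, y, seed=3).predict_proba(X)[:, 1]
        b = train_binary_classifier(X, y, seed=3).predict_proba(X)[:, 1]
        np.testing.assert_array_equal(a, b)

    def test_label_inversion_roughly_flips_scores(self, separable):
        X, y = separable
        a = train_binary_classifier(X, y, seed=0).predict_proba(X)[:, 1]
        b = train_binary_classifier(X, 1 - y, seed=0).predict_proba(X)[:, 1]
        np.testing.assert_allclose(a, 1 - b, atol=0.15)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_binary_classifier(np.zeros((4, 2)), np.ones(4))


class TestTrainedClassModels:
    def test_synthetic_classes_recovered(self, small_benchmark):
        """Motif-defined families yield high AUROC for every base predictor."""
        for ec, model in small_benchmark.tree.models.items():
            assert (model.aurocs > 0.6).all(), (ec, model.aurocs)
            assert model.aurocs[0] > 0.9  # subsequence profiles see the motifs
            assert model.weights.sum() == pytest.approx(1.0)
            assert model.negative_cutoff == 0.3
            assert 0.3 < model.positive_cutoff <= 1.0

    def test_cutoffs_in_plausible_band(self, small_benchmark):
        cutoffs = [m.positive_cutoff for m in small_benchmark.tree.models.values()]
        assert all(0.4 <= c <= 0.95 for c in cutoffs)

    def test_balanced_negative_sets(self, small_benchmark):
        for model in small_benchmark.tree.models.values():
            meta = model.metadata
            assert abs(meta["n_negative_train"] - meta["n_positive_train"]) <= 1

    def test_model_roundtrips_through_directory(self, small_benchmark, tmp_path, rng):
        from enzyclass.ensemble import ECClassModel
        from enzyclass.records import ProteinRecord

        ec = next(iter(small_benchmark.tree.models))
        model = small_benchmark.tree.models[ec]
        model.save(tmp_path / "m")
        loaded = ECClassModel.load(tmp_path / "m")
        from conftest import random_protein

        probe = ProteinRecord("probe", random_protein(rng, 150))
        assert loaded.score(probe) == pytest.approx(model.score(probe))
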