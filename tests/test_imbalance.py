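"""Oversampling, reverse loss re-weighting, and the gradient penalty."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from restransnet.imbalance import (
    PenaltyConfig,
    apply_gradient_penalty,
    cosine_similarity_matrix,
    gradient_penalty_factors,
    oversample,
    penalty_factors,
    reverse_weights,
)


class TestOversample:
    def test_four_to_one_labels_balance_to_majority_count(self):
        labels = np.array([0, 0, 0, 0, 1])
        idx = oversample(labels, np.random.default_rng(0))
        assert len(idx) == 8
        assert (labels[idx] == 0).sum() == 4
        assert (labels[idx] == 1).sum() == 4
        assert set(idx[labels[idx] == 1]) == {4}  # the single positive repeated

    def test_balanced_labels_give_a_permutation(self):
        labels = np.array([0, 1, 0, 1])
        idx = oversample(labels, np.random.default_rng(1))
        assert sorted(idx) == [0, 1, 2, 3]

    def test_59_16_training_ratio_becomes_59_59(self):
        labels = np.array([0] * 59 + [1] * 16)
        idx = oversample(labels, np.random.default_rng(2))
        assert (labels[idx] == 0).sum() == 59
        assert (labels[idx] == 1).sum() == 59

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            oversample(np.zeros(5, dtype=int), np.random.default_rng(0))

    def test_deterministic_given_seed(self):
        labels = np.array([0, 0, 0, 1, 1])
        a = oversample(labels, np.random.default_rng(7))
        b = oversample(labels, np.random.default_rng(7))
        assert np.array_equal(a, b)


class TestReverseWeights:
    def test_59_16_counts_weight_tail_over_head(self):
        w = reverse_weights([59, 16])
        assert w[1] / w[0] == pytest.approx(59 / 16)
        assert w.mean() == pytest.approx(1.0)

    def test_equal_counts_give_unit_weights(self):
        np.testing.assert_allclose(reverse_weights([10, 10]), [1.0, 1.0])

    def test_zero_count_raises(self):
        with pytest.raises(ValueError):
            reverse_weights([5, 0])


class TestCosineSimilarity:
    def test_identical_and_orthogonal_vectors(self):
        g = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 2.0]])
        s = cosine_similarity_matrix(g)
        assert s[0, 1] == pytest.approx(1.0)
        assert s[0, 2] == pytest.approx(0.0)
        np.testing.assert_allclose(s, s.T)
        np.testing.assert_allclose(np.diag(s), 1.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(3)
        g = rng.normal(size=(4, 10))
        s = cosine_similarity_matrix(g)
        for i in range(4):
            for j in range(4):
                expect = g[i] @ g[j] / (np.linalg.norm(g[i]) * np.linalg.norm(g[j]))
                assert s[i, j] == pytest.approx(expect, abs=1e-6)

    def test_zero_gradient_vector_gets_zero_similarity(self):
        g = np.array([[0.0, 0.0], [1.0, 1.0]])
        s = cosine_similarity_matrix(g)
        assert s[0, 0] == 0.0 and s[0, 1] == 0.0

    def test_non_finite_gradients_raise(self):
        with pytest.raises(ValueError):
            cosine_similarity_matrix(np.array([[np.inf, 0.0], [1.0, 0.0]]))


class TestPenaltyFactors:
    def test_duplicated_pair_shrinks_both(self):
        s = np.array([[1.0, 1.0], [1.0, 1.0]])
        np.testing.assert_allclose(penalty_factors(s, 0.9, 0.5), [0.5, 0.5])

    def test_orthogonal_batch_untouched(self):
        np.testing.assert_allclose(penalty_factors(np.eye(3), 0.9, 0.5), 1.0)

    def test_mixed_batch_matches_any_pair_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            g = rng.normal(size=(6, 8))
            g[1] = g[0] * rng.uniform(0.5, 2.0)  # force one aligned pair
            s = cosine_similarity_matrix(g)
            f = penalty_factors(s, 0.9, 0.5)
            for i in range(6):
                exceeds = any(s[i, j] > 0.9 for j in range(6) if j != i)
                assert f[i] == (0.5 if exceeds else 1.0)

    def test_per_pair_variant_compounds_lambda(self):
        s = np.ones((3, 3))
        f = penalty_factors(s, 0.9, 0.5, per_pair=True)
        np.testing.assert_allclose(f, 0.25)  # two above-threshold partners each

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6), st.floats(0.05, 0.9), st.floats(0.0, 0.099))
    def test_monotone_in_epsilon(self, seed, eps, bump):
        rng = np.random.default_rng(seed)
        s = cosine_similarity_matrix(rng.normal(size=(5, 6)))
        f_low = penalty_factors(s, eps, 0.5)
        f_high = penalty_factors(s, eps + bump, 0.5)
        assert (f_high >= f_low).all()  # raising epsilon never penalises more

    def test_invalid_epsilon_raises(self):
        with pytest.raises(ValueError):
            penalty_factors(np.eye(2), epsilon=1.5)


class TestApplyGradientPenalty:
    def test_unit_factors_reproduce_plain_mean_gradient(self):
        rng = np.random.default_rng(5)
        g = rng.normal(size=(4, 7))
        np.testing.assert_array_equal(
            apply_gradient_penalty(g, np.ones(4)), g.mean(axis=0))

    def test_duplicated_samples_scale_aggregate_by_lambda(self):
        g = np.tile(np.random.default_rng(6).normal(size=7), (2, 1))
        f = gradient_penalty_factors(g, PenaltyConfig(epsilon=0.9, lambda_shrink=0.5))
        np.testing.assert_allclose(
            apply_gradient_penalty(g, f), 0.5 * g.mean(axis=0), atol=1e-12)

    def test_matches_per_sample_loop_oracle(self):
        rng = np.random.default_rng(7)
        g = rng.normal(size=(5, 9))
        f = rng.uniform(0.3, 1.0, size=5)
        loop = sum(f[i] * g[i] for i in range(5)) / 5
        np.testing.assert_allclose(apply_gradient_penalty(g, f), loop, atol=1e-12)

    def test_penalised_norm_never_exceeds_unpenalised_for_aligned_batch(self):
        rng = np.random.default_rng(8)
        base = rng.normal(size=9)
        g = np.stack([base * s for s in rng.uniform(0.5, 2.0, size=6)])
        f = gradient_penalty_factors(g)
        assert np.linalg.norm(apply_gradient_penalty(g, f)) <= \
            np.linalg.norm(g.mean(axis=0)) + 1e-12

    def test_factor_count_mismatch_raises(self):
        with pytest.raises(ValueError):
            apply_gradient_penalty(np.ones((3, 2)), np.ones(2))


def test_per_sample_gradients_full_scope_matches_penalty_scope_tail(tiny_model,
                                                                    small_cohort):
    """Scoped per-sample gradients equal the corresponding slice of the
    full-network per-sample gradients (same loss, same parameters)."""
    x = np.stack([s.image.pixels for s in small_cohort[:3]])[:, None]
    y = np.array([s.label for s in small_cohort[:3]])
    tiny_model.eval()  # keep batch statistics out of the comparison
    g_scope = tiny_model.per_sample_gradients(x, y, scope="penalty")
    g_full = tiny_model.per_sample_gradients(x, y, scope="full")
    scope_names = {name for name, _ in tiny_model.penalty_scope_parameters()}
    cols, start = [], 0
    for name, p in tiny_model.named_parameters():
        size = p.data.size
        if name in scope_names:
            cols.append(np.arange(start, start + size))
        start += size
    sel = np.concatenate(cols)
    np.testing.assert_allclose(g_scope, g_full[:, sel], atol=1e-5)


def test_duplicate_images_in_batch_are_penalised(tiny_model, small_cohort):
    """Oversampling duplicates produce cosine-1 gradient pairs, which the
    penalty shrinks by lambda."""
    x1 = small_cohort[0].image.pixels[None, None]
    x = np.concatenate([x1, x1, small_cohort[1].image.pixels[None, None]])
    y = np.array([small_cohort[0].label] * 2 + [small_cohort[1].label])
    tiny_model.eval()
    g = tiny_model.per_sample_gradients(x, y, scope="penalty")
    f = gradient_penalty_factors(g, PenaltyConfig(epsilon=0.9, lambda_shrink=0.5))
    assert f[0] == 0.5 and f[1] == 0.5
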