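"""Closed-form values, bounds and gradients of the complement-entropy family."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from drgrade import (
    LabeledBatch,
    LossConfig,
    balanced_complement_entropy,
    cce_loss,
    complement_entropy,
    cross_entropy,
    focal_loss,
    make_training_loss,
)
from drgrade import autodiff as ad


def batch(probs, labels):
    return LabeledBatch(np.asarray(probs), np.asarray(labels))


def random_simplex_batch(rng, n, k):
    p = rng.dirichlet(np.ones(k) * rng.uniform(0.3, 3.0), size=n)
    g = rng.integers(0, k, size=n)
    return batch(p, g)


class TestCrossEntropy:
    def test_perfect_prediction_is_zero(self):
        b = batch([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]], [0, 1])
        assert cross_entropy(b) == pytest.approx(0.0, abs=1e-6)

    def test_uniform_five_class_is_ln5(self):
        b = batch(np.full((3, 5), 0.2), [0, 2, 4])
        assert cross_entropy(b) == pytest.approx(np.log(5.0), rel=1e-12)

    def test_mean_reduction_over_samples(self):
        b1 = batch([[0.7, 0.3]], [0])
        b2 = batch([[0.2, 0.8]], [1])
        both = batch([[0.7, 0.3], [0.2, 0.8]], [0, 1])
        assert cross_entropy(both) == pytest.approx(
            (cross_entropy(b1) + cross_entropy(b2)) / 2
        )

    def test_invalid_label_rejected(self):
        with pytest.raises(IndexError):
            batch([[0.5, 0.5]], [2])


class TestComplementEntropy:
    def test_uniform_non_target_pair_is_ln2(self):
        b = batch([[0.5, 0.25, 0.25]], [0])
        assert complement_entropy(b) == pytest.approx(np.log(2.0), rel=1e-12)

    def test_degenerate_non_target_mass_is_zero(self):
        b = batch([[0.5, 0.5, 0.0]], [0])
        assert complement_entropy(b) == pytest.approx(0.0, abs=1e-12)

    def test_maximal_uniform_mass_over_four_classes(self):
        b = batch([[0.2, 0.2, 0.2, 0.2, 0.2]], [0])
        assert complement_entropy(b) == pytest.approx(np.log(4.0), rel=1e-12)

    def test_certain_target_contributes_zero(self):
        b = batch([[1.0, 0.0, 0.0]], [0])
        assert complement_entropy(b) == pytest.approx(0.0, abs=1e-9)

    def test_two_classes_rejected_below(self):
        with pytest.raises(ValueError):
            complement_entropy(batch([[1.0]], [0]))

    def test_invariant_to_non_target_permutation(self, rng):
        p = np.array([[0.4, 0.3, 0.2, 0.1]])
        b1 = batch(p, [0])
        b2 = batch(p[:, [0, 3, 1, 2]], [0])
        assert complement_entropy(b1) == pytest.approx(complement_entropy(b2))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(2, 10), st.integers(0, 10_000))
    def test_bounded_by_log_k_minus_1(self, k, seed):
        rng = np.random.default_rng(seed)
        b = random_simplex_batch(rng, 20, k)
        c = complement_entropy(b)
        assert -1e-9 <= c <= np.log(max(k - 1, 1)) + 1e-9

    def test_maximised_at_uniform_non_target_mass(self):
        """Grid search over the 2-simplex at K=3: max at equal non-target split."""
        best, best_p = -1.0, None
        for p1 in np.linspace(0.0, 0.6, 61):
            p2 = 0.6 - p1
            b = batch([[0.4, p1, p2]], [0])
            c = complement_entropy(b)
            if c > best:
                best, best_p = c, (p1, p2)
        assert best == pytest.approx(np.log(2.0), rel=1e-9)
        assert best_p[0] == pytest.approx(best_p[1], abs=1e-9)


class TestBalancedAndCombined:
    def test_balance_coefficient(self):
        b = batch([[0.2, 0.2, 0.2, 0.2, 0.2]], [0])
        assert balanced_complement_entropy(b) == pytest.approx(np.log(4.0) / 4.0)

    def test_two_classes_coefficient_is_one(self):
        b = batch([[0.6, 0.4]], [0])
        assert balanced_complement_entropy(b) == pytest.approx(complement_entropy(b))

    def test_gamma_zero_reduces_to_cross_entropy(self, rng):
        b = random_simplex_batch(rng, 30, 5)
        cfg = LossConfig(gamma=0.0)
        assert cce_loss(b, cfg) == cross_entropy(b, cfg)

    def test_direct_evaluation_with_default_gamma(self):
        b = batch([[0.5, 0.25, 0.25]], [0])
        expected = np.log(2.0) - 0.5 * np.log(2.0)
        assert cce_loss(b) == pytest.approx(expected, rel=1e-12)

    def test_negative_gamma_rewards_flat_non_target_mass(self):
        flat = batch([[0.5, 0.25, 0.25]], [0])
        peaked = batch([[0.5, 0.45, 0.05]], [0])
        assert cce_loss(flat) < cce_loss(peaked)


class TestFocalLoss:
    def test_reduces_to_cross_entropy_at_gamma_zero(self, rng):
        b = random_simplex_batch(rng, 30, 5)
        cfg = LossConfig(focal_gamma=0.0, focal_alpha=1.0)
        assert focal_loss(b, cfg) == pytest.approx(cross_entropy(b, cfg))

    def test_perfect_prediction_is_zero(self):
        b = batch([[1.0, 0.0]], [0])
        assert focal_loss(b) == pytest.approx(0.0, abs=1e-9)

    def test_direct_evaluation(self):
        b = batch([[0.5, 0.5]], [0])
        cfg = LossConfig(focal_gamma=2.0, focal_alpha=1.0)
        assert focal_loss(b, cfg) == pytest.approx(0.25 * np.log(2.0), rel=1e-12)

    def test_negative_focal_gamma_rejected(self):
        with pytest.raises(ValueError):
            focal_loss(batch([[0.5, 0.5]], [0]), LossConfig(focal_gamma=-1.0))


class TestDifferentiableLosses:
    """Analytic gradients of the training losses vs central finite differences."""

    @pytest.mark.parametrize("name", ["ce", "cce", "focal"])
    def test_gradient_matches_finite_differences(self, name, rng):
        n, k = 4, 5
        p = rng.dirichlet(np.ones(k), size=n)
        labels = rng.integers(0, k, size=n)
        loss_fn = make_training_loss(name, LossConfig())

        t = ad.tensor(p, requires_grad=True)
        loss_fn(t, labels).backward()

        eps = 1e-6
        num = np.zeros_like(p)
        for i in range(n):
            for j in range(k):
                pp, pm = p.copy(), p.copy()
                pp[i, j] += eps
                pm[i, j] -= eps
                num[i, j] = (
                    loss_fn(ad.tensor(pp), labels).item()
                    - loss_fn(ad.tensor(pm), labels).item()
                ) / (2 * eps)
        np.testing.assert_allclose(t.grad, num, atol=1e-5)

    def test_gradient_at_uniform_distribution(self):
        k = 5
        p = np.full((1, k), 1.0 / k)
        labels = np.array([2])
        loss_fn = make_training_loss("cce", LossConfig())
        t = ad.tensor(p, requires_grad=True)
        loss_fn(t, labels).backward()
        eps = 1e-6
        for j in range(k):
            pp, pm = p.copy(), p.copy()
            pp[0, j] += eps
            pm[0, j] -= eps
            num = (loss_fn(ad.tensor(pp), labels).item()
                   - loss_fn(ad.tensor(pm), labels).item()) / (2 * eps)
            assert t.grad[0, j] == pytest.approx(num, abs=1e-5)

    def test_training_and_reference_values_agree(self, rng):
        b = random_simplex_batch(rng, 25, 5)
        for name, ref in [("ce", cross_entropy), ("cce", cce_loss),
                          ("focal", focal_loss)]:
            fn = make_training_loss(name)
            assert fn(ad.tensor(b.probs), b.labels).item() == pytest.approx(
                ref(b), rel=1e-9
            )

    def test_unknown_loss_rejected(self):
        with pytest.raises(ValueError):
            make_training_loss("hinge")
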