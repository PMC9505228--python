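"""Loss functions, weighting schemes, and their analytic gradients."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acnedet.losses import (
    LossConfig,
    WeightScheme,
    combined_loss,
    compute_weights,
    cross_entropy_grad_logits,
    focal_grad_logits,
    focal_loss,
    kl_divergence_loss,
    kl_grad_logits,
    log_softmax,
    softmax,
    weighted_cross_entropy,
)


class TestComputeWeights:
    def test_uniform_is_all_ones(self):
        assert np.array_equal(compute_weights([3, 7, 9], "uniform"), [1, 1, 1])

    def test_category_size_is_identity_on_sizes(self):
        assert np.array_equal(compute_weights([3, 7, 9], "category_size"), [3, 7, 9])

    def test_minmax_normalization(self):
        assert np.allclose(compute_weights([1, 3, 5], "minmax_normalized"), [0, 0.5, 1])

    def test_standardization_uses_population_std(self):
        w = compute_weights([2, 4, 6], "standardized")
        assert np.allclose(w, [-1.22474487, 0.0, 1.22474487], atol=1e-8)

    def test_sum_one_rescale_of_minmax(self):
        w = compute_weights([1, 3, 5], "normalized_sum_one")
        assert np.allclose(w, [0, 1 / 3, 2 / 3])
        assert w.sum() == pytest.approx(1.0)

    def test_degenerate_scale_rejected(self):
        for scheme in ("minmax_normalized", "standardized"):
            with pytest.raises(ValueError, match="degenerate"):
                compute_weights([5, 5, 5], scheme)

    def test_minmax_bounds_hold_for_random_sizes(self, rng):
        for _ in range(20):
            sizes = rng.integers(0, 200, size=8)
            if np.ptp(sizes) == 0:
                continue
            w = compute_weights(sizes, "minmax_normalized")
            assert w.min() == 0.0 and w.max() == 1.0

    def test_inverse_frequency_downweights_large_categories(self):
        w = compute_weights([10, 100], "inverse_frequency")
        assert w[0] > w[1]


class TestCrossEntropy:
    def test_direct_value(self):
        assert weighted_cross_entropy([0.5, 0.25, 0.25], 0) == pytest.approx(np.log(2))

    def test_perfect_prediction_is_zero(self):
        assert weighted_cross_entropy([0, 1.0, 0], 1) == pytest.approx(0.0, abs=1e-10)

    def test_linear_in_weights(self, rng):
        p = rng.dirichlet(np.ones(4), size=6)
        y = rng.integers(0, 4, size=6)
        w = rng.uniform(0.5, 2.0, size=4)
        assert weighted_cross_entropy(p, y, 2 * w) == pytest.approx(
            2 * weighted_cross_entropy(p, y, w)
        )

    def test_wrong_weight_length_rejected(self):
        with pytest.raises(ValueError):
            weighted_cross_entropy([0.5, 0.5], 0, [1.0, 1.0, 1.0])


class TestFocalLoss:
    def test_alpha_zero_degenerates_to_cross_entropy(self, rng):
        for _ in range(100):
            p = rng.dirichlet(np.ones(5), size=4)
            y = rng.integers(0, 5, size=4)
            w = rng.uniform(0.1, 3.0, size=5)
            assert abs(
                focal_loss(p, y, w, 0.0) - weighted_cross_entropy(p, y, w)
            ) < 1e-12

    def test_direct_value(self):
        assert focal_loss([0.5, 0.5], 0, None, 2.0) == pytest.approx(0.25 * np.log(2))

    def test_loss_decreases_with_alpha_for_confident_prediction(self):
        losses = [focal_loss([0.9, 0.1], 0, None, a) for a in (0, 1, 2, 3, 4)]
        assert all(b < a for a, b in zip(losses, losses[1:]))

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError):
            focal_loss([0.5, 0.5], 0, None, -1.0)


class TestKlDivergence:
    def test_identical_distributions_give_zero(self, rng):
        p = rng.dirichlet(np.ones(6))
        assert kl_divergence_loss(np.log(p), p) == pytest.approx(0.0, abs=1e-12)

    def test_one_hot_target_against_uniform(self):
        assert kl_divergence_loss(np.log([0.5, 0.5]), [1.0, 0.0]) == pytest.approx(np.log(2))

    def test_nonnegative_on_random_pairs(self, rng):
        for _ in range(100):
            p = rng.dirichlet(np.ones(8))
            q = rng.dirichlet(np.ones(8))
            assert kl_divergence_loss(np.log(p), q) >= -1e-12

    def test_unnormalized_target_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            kl_divergence_loss(np.log([0.5, 0.5]), [0.7, 0.6])

    def test_one_hot_target_equals_cross_entropy(self, rng):
        # KL to a one-hot target has zero entropy term
        for _ in range(20):
            z = rng.normal(size=(3, 5))
            y = rng.integers(0, 5, size=3)
            onehot = np.eye(5)[y]
            kl = kl_divergence_loss(log_softmax(z), onehot)
            ce = weighted_cross_entropy(softmax(z), y)
            assert kl == pytest.approx(ce, abs=1e-9)


class TestCombinedLoss:
    @pytest.mark.parametrize(
        "det,cls,a,b,expect",
        [(1.0, 2.0, 0.5, 0.5, 1.5), (3.0, 9.9, 0.5, 0.0, 1.5), (1.0, 1.0, 0.0, 0.0, 0.0)],
    )
    def test_arithmetic(self, det, cls, a, b, expect):
        assert combined_loss(det, cls, a, b) == pytest.approx(expect)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            combined_loss(np.nan, 1.0)


class TestBatchProperties:
    @settings(deadline=None, max_examples=20)
    @given(st.integers(0, 2**31 - 1))
    def test_losses_permutation_equivariant_in_batch(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(4), size=8)
        y = rng.integers(0, 4, size=8)
        perm = rng.permutation(8)
        assert weighted_cross_entropy(p, y) == pytest.approx(
            weighted_cross_entropy(p[perm], y[perm])
        )
        assert focal_loss(p, y, None, 2.0) == pytest.approx(
            focal_loss(p[perm], y[perm], None, 2.0)
        )
        q = rng.dirichlet(np.ones(4), size=8)
        assert kl_divergence_loss(np.log(p), q) == pytest.approx(
            kl_divergence_loss(np.log(p[perm]), q[perm])
        )


class TestGradients:
    """Analytic gradients drive training; verify against finite differences."""

    def _num_grad(self, f, z, eps=1e-6):
        g = np.zeros_like(z)
        it = np.nditer(z, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            z[i] += eps
            fp = f(z)
            z[i] -= 2 * eps
            fm = f(z)
            z[i] += eps
            g[i] = (fp - fm) / (2 * eps)
        return g

    @pytest.mark.parametrize("focusing", [0.0, 2.0])
    def test_focal_and_ce_gradients(self, rng, focusing):
        z = rng.normal(size=(3, 5))
        y = rng.integers(0, 5, size=3)
        w = rng.uniform(0.5, 2.0, size=5)
        loss, grad = focal_grad_logits(z, y, w, focusing)
        num = self._num_grad(lambda zz: focal_grad_logits(zz, y, w, focusing)[0], z)
        assert np.allclose(grad, num, atol=1e-7)
        if focusing == 0.0:
            loss_ce, grad_ce = cross_entropy_grad_logits(z, y, w)
            assert loss == pytest.approx(loss_ce, abs=1e-12)
            assert np.allclose(grad, grad_ce, atol=1e-12)

    def test_kl_gradient(self, rng):
        z = rng.normal(size=(4, 6))
        t = rng.dirichlet(np.ones(6), size=4)
        _, grad = kl_grad_logits(z, t)
        num = self._num_grad(lambda zz: kl_grad_logits(zz, t)[0], z)
        assert np.allclose(grad, num, atol=1e-7)


def test_loss_config_validation():
    with pytest.raises(ValueError):
        LossConfig(kind="hinge")
    with pytest.raises(ValueError):
        LossConfig(focusing=-0.5)
    cfg = LossConfig(kind="focal", weight_scheme="minmax_normalized")
    assert cfg.weight_scheme is WeightScheme.MINMAX_NORMALIZED
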