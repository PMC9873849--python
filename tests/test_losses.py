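"""Loss algebra: balance weights, weighted BCE, soft margin, ECR/OHEM, combo."""

import numpy as np
import pytest

from camloc.losses import (SeamLossConfig, class_balance_weights, ecr_with_ohem,
                           multilabel_soft_margin, seam_total, weighted_bce)
from camloc.nn import Tensor


def bce_oracle(probs, labels, bp, bn, eps=1e-7):
    """Literal per-element double loop over the weighted BCE definition."""
    B, n = probs.shape
    per_sample = np.zeros(B)
    for b in range(B):
        for c in range(n):
            f = min(max(probs[b, c], eps), 1 - eps)
            per_sample[b] += -bp[c] * labels[b, c] * np.log(f) \
                             - bn[c] * (1 - labels[b, c]) * np.log(1 - f)
    return per_sample.mean()


class TestBalanceWeights:
    def test_one_positive_three_negatives(self):
        y = np.array([[1], [0], [0], [0]])
        w = class_balance_weights(y)
        assert np.allclose(w.beta_P, 4.0) and np.allclose(w.beta_N, 4 / 3)

    def test_balanced_counts(self):
        y = np.array([[1], [1], [0], [0]])
        w = class_balance_weights(y)
        assert np.allclose(w.beta_P, 2.0) and np.allclose(w.beta_N, 2.0)

    def test_all_negative_class_zero_guard(self):
        y = np.zeros((5, 1))
        w = class_balance_weights(y)
        assert w.beta_P[0] == 0.0 and np.allclose(w.beta_N, 1.0)

    def test_reciprocal_identity_on_random_batches(self, rng):
        for _ in range(20):
            y = (rng.uniform(size=(16, 6)) < 0.3).astype(float)
            w = class_balance_weights(y)
            both = (y.sum(0) > 0) & (y.sum(0) < 16)
            ident = 1 / w.beta_P[both] + 1 / w.beta_N[both]
            assert np.allclose(ident, 1.0)


class TestWeightedBce:
    def test_hand_value_single_sample(self):
        from camloc.losses import ClassBalanceWeights
        w = ClassBalanceWeights(beta_P=np.array([2.0]), beta_N=np.array([1.0]))
        loss = weighted_bce(np.array([[0.8]]), np.array([[1]]), w)
        assert abs(loss.item() - 2 * -np.log(0.8)) < 1e-9

    def test_perfect_predictions_vanish(self):
        y = np.array([[1.0, 0.0]])
        w = class_balance_weights(y)
        loss = weighted_bce(np.array([[1.0 - 1e-9, 1e-9]]), y, w)
        assert loss.item() < 1e-5

    def test_balanced_batch_is_twice_unweighted(self, rng):
        y = np.array([[1.0], [0.0]])
        w = class_balance_weights(y)      # beta_P = beta_N = 2
        f = rng.uniform(0.1, 0.9, size=(2, 1))
        unweighted = -(np.log(f[0, 0]) + np.log(1 - f[1, 0])) / 2
        assert abs(weighted_bce(f, y, w).item() - 2 * unweighted) < 1e-9

    def test_matches_element_wise_oracle(self, rng):
        for _ in range(20):
            y = (rng.uniform(size=(8, 5)) < 0.4).astype(float)
            f = rng.uniform(1e-4, 1 - 1e-4, size=(8, 5))
            w = class_balance_weights(y)
            assert abs(weighted_bce(f, y, w).item()
                       - bce_oracle(f, y, w.beta_P, w.beta_N)) < 1e-6

    def test_non_binary_labels_rejected(self):
        w = class_balance_weights(np.array([[1.0]]))
        with pytest.raises(ValueError):
            weighted_bce(np.array([[0.5]]), np.array([[0.5]]), w)

    def test_gradient_flows_to_probabilities(self):
        y = np.array([[1.0]])
        w = class_balance_weights(y)
        p = Tensor(np.array([[0.3]]), requires_grad=True)
        weighted_bce(p, y, w).backward()
        assert p.grad is not None and p.grad[0, 0] < 0     # push p upward


class TestSoftMargin:
    def test_zero_scores_give_log_two(self):
        z = np.zeros((3, 4))
        y = np.eye(4)[:3]
        assert abs(multilabel_soft_margin(z, y).item() - np.log(2)) < 1e-12

    def test_large_correct_score_vanishes(self):
        loss = multilabel_soft_margin(np.array([[50.0]]), np.array([[1.0]]))
        assert loss.item() < 1e-12

    def test_equals_negative_log_sigmoid_identity(self, rng):
        for _ in range(20):
            z = rng.normal(scale=3, size=(4, 6))
            y = (rng.uniform(size=(4, 6)) < 0.5).astype(float)
            sig = 1 / (1 + np.exp(-z))
            expect = -(y * np.log(sig) + (1 - y) * np.log(1 - sig)).mean()
            assert abs(multilabel_soft_margin(z, y).item() - expect) < 1e-9


class TestEcrOhem:
    def test_consistent_identity_transform_is_zero(self, rng):
        maps = rng.normal(size=(1, 2, 4, 4))
        loss = ecr_with_ohem(maps, maps, maps, maps)
        assert loss.item() == 0.0

    def test_hand_ohem_keeps_one_pixel_of_four(self):
        # per-pixel losses (1, 0, 0, 1) in each term; ceil(0.2 * 4) = 1 kept
        y_o = np.array([[[[1.0, 0.0], [0.0, 1.0]]]])
        zeros = np.zeros_like(y_o)
        loss = ecr_with_ohem(y_o, y_o, zeros, zeros, keep_fraction=0.2)
        assert abs(loss.item() - 2.0) < 1e-12

    def test_non_negative_under_sum_convention(self, rng):
        for _ in range(20):
            stacks = [rng.normal(size=(2, 3, 4, 4)) for _ in range(4)]
            assert ecr_with_ohem(*stacks).item() >= 0.0

    def test_invariant_to_joint_permutation(self, rng):
        stacks = [rng.normal(size=(1, 3, 4, 4)) for _ in range(4)]
        base = ecr_with_ohem(*stacks).item()
        perm_c = np.random.default_rng(0).permutation(3)
        permuted = [s[:, perm_c] for s in stacks]
        assert abs(ecr_with_ohem(*permuted).item() - base) < 1e-12

    def test_masked_pixels_excluded(self):
        y_o = np.zeros((1, 1, 2, 2))
        yhat_t = np.array([[[[5.0, 0.0], [0.0, 0.0]]]])
        mask = np.array([[[[False, True], [True, True]]]])
        loss = ecr_with_ohem(y_o, y_o, y_o, yhat_t, valid_mask=mask,
                             keep_fraction=1.0)
        assert loss.item() == 0.0
        loss_unmasked = ecr_with_ohem(y_o, y_o, y_o, yhat_t, keep_fraction=1.0)
        assert loss_unmasked.item() > 0.0

    def test_bad_keep_fraction_rejected(self, rng):
        s = rng.normal(size=(1, 1, 2, 2))
        with pytest.raises(ValueError):
            ecr_with_ohem(s, s, s, s, keep_fraction=0.0)


class TestSeamTotal:
    def test_weighted_combination(self):
        assert seam_total(2.0, 4.0, SeamLossConfig()) == 7.0
        assert seam_total(0.0, 0.0) == 0.0

    def test_gradient_splits_by_lambdas(self):
        m = Tensor(np.array(1.3), requires_grad=True)
        e = Tensor(np.array(0.4), requires_grad=True)
        seam_total(m, e, SeamLossConfig()).backward()
        assert m.grad == pytest.approx(1.5) and e.grad == pytest.approx(1.0)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SeamLossConfig(ohem_keep_fraction=0.0)
        with pytest.raises(ValueError):
            SeamLossConfig(lambda_msml=-1.0)
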