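"""Loss oracle tests: brute-force per-pixel reference, closed forms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lesionseg.losses import balanced_bce, class_balance_weights, joint_loss
from lesionseg.nn.autograd import Tensor


def brute_force_bce(pred, target):
    """Independent oracle: explicit python double loop over pixels."""
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    n = pred.size
    npos = float(target.sum())
    w1, w0 = (n - npos) / n, npos / n
    total = 0.0
    for i in range(pred.shape[0]):
        for j in range(pred.shape[1]):
            h = min(max(pred[i, j], 1e-7), 1 - 1e-7)
            y = target[i, j]
            total += w1 * y * math.log(h) + w0 * (1 - y) * math.log(1 - h)
    return -total / n


def test_matches_brute_force_on_random_instances(rng):
    for _ in range(100):
        pred = rng.uniform(0.001, 0.999, size=(8, 8))
        target = (rng.uniform(size=(8, 8)) > rng.uniform(0.2, 0.8)).astype(float)
        assert balanced_bce(pred, target) == pytest.approx(
            brute_force_bce(pred, target), rel=1e-6)


@pytest.mark.parametrize("p", [round(0.1 * k, 1) for k in range(1, 10)])
def test_closed_form_for_constant_half_prediction(p):
    """For pred=0.5 everywhere and foreground fraction p the loss is
    2 p (1-p) ln 2 (both class terms contribute p(1-p) ln2)."""
    n = 100
    target = np.zeros(n)
    target[: int(p * n)] = 1.0
    loss = balanced_bce(np.full(n, 0.5).reshape(10, 10), target.reshape(10, 10))
    assert loss == pytest.approx(2 * p * (1 - p) * math.log(2), rel=1e-9)


def test_enumerated_2x2_case():
    """w1=0.75, w0=0.25; hand-expanded sum over the four pixels."""
    target = np.array([[1.0, 0.0], [0.0, 0.0]])
    pred = np.full((2, 2), 0.8)
    expect = -(0.75 * math.log(0.8) + 3 * 0.25 * math.log(0.2)) / 4
    assert balanced_bce(pred, target) == pytest.approx(expect, rel=1e-12)


def test_perfect_prediction_is_almost_zero(rng):
    target = (rng.uniform(size=(8, 8)) > 0.5).astype(float)
    assert balanced_bce(target.copy(), target) == pytest.approx(0.0, abs=1e-5)


@pytest.mark.parametrize("value", [0.0, 1.0])
def test_degenerate_targets_are_finite(value):
    """All-foreground / all-background masks: the absent class has weight 0."""
    target = np.full((4, 4), value)
    loss = balanced_bce(np.full((4, 4), 0.5), target)
    assert np.isfinite(loss) and loss >= 0


def test_weights_sum_to_one(rng):
    for _ in range(20):
        t = (rng.uniform(size=(6, 6)) > rng.uniform()).astype(int)
        w1, w0 = class_balance_weights(t)
        assert w1 + w0 == pytest.approx(1.0)
        assert w1 == pytest.approx(1 - t.mean())


def test_non_binary_target_rejected():
    with pytest.raises(ValueError, match="binary"):
        balanced_bce(np.full((2, 2), 0.5), np.full((2, 2), 0.3))


def test_monotone_in_prediction_quality(rng):
    """Moving every probability toward its target never increases the loss."""
    target = (rng.uniform(size=(8, 8)) > 0.6).astype(float)
    pred = rng.uniform(0.05, 0.95, size=(8, 8))
    losses = []
    for lam in np.linspace(0, 0.95, 8):
        moved = pred + lam * (target * (1 - 2e-7) + 1e-7 - pred)
        losses.append(balanced_bce(moved, target))
    assert all(a >= b - 1e-12 for a, b in zip(losses, losses[1:]))


def test_batched_loss_is_mean_of_per_image_losses(rng):
    preds = rng.uniform(0.01, 0.99, size=(3, 1, 5, 5))
    targets = (rng.uniform(size=(3, 1, 5, 5)) > 0.5).astype(float)
    per_image = [balanced_bce(preds[i, 0], targets[i, 0]) for i in range(3)]
    assert balanced_bce(preds, targets) == pytest.approx(np.mean(per_image), rel=1e-12)


@settings(max_examples=30, derandomize=True)
@given(st.floats(0.1, 10), st.floats(0.0, 10), st.floats(0.005, 0.5))
def test_joint_loss_arithmetic(l_seg, l_edge, alpha):
    assert joint_loss(l_seg, l_edge, alpha) == pytest.approx(alpha * l_seg + l_edge)
    assert joint_loss(l_seg, 0.0, alpha) == pytest.approx(alpha * l_seg)


def test_joint_loss_default_weighting():
    assert joint_loss(1.0, 2.0, 0.05) == pytest.approx(2.05)


def test_joint_loss_backpropagates_alpha(rng):
    pred = Tensor(rng.uniform(0.2, 0.8, size=(1, 1, 4, 4)), requires_grad=True)
    target = (rng.uniform(size=(1, 1, 4, 4)) > 0.5).astype(float)
    l_seg = balanced_bce(pred, target)
    total = joint_loss(l_seg, 0.0, alpha=0.05)
    total.backward()
    grad_scaled = pred.grad.copy()
    pred.grad = None
    balanced_bce(pred, target).backward()
    np.testing.assert_allclose(grad_scaled, 0.05 * pred.grad, rtol=1e-10)
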