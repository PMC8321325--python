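"""Finite-difference validation of the autodiff engine.

Every primitive the network uses is checked against central differences in
float64 on small random instances; this is what licenses trusting the
training loop."""

import numpy as np
import pytest

from lesionseg.nn import autograd as ag
from lesionseg.nn.autograd import Tensor


def _numeric_grad(fn, t, eps=1e-6):
    num = np.zeros_like(t.data)
    it = np.nditer(t.data, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = t.data[idx]
        t.data[idx] = orig + eps
        lp = float(fn().data)
        t.data[idx] = orig - eps
        lm = float(fn().data)
        t.data[idx] = orig
        num[idx] = (lp - lm) / (2 * eps)
    return num


def _check(make_out, tensors, tol=1e-6, eps=1e-6):
    loss_fn = lambda: ag.mean(ag.mul(make_out(), make_out()))
    loss = loss_fn()
    loss.backward()
    for t in tensors:
        num = _numeric_grad(loss_fn, t, eps=eps)
        scale = max(np.abs(num).max(), 1e-10)
        assert np.abs(num - t.grad).max() / scale < tol, "gradient mismatch"


def _t(rng, shape):
    return Tensor(rng.normal(size=shape), requires_grad=True)


@pytest.mark.parametrize("stride,padding,dilation", [(1, 1, 1), (2, 1, 1), (1, 2, 2), (2, 3, 3)])
def test_conv2d_gradients(rng, stride, padding, dilation):
    x, w, b = _t(rng, (2, 3, 7, 7)), _t(rng, (4, 3, 3, 3)), _t(rng, (4,))
    _check(lambda: ag.conv2d(x, w, b, stride=stride, padding=padding,
                             dilation=dilation), [x, w, b])


def test_conv2d_matches_scipy_correlation(rng):
    """Independent oracle: dense conv equals scipy.ndimage.correlate per channel."""
    from scipy.ndimage import correlate

    x = rng.normal(size=(1, 2, 8, 8))
    w = rng.normal(size=(3, 2, 3, 3))
    y = ag.conv2d(Tensor(x), Tensor(w), padding=1).data
    for o in range(3):
        expect = sum(
            correlate(x[0, c], w[o, c], mode="constant", cval=0.0)
            for c in range(2)
        )
        np.testing.assert_allclose(y[0, o], expect, atol=1e-10)


def test_conv2d_channel_mismatch_raises(rng):
    with pytest.raises(ValueError, match="channels"):
        ag.conv2d(Tensor(rng.normal(size=(1, 3, 4, 4))),
                  Tensor(rng.normal(size=(2, 4, 1, 1))))


@pytest.mark.parametrize("training", [True, False])
def test_batch_norm_gradients(rng, training):
    x, g, b = _t(rng, (2, 4, 5, 5)), _t(rng, (4,)), _t(rng, (4,))
    rm = rng.normal(size=4)
    rv = rng.uniform(0.5, 2.0, size=4)
    # batch norm self-normalises, so the probe loss is nearly flat in x and
    # central differences need a larger step to beat roundoff
    _check(lambda: ag.batch_norm2d(x, g, b, rm.copy(), rv.copy(),
                                   training=training), [x, g, b], tol=1e-4, eps=1e-4)


def test_batch_norm_updates_running_stats(rng):
    x = Tensor(rng.normal(loc=3.0, size=(4, 2, 6, 6)))
    g, b = Tensor(np.ones(2), requires_grad=True), Tensor(np.zeros(2), requires_grad=True)
    rm, rv = np.zeros(2), np.ones(2)
    ag.batch_norm2d(x, g, b, rm, rv, training=True, momentum=0.5)
    assert rm[0] > 1.0  # moved toward the batch mean of ~3


def test_pool_resize_concat_gradients(rng):
    x = _t(rng, (2, 3, 5, 5))
    _check(lambda: ag.max_pool2d(x, 3, 2, 1), [x])
    x2 = _t(rng, (2, 3, 5, 5))
    _check(lambda: ag.resize_bilinear(x2, 9, 9), [x2])
    x3 = _t(rng, (2, 3, 7, 7))
    _check(lambda: ag.adaptive_avg_pool2d(x3, 3), [x3])
    a, b = _t(rng, (1, 2, 4, 4)), _t(rng, (1, 2, 4, 4))
    _check(lambda: ag.concat([ag.relu(a), ag.sigmoid(b)], axis=1), [a, b])


def test_adaptive_avg_pool_global_is_mean(rng):
    x = rng.normal(size=(2, 3, 7, 7))
    out = ag.adaptive_avg_pool2d(Tensor(x), 1).data
    np.testing.assert_allclose(out[..., 0, 0], x.mean(axis=(2, 3)), atol=1e-12)


def test_bilinear_resize_preserves_constants():
    x = Tensor(np.full((1, 1, 5, 5), 3.25))
    out = ag.resize_bilinear(x, 13, 13).data
    np.testing.assert_allclose(out, 3.25, atol=1e-6)


def test_no_grad_builds_no_graph(rng):
    x = Tensor(rng.normal(size=(1, 2, 4, 4)), requires_grad=True)
    with ag.no_grad():
        y = ag.relu(x)
    assert not y.requires_grad and y._backrefs == []


def test_gradient_accumulates_over_reuse(rng):
    x = Tensor(np.array(2.0), requires_grad=True)
    y = ag.add(ag.mul(x, x), x)  # x^2 + x
    y.backward()
    assert x.grad == pytest.approx(5.0)  # 2x + 1 at x=2
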