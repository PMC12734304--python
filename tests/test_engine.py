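"""Unit tests for the NumPy engine: convolution correctness against
brute-force oracles, gradient checks, loss closed forms, optimiser contracts."""

import numpy as np
import pytest

from voxslim.engine import (BatchNorm3d, Conv3d, GlobalAvgPool3d, Linear,
                            ReduceLROnPlateau, ReLU, SGD, conv_out_size,
                            label_smoothing_loss, softmax)

from conftest import numerical_gradient


def brute_force_conv3d(x, w, bias=None, stride=1, pad=0, dilation=1, groups=1):
    """Direct (quintuple-loop) 3D cross-correlation — the independent oracle."""
    n, c_in, d, h, wd = x.shape
    c_out, cg, k, _, _ = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad), (pad, pad)))
    do = conv_out_size(d, k, stride, pad, dilation)
    ho = conv_out_size(h, k, stride, pad, dilation)
    wo = conv_out_size(wd, k, stride, pad, dilation)
    out = np.zeros((n, c_out, do, ho, wo))
    cog = c_out // groups
    for ni in range(n):
        for co in range(c_out):
            gi = co // cog
            for zi in range(do):
                for yi in range(ho):
                    for xi in range(wo):
                        acc = 0.0
                        for ci in range(cg):
                            cin_abs = gi * cg + ci
                            for a in range(k):
                                for b in range(k):
                                    for cc in range(k):
                                        acc += (xp[ni, cin_abs,
                                                   zi * stride + a * dilation,
                                                   yi * stride + b * dilation,
                                                   xi * stride + cc * dilation]
                                                * w[co, ci, a, b, cc])
                        out[ni, co, zi, yi, xi] = acc
            if bias is not None:
                out[ni, co] += bias[co]
    return out


@pytest.mark.parametrize("c_in,c_out,k,stride,pad,dilation,groups", [
    (2, 3, 3, 1, 1, 1, 1),
    (2, 4, 3, 2, 1, 1, 2),
    (3, 3, 3, 1, 2, 2, 3),   # dilated depthwise
    (1, 2, 1, 1, 0, 1, 1),   # pointwise
    (3, 3, 3, 2, 2, 2, 3),   # strided dilated depthwise
])
def test_conv3d_matches_brute_force(rng, c_in, c_out, k, stride, pad, dilation, groups):
    x = rng.normal(size=(2, c_in, 6, 7, 7)).astype(np.float32)
    conv = Conv3d(c_in, c_out, k, stride=stride, padding=pad, dilation=dilation,
                  groups=groups, bias=True, rng=rng)
    got = conv.forward(x)
    want = brute_force_conv3d(x, conv.weight.data, conv.bias.data,
                              stride=stride, pad=pad, dilation=dilation, groups=groups)
    np.testing.assert_allclose(got, want, rtol=1e-4, atol=1e-5)


def test_dilated_r1_equals_standard_conv(rng):
    """A dilation rate of 1 reduces the dilated convolution to the plain one."""
    x = rng.normal(size=(1, 2, 6, 6, 6)).astype(np.float32)
    base = Conv3d(2, 3, 3, padding=1, dilation=1, rng=rng)
    dil = Conv3d(2, 3, 3, padding=1, dilation=1, rng=rng)
    dil.weight.data = base.weight.data.copy()
    np.testing.assert_array_equal(base.forward(x), dil.forward(x))


def test_dilated_taps_span_dilated_lattice(rng):
    """r=2 with a 3^3 kernel reaches a 5^5^5 neighbourhood, only on the lattice."""
    conv = Conv3d(1, 1, 3, padding=0, dilation=2, rng=rng)
    conv.weight.data = np.ones_like(conv.weight.data)
    for pos in [(0, 0, 0), (2, 2, 2), (4, 4, 4), (0, 2, 4)]:
        x = np.zeros((1, 1, 5, 5, 5), dtype=np.float32)
        x[(0, 0, *pos)] = 1.0
        on_lattice = all(p % 2 == 0 for p in pos)
        out = conv.forward(x)
        assert out.shape == (1, 1, 1, 1, 1)
        assert (out[0, 0, 0, 0, 0] != 0) == on_lattice
    x = np.zeros((1, 1, 5, 5, 5), dtype=np.float32)
    x[0, 0, 1, 1, 1] = 1.0  # off-lattice voxel
    assert conv.forward(x)[0, 0, 0, 0, 0] == 0.0


def test_unit_kernel_any_dilation_is_identity(rng):
    x = rng.normal(size=(1, 2, 4, 4, 4)).astype(np.float32)
    for r in (1, 2, 3):
        conv = Conv3d(2, 2, 1, padding=0, dilation=r, groups=2, rng=rng)
        conv.weight.data = np.ones_like(conv.weight.data)
        np.testing.assert_array_equal(conv.forward(x), x)


class TestDepthwiseSeparable:
    def test_all_ones_sums_receptive_field(self):
        """Ones kernel over a ones 3^3 input with unit pointwise weight gives 27."""
        dw = Conv3d(1, 1, 3, padding=0, groups=1, rng=np.random.default_rng(0))
        dw.weight.data = np.ones_like(dw.weight.data)
        pw = Conv3d(1, 1, 1, padding=0, rng=np.random.default_rng(0))
        pw.weight.data = np.ones_like(pw.weight.data)
        x = np.ones((1, 1, 3, 3, 3), dtype=np.float32)
        out = pw.forward(dw.forward(x))
        assert out.shape == (1, 1, 1, 1, 1)
        assert out[0, 0, 0, 0, 0] == pytest.approx(27.0)

    def test_delta_depthwise_identity_pointwise(self, rng):
        """Centred-delta depthwise kernels + identity pointwise reproduce the input."""
        c = 3
        dw = Conv3d(c, c, 3, padding=1, groups=c, rng=rng)
        dw.weight.data[...] = 0.0
        dw.weight.data[:, 0, 1, 1, 1] = 1.0
        pw = Conv3d(c, c, 1, padding=0, rng=rng)
        pw.weight.data = np.eye(c, dtype=np.float32).reshape(c, c, 1, 1, 1)
        x = rng.normal(size=(2, c, 4, 5, 5)).astype(np.float32)
        np.testing.assert_allclose(pw.forward(dw.forward(x)), x, atol=1e-6)

    def test_zero_pointwise_annihilates(self, rng):
        c = 2
        dw = Conv3d(c, c, 3, padding=1, groups=c, rng=rng)
        pw = Conv3d(c, 4, 1, padding=0, bias=True, rng=rng)
        pw.weight.data[...] = 0.0
        pw.bias.data[...] = 0.5
        x = rng.normal(size=(1, c, 3, 3, 3)).astype(np.float32)
        np.testing.assert_allclose(pw.forward(dw.forward(x)), 0.5, atol=1e-7)

    def test_equals_composed_full_convolution(self, rng):
        """Depthwise then pointwise equals one full conv whose kernel is the
        rank-structured composition w_full[o, c] = v[o, c] * w_dw[c]."""
        c_in, c_out = 3, 4
        dw = Conv3d(c_in, c_in, 3, padding=1, groups=c_in, rng=rng)
        pw = Conv3d(c_in, c_out, 1, padding=0, rng=rng)
        w_full = (pw.weight.data[:, :, 0, 0, 0][:, :, None, None, None]
                  * dw.weight.data[None, :, 0])
        x = rng.normal(size=(2, c_in, 5, 5, 5)).astype(np.float32)
        got = pw.forward(dw.forward(x))
        want = brute_force_conv3d(x, w_full, stride=1, pad=1)
        np.testing.assert_allclose(got, want, rtol=1e-4, atol=1e-5)


def test_conv_channel_mismatch_message(rng):
    conv = Conv3d(3, 4, 3, rng=rng)
    with pytest.raises(ValueError, match="expected 3.*found 2"):
        conv.forward(np.zeros((1, 2, 4, 4, 4), dtype=np.float32))


@pytest.mark.parametrize("make,shape,training", [
    (lambda r: Conv3d(2, 3, 3, stride=2, padding=1, rng=r), (2, 2, 5, 6, 6), False),
    (lambda r: Conv3d(3, 3, 3, groups=3, padding="same", dilation=2, rng=r),
     (2, 3, 7, 7, 7), False),
    (lambda r: BatchNorm3d(3), (2, 3, 4, 4, 4), True),
    (lambda r: Linear(5, 3, rng=r), (4, 5), False),
])
def test_backward_matches_numerical_gradient(rng, make, shape, training):
    layer = make(rng)
    x = rng.normal(size=shape).astype(np.float32)
    w = rng.normal(size=layer.forward(x, training=training).shape).astype(np.float32)

    def loss():
        return float((layer.forward(x, training=training) * w).sum())

    layer.zero_grad()
    layer.forward(x, training=training)
    dx = layer.backward(w.copy())
    ng = numerical_gradient(loss, x)
    assert np.abs(dx - ng).max() / (np.abs(ng).max() + 1e-8) < 2e-2
    for _, p in layer.named_params():
        ng = numerical_gradient(loss, p.data)
        assert np.abs(p.grad - ng).max() / (np.abs(ng).max() + 1e-8) < 2e-2


class TestLabelSmoothingLoss:
    def test_zero_epsilon_is_plain_cross_entropy(self, rng):
        scores = rng.normal(size=(6, 3)).astype(np.float32)
        labels = np.array([0, 1, 2, 0, 1, 2])
        loss, _ = label_smoothing_loss(scores, labels, epsilon=0.0)
        p = softmax(scores.astype(np.float64), axis=1)
        want = -np.log(p[np.arange(6), labels]).mean()
        assert loss == pytest.approx(want, rel=1e-6)

    def test_uniform_scores_give_log_k(self):
        scores = np.zeros((3, 2), dtype=np.float32)
        for eps in (0.0, 0.1, 0.5):
            loss, _ = label_smoothing_loss(scores, np.array([0, 1, 0]), eps)
            assert loss == pytest.approx(np.log(2), rel=1e-6)

    def test_closed_form_two_class(self):
        """eps=0.1, K=2, p(true)=0.9 -> -(0.95 ln 0.9 + 0.05 ln 0.1)."""
        p = 0.9
        scores = np.array([[np.log(p), np.log(1 - p)]], dtype=np.float32)
        loss, _ = label_smoothing_loss(scores, np.array([0]), epsilon=0.1)
        want = -(0.95 * np.log(0.9) + 0.05 * np.log(0.1))
        assert loss == pytest.approx(want, rel=1e-5)

    def test_invalid_epsilon_rejected(self):
        with pytest.raises(ValueError):
            label_smoothing_loss(np.zeros((1, 2)), np.array([0]), epsilon=1.0)


def test_sgd_zero_lr_is_null_update(rng):
    lin = Linear(4, 2, rng=rng)
    before = lin.weight.data.copy()
    opt = SGD(lin.params(), lr=0.0, momentum=0.9, weight_decay=1e-4)
    lin.weight.grad[...] = rng.normal(size=lin.weight.grad.shape)
    opt.step()
    np.testing.assert_array_equal(lin.weight.data, before)


def test_plateau_scheduler_decays_after_patience(rng):
    lin = Linear(2, 2, rng=rng)
    opt = SGD(lin.params(), lr=1.0)
    sched = ReduceLROnPlateau(opt, factor=0.1, patience=2, threshold=1e-4)
    sched.step(1.0)           # establishes best
    assert opt.lr == 1.0
    for _ in range(2):
        sched.step(1.0)       # non-improving, within patience
    assert opt.lr == 1.0
    sched.step(1.0)           # exceeds patience
    assert opt.lr == pytest.approx(0.1)
    sched.step(0.5)           # improvement resets the counter
    sched.step(0.5)
    assert opt.lr == pytest.approx(0.1)
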