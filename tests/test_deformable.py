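"""Deformable-convolution oracles: zero-offset reduction, shift equivalence,
brute-force triple-loop agreement, and gradient checks."""

import numpy as np
import pytest

from rdsunet.deformable import (KernelGrid, bilinear_sample,
                                deform_conv_backward, deform_conv_forward,
                                deformable_conv, standard_conv_ref,
                                validate_offset_field)
from rdsunet.errors import ShapeError

from conftest import numeric_grad

RNG = np.random.default_rng(3)


def _bilinear_scalar(x, r, c):
    """Independent scalar bilinear interpolation (zero outside the grid)."""
    h, w = x.shape
    r0, c0 = int(np.floor(r)), int(np.floor(c))
    fr, fc = r - r0, c - c0
    val = 0.0
    for dr, wr in ((0, 1 - fr), (1, fr)):
        for dc, wc in ((0, 1 - fc), (1, fc)):
            rr, cc = r0 + dr, c0 + dc
            if 0 <= rr < h and 0 <= cc < w:
                val += x[rr, cc] * wr * wc
    return val


def _deform_loop(x, grid, offsets):
    """Scalar triple-loop deformable-sampling oracle."""
    cin, h, w = x.shape
    cout = grid.weights.shape[0]
    taps = grid.taps
    out = np.zeros((cout, h, w))
    for o in range(cout):
        for r in range(h):
            for c in range(w):
                acc = 0.0
                for n, (dy, dx) in enumerate(taps):
                    oy = offsets[r, c, 2 * n]
                    ox = offsets[r, c, 2 * n + 1]
                    for ci in range(cin):
                        acc += grid.weights[o, ci, n // 3, n % 3] * \
                            _bilinear_scalar(x[ci], r + dy + oy, c + dx + ox)
                out[o, r, c] = acc
    return out


# ---------------------------------------------------------------------------
# standard_conv_ref (plain-convolution reference)
# ---------------------------------------------------------------------------

def test_identity_kernel_returns_input():
    w = np.zeros((3, 3))
    w[1, 1] = 1.0
    x = RNG.normal(size=(5, 5))
    np.testing.assert_allclose(standard_conv_ref(x, KernelGrid(w))[0], x)


def test_ones_kernel_on_impulse_gives_block():
    x = np.zeros((5, 5))
    x[2, 2] = 1.0
    out = standard_conv_ref(x, KernelGrid(np.ones((3, 3))))[0]
    expected = np.zeros((5, 5))
    expected[1:4, 1:4] = 1.0
    np.testing.assert_allclose(out, expected)


def test_standard_conv_matches_double_loop():
    x = RNG.normal(size=(5, 5))
    w = RNG.normal(size=(3, 3))
    out = standard_conv_ref(x, KernelGrid(w))[0]
    ref = np.zeros((5, 5))
    for r in range(5):
        for c in range(5):
            for i in range(3):
                for j in range(3):
                    rr, cc = r + i - 1, c + j - 1
                    if 0 <= rr < 5 and 0 <= cc < 5:
                        ref[r, c] += w[i, j] * x[rr, cc]
    np.testing.assert_allclose(out, ref, atol=1e-6)


# ---------------------------------------------------------------------------
# bilinear_sample
# ---------------------------------------------------------------------------

def test_bilinear_integer_coordinate_exact():
    x = RNG.normal(size=(4, 4))
    assert bilinear_sample(x, (2.0, 3.0)) == pytest.approx(x[2, 3])


def test_bilinear_midpoint():
    x = np.array([[2.0, 4.0]])
    assert bilinear_sample(x, (0.0, 0.5)) == pytest.approx(3.0)


def test_bilinear_outside_support_is_zero():
    x = RNG.normal(size=(4, 4))
    assert bilinear_sample(x, (-5.7, -5.7)) == 0.0


def test_bilinear_nonfinite_coordinate_raises():
    with pytest.raises(ValueError):
        bilinear_sample(np.zeros((3, 3)), (np.nan, 0.0))


def test_bilinear_matches_scalar_oracle_at_random_points():
    x = RNG.normal(size=(6, 7))
    pts = RNG.uniform(-2, 8, size=(50, 2))
    got = bilinear_sample(x, pts)
    ref = np.array([_bilinear_scalar(x, r, c) for r, c in pts])
    np.testing.assert_allclose(got, ref, atol=1e-10)


# ---------------------------------------------------------------------------
# deformable_conv (offset-sampled convolution)
# ---------------------------------------------------------------------------

def test_zero_offsets_reduce_to_standard_conv_exactly():
    # single-tap kernels have one-term sums, so the reduction is bit-exact
    # (bilinear weights are exactly {0, 1} at integer coordinates)
    x = RNG.normal(size=(1, 6, 6))
    off = np.zeros((6, 6, 18))
    for n in range(9):
        w = np.zeros((1, 1, 3, 3))
        w[0, 0, n // 3, n % 3] = RNG.normal()
        grid = KernelGrid(w)
        np.testing.assert_array_equal(deformable_conv(x, grid, off),
                                      standard_conv_ref(x, grid))


def test_zero_offsets_full_kernel_matches_to_summation_order():
    # full kernels agree to reassociation rounding only (~1e-15 relative):
    # the two references sum the 18 products in different orders
    x = RNG.normal(size=(2, 6, 6))
    grid = KernelGrid(RNG.normal(size=(3, 2, 3, 3)))
    off = np.zeros((6, 6, 18))
    got = deformable_conv(x, grid, off)
    ref = standard_conv_ref(x, grid)
    np.testing.assert_allclose(got, ref, rtol=1e-12, atol=1e-13)


def test_uniform_column_shift_equals_shifted_input_conv():
    x = RNG.normal(size=(1, 6, 6))
    grid = KernelGrid(RNG.normal(size=(1, 1, 3, 3)))
    off = np.zeros((6, 6, 18))
    off[:, :, 1::2] = 1.0          # every tap shifted one column right
    got = deformable_conv(x, grid, off)
    shifted = np.zeros_like(x)
    shifted[:, :, :-1] = x[:, :, 1:]
    ref = standard_conv_ref(shifted, grid)
    # column 0 differs by construction: pre-shifting discards the original
    # first column, which the deformable op still samples from the true grid
    np.testing.assert_allclose(got[:, :, 1:], ref[:, :, 1:], atol=1e-10)
    np.testing.assert_allclose(
        got[:, :, 0],
        ref[:, :, 0] + grid.weights[:, 0, :, 0] @ np.vstack(
            [np.r_[0.0, x[0, :-1, 0]], x[0, :, 0], np.r_[x[0, 1:, 0], 0.0]]),
        atol=1e-10)


def test_random_offsets_match_triple_loop_oracle():
    x = RNG.normal(size=(1, 6, 6))
    grid = KernelGrid(RNG.normal(size=(2, 1, 3, 3)))
    off = RNG.uniform(-1.5, 1.5, size=(6, 6, 18))
    got = deformable_conv(x, grid, off)
    ref = _deform_loop(x, grid, off)
    np.testing.assert_allclose(got, ref, atol=1e-5)


def test_multichannel_matches_triple_loop_oracle():
    x = RNG.normal(size=(3, 4, 4))
    grid = KernelGrid(RNG.normal(size=(2, 3, 3, 3)))
    off = RNG.uniform(-1.0, 1.0, size=(4, 4, 18))
    np.testing.assert_allclose(deformable_conv(x, grid, off),
                               _deform_loop(x, grid, off), atol=1e-5)


def test_linearity_in_input():
    grid = KernelGrid(RNG.normal(size=(2, 2, 3, 3)))
    off = RNG.uniform(-1, 1, size=(5, 5, 18))
    xa = RNG.normal(size=(2, 5, 5))
    xb = RNG.normal(size=(2, 5, 5))
    lhs = deformable_conv(2.0 * xa + 3.0 * xb, grid, off)
    rhs = 2.0 * deformable_conv(xa, grid, off) + \
        3.0 * deformable_conv(xb, grid, off)
    np.testing.assert_allclose(lhs, rhs, atol=1e-8)


def test_offset_field_wrong_channels_raises():
    with pytest.raises(ShapeError):
        validate_offset_field(np.zeros((4, 4, 10)), 9)


# ---------------------------------------------------------------------------
# batched core gradients (finite differences)
# ---------------------------------------------------------------------------

def test_deform_conv_gradients_match_finite_differences():
    x = RNG.normal(size=(1, 2, 4, 4)).astype(np.float64)
    w = RNG.normal(size=(2, 2, 3, 3)).astype(np.float64)
    off = RNG.uniform(-0.8, 0.8, size=(1, 18, 4, 4)).astype(np.float64)
    bias = RNG.normal(size=(2,)).astype(np.float64)
    gy = RNG.normal(size=(1, 2, 4, 4)).astype(np.float64)

    def loss():
        y, _ = deform_conv_forward(x, w, off, bias)
        return float((y * gy).sum())

    y, cache = deform_conv_forward(x, w, off, bias, want_cache=True)
    dx, dw, doff, dbias = deform_conv_backward(gy, w, cache)
    for arr, grad in ((x, dx), (w, dw), (off, doff), (bias, dbias)):
        num = numeric_grad(loss, arr, eps=1e-5)
        np.testing.assert_allclose(grad, num, atol=5e-4,
                                   err_msg=f"shape {arr.shape}")


def test_offset_branch_zero_init_and_channel_count():
    from rdsunet.nn.modules import DeformableConv2d
    from rdsunet.nn.tensor import Tensor
    layer = DeformableConv2d(4, 5, rng=np.random.default_rng(0))
    assert layer.offset_conv.weight.shape[0] == 18       # 2N for 3x3
    assert np.all(layer.offset_conv.weight.data == 0.0)
    # zero offsets at init: layer == plain conv with the same main weights
    x = Tensor(RNG.normal(size=(1, 4, 6, 6)).astype(np.float32))
    from rdsunet.nn.tensor import conv2d
    got = layer(x).data
    ref = conv2d(x, layer.weight, layer.bias, stride=1, padding=1).data
    np.testing.assert_allclose(got, ref, atol=1e-5)


def test_offset_branch_receives_gradient():
    from rdsunet.nn.modules import DeformableConv2d
    from rdsunet.nn.tensor import Tensor
    layer = DeformableConv2d(3, 2, rng=np.random.default_rng(1))
    # move offsets off the zero fixed point so the gate has slope
    layer.offset_conv.weight.data[:] = np.random.default_rng(2).normal(
        scale=0.1, size=layer.offset_conv.weight.shape).astype(np.float32)
    x = Tensor(RNG.normal(size=(1, 3, 5, 5)).astype(np.float32))
    (layer(x) ** 2.0).sum().backward()
    assert layer.offset_conv.weight.grad is not None
    assert np.abs(layer.offset_conv.weight.grad).max() > 0.0
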