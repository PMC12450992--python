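"""Variance-adaptive windowed attention: variance maps, window assignment,
focus regions, masked windowed attention and the residual block."""

import numpy as np
import pytest

from retinagrade import nn
from retinagrade.dwam_attention import (DwamBlock, DwamConfig,
                                        WindowProjections, assign_windows,
                                        derive_focus_regions, focus_region,
                                        local_variance, windowed_attention)
from retinagrade.nn import Tensor


# -- local variance ------------------------------------------------------------

def test_constant_input_has_zero_variance():
    x = np.full((1, 3, 8, 8), 7.5)
    v = local_variance(x, 4)
    assert v.shape == (1, 2, 2)
    np.testing.assert_array_equal(v, 0.0)


def test_variance_closed_form_small_cell():
    # single channel, one 2x2 cell holding {0, 0, 1, 1}: population var 0.25
    x = np.array([[[[0.0, 0.0], [1.0, 1.0]]]])
    v = local_variance(x, 2)
    assert v.shape == (1, 1, 1)
    assert v[0, 0, 0] == pytest.approx(0.25)


def test_variance_matches_two_pass_oracle(rng):
    x = rng.standard_normal((1, 4, 8, 8))
    v = local_variance(x, 4)
    for i in range(2):
        for j in range(2):
            cell = x[0, :, 4 * i:4 * i + 4, 4 * j:4 * j + 4].ravel()
            mean = cell.sum() / cell.size
            expected = ((cell - mean) ** 2).sum() / cell.size
            assert v[0, i, j] == pytest.approx(expected, rel=1e-10)


def test_variance_is_shift_invariant(rng):
    x = rng.standard_normal((2, 3, 8, 8))
    np.testing.assert_allclose(local_variance(x, 4),
                               local_variance(x + 123.4, 4), atol=1e-8)


def test_variance_rejects_nonpositive_grid():
    with pytest.raises(ValueError):
        local_variance(np.zeros((1, 1, 8, 8)), 0)


# -- window assignment ---------------------------------------------------------

def test_all_equal_variance_assigns_largest_window():
    cfg = DwamConfig()
    sizes = assign_windows(np.zeros((4, 4)), cfg)
    np.testing.assert_array_equal(sizes, 15)


def test_assignment_monotone_in_variance():
    cfg = DwamConfig()
    v = np.array([[0.0, 0.1], [0.5, 0.9]])
    sizes = assign_windows(v, cfg)
    flat_v, flat_s = v.ravel(), sizes.ravel()
    for i in range(4):
        for j in range(4):
            if flat_v[i] > flat_v[j]:
                assert flat_s[i] <= flat_s[j]


def test_assignment_matches_quantile_threshold_oracle(rng):
    cfg = DwamConfig()
    v = rng.uniform(size=(4, 4))
    sizes = assign_windows(v, cfg)
    t_lo, t_hi = np.quantile(v, [1 / 3, 2 / 3])
    for val, s in zip(v.ravel(), sizes.ravel()):
        if val >= t_hi:
            assert s == 3          # ties fall toward the smaller window
        elif val >= t_lo:
            assert s == 8
        else:
            assert s == 15


def test_assignment_property_monotone_random(rng):
    cfg = DwamConfig(allowed_sizes=(2, 4, 8), variance_grid=8)
    for _ in range(20):
        v = rng.gamma(1.0, size=(5, 5))
        s = assign_windows(v, cfg)
        order = np.argsort(v.ravel())
        assert (np.diff(s.ravel()[order]) <= 0).all()


# -- focus regions -------------------------------------------------------------

def test_focus_full_fraction_covers_whole_map(rng):
    v = rng.uniform(size=(3, 5))
    assert derive_focus_regions(v, 1.0) == [(0, 0, 3, 5)]


def test_focus_single_peak_cell():
    v = np.zeros((4, 4))
    v[2, 1] = 5.0
    assert derive_focus_regions(v, 0.05) == [(2, 1, 3, 2)]


def test_focus_matches_sort_and_slice_oracle(rng):
    v = rng.uniform(size=(4, 4))
    regions = derive_focus_regions(v, 0.25)
    thr = np.quantile(v, 0.75)
    covered = np.zeros_like(v, dtype=bool)
    for r0, c0, r1, c1 in regions:
        covered[r0:r1, c0:c1] = True
    assert covered[v >= thr].all()   # every top-quantile cell is inside a rect


def test_focus_rejects_empty_map():
    with pytest.raises(ValueError):
        derive_focus_regions(np.zeros((0, 0)), 0.5)


def test_focus_region_identity_and_indexing(rng):
    x = Tensor(np.arange(2 * 3 * 4 * 4, dtype=float).reshape(2, 3, 4, 4))
    (full,) = focus_region(x, [(0, 0, 4, 4)])
    np.testing.assert_array_equal(full.data, x.data)
    patches = focus_region(x, [(0, 0, 2, 2), (2, 2, 4, 4)])
    assert patches[0].shape == (2, 3, 2, 2)
    np.testing.assert_array_equal(patches[0].data, x.data[:, :, 0:2, 0:2])
    with pytest.raises(IndexError, match="region"):
        focus_region(x, [(0, 0, 5, 2)])


# -- windowed attention --------------------------------------------------------

def _identityish_proj(channels, heads, rng):
    return WindowProjections(channels, heads, rng)


def test_uniform_keys_average_values(rng):
    # all key vectors equal -> uniform softmax -> each output is the value mean
    q = Tensor(rng.standard_normal((1, 1, 4, 2)))
    k = Tensor(np.ones((1, 1, 4, 2)))
    v = Tensor(rng.standard_normal((1, 1, 4, 2)))
    out, attn = nn.scaled_dot_attention(q, k, v)
    np.testing.assert_allclose(out.data[0, 0],
                               np.tile(v.data[0, 0].mean(axis=0), (4, 1)),
                               atol=1e-10)
    np.testing.assert_allclose(attn.data.sum(axis=-1), 1.0, atol=1e-10)


def test_single_token_window_passes_value_through(rng):
    q = Tensor(rng.standard_normal((1, 1, 1, 3)))
    k = Tensor(rng.standard_normal((1, 1, 1, 3)))
    v = Tensor(rng.standard_normal((1, 1, 1, 3)))
    out, _ = nn.scaled_dot_attention(q, k, v)
    np.testing.assert_allclose(out.data, v.data, atol=1e-12)


def test_two_token_softmax_hand_oracle():
    # d_k = 1, q = 1, k = (1, 2), v = (0, 1):
    # out = softmax([1, 2]) . [0, 1] = e^2/(e^1+e^2) = sigmoid(1)
    q = Tensor(np.array([[[[1.0]]]]))
    k = Tensor(np.array([[[[1.0], [2.0]]]]))
    v = Tensor(np.array([[[[0.0], [1.0]]]]))
    out, _ = nn.scaled_dot_attention(q, k, v)
    assert out.data[0, 0, 0, 0] == pytest.approx(1 / (1 + np.exp(-1.0)), abs=1e-6)


def test_windowed_attention_shape_and_row_norm(rng, toy_dwam_config):
    cfg = toy_dwam_config
    proj = _identityish_proj(8, 4, rng)
    x = Tensor(rng.standard_normal((2, 8, 8, 8)).astype(np.float32))
    sizes = np.full((2, 1, 1), 4)
    out = windowed_attention(x, sizes, cfg, proj)
    assert out.shape == x.shape


def test_heads_must_divide_channels(rng):
    with pytest.raises(ValueError, match="num_heads"):
        WindowProjections(10, 3, rng)


def test_locality_no_information_flow_between_windows(rng):
    """Perturbing one token only changes outputs inside its own window."""
    cfg = DwamConfig(allowed_sizes=(4,), variance_grid=4, num_heads=2,
                     quantile_edges=())
    proj = _identityish_proj(4, 2, rng)
    x = rng.standard_normal((1, 4, 8, 8)).astype(np.float32)
    sizes = np.full((1, 2, 2), 4)
    base = windowed_attention(Tensor(x), sizes, cfg, proj).data
    x2 = x.copy()
    x2[0, :, 0, 0] += 3.0      # inside the top-left 4x4 window
    pert = windowed_attention(Tensor(x2), sizes, cfg, proj).data
    delta = np.abs(pert - base).max(axis=1)[0]   # (H, W)
    assert delta[:4, :4].max() > 1e-6
    assert delta[:4, 4:].max() < 1e-6
    assert delta[4:, :].max() < 1e-6


# -- the block -----------------------------------------------------------------

def test_zero_init_projection_gives_exact_identity(rng, toy_dwam_config):
    cfg = DwamConfig(allowed_sizes=(2, 4, 8), variance_grid=8, num_heads=4,
                     zero_init_output_projection=True)
    block = DwamBlock(8, cfg, rng)
    x = Tensor(rng.standard_normal((2, 8, 16, 16)).astype(np.float32))
    out = block(x)
    np.testing.assert_array_equal(out.data, x.data)


def test_block_output_shape_matches_input(rng, toy_dwam_config):
    block = DwamBlock(8, toy_dwam_config, rng)
    for shape in [(1, 8, 8, 8), (2, 8, 16, 16), (1, 8, 12, 20)]:
        x = Tensor(rng.standard_normal(shape).astype(np.float32))
        assert block(x).shape == shape


def _fixed_window_oracle(x, window, proj):
    """Single-window multi-head attention, straight-line numpy (no autodiff)."""
    B, C, H, W = x.shape
    h, dk = proj.num_heads, proj.head_dim
    Wqkv, bqkv = proj.qkv.weight.data, proj.qkv.bias.data
    Wout, bout = proj.out.weight.data, proj.out.bias.data
    out = np.zeros_like(x)
    for b in range(B):
        for r0 in range(0, H, window):
            for c0 in range(0, W, window):
                patch = x[b, :, r0:r0 + window, c0:c0 + window]
                hh, ww = patch.shape[1], patch.shape[2]
                tokens = patch.reshape(C, hh * ww).T            # (T, C)
                qkv = tokens @ Wqkv + bqkv                       # (T, 3C)
                qkv = qkv.reshape(-1, 3, h, dk)
                q, k, v = qkv[:, 0], qkv[:, 1], qkv[:, 2]        # (T, h, dk)
                res = np.zeros_like(tokens)
                for head in range(h):
                    s = (q[:, head] @ k[:, head].T) / np.sqrt(dk)
                    s = s - s.max(axis=1, keepdims=True)
                    a = np.exp(s)
                    a /= a.sum(axis=1, keepdims=True)
                    res[:, head * dk:(head + 1) * dk] = a @ v[:, head]
                res = res @ Wout + bout
                out[b, :, r0:r0 + window, c0:c0 + window] = \
                    res.T.reshape(C, hh, ww)
    return out + x


def test_constant_input_equals_fixed_window_oracle(rng):
    """Uniform variance degenerates to max-window attention everywhere."""
    cfg = DwamConfig(allowed_sizes=(2, 4, 8), variance_grid=8, num_heads=4)
    block = DwamBlock(32, cfg, rng, adaptive_windows=True, focus=False)
    x = np.full((2, 32, 8, 8), 0.25, dtype=np.float32)
    out = block(Tensor(x)).data
    oracle = _fixed_window_oracle(x.astype(np.float64), 8, block.proj)
    assert np.abs(out - oracle).max() <= 1e-5
    np.testing.assert_array_equal(block.last.sizes, 8)


def test_uniform_assignment_equals_oracle_on_random_input(rng):
    """When every cell is forced to one window size, the heterogeneous path
    reduces to plain fixed-window attention."""
    cfg = DwamConfig(allowed_sizes=(4,), variance_grid=4, num_heads=2,
                     quantile_edges=())
    proj = WindowProjections(8, 2, rng)
    x = rng.standard_normal((2, 8, 8, 8)).astype(np.float32)
    sizes = np.full((2, 2, 2), 4)
    ours = windowed_attention(Tensor(x), sizes, cfg, proj).data
    oracle = _fixed_window_oracle(x.astype(np.float64), 4, proj) - x
    assert np.abs(ours - oracle).max() <= 1e-5
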