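"""Variance-adaptive windowed self-attention.

The mechanism assigns each coarse grid cell of a feature map an attention
window size drawn from a discrete allowed set (default {3, 8, 15}, matching
the microaneurysm / hemorrhage / exudate scale bands): high local feature
variance — detail-rich, lesion-prone regions — gets the smallest window,
smooth regions the largest.  Window size is therefore a monotone
non-increasing function of local variance, realised as a quantile binning
rather than a literal reciprocal, which keeps the geometry discrete and
valid.  Within each window, standard multi-head scaled-dot-product
attention runs over the window's tokens; a zero-initialisable output
projection plus an identity shortcut makes the whole block residual-safe.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from . import nn
from .nn import Tensor

__all__ = [
    "DwamConfig", "DwamBlock",
    "local_variance", "assign_windows", "derive_focus_regions",
    "focus_region", "windowed_attention",
]


@dataclass
class DwamConfig:
    """Configuration of the adaptive-window attention block.

    allowed_sizes
        Ordered set of window edge lengths, smallest to largest.
    variance_grid
        Cell size g of the coarse variance grid; defaults to max(allowed_sizes)
        so every cell can host any allowed window.
    quantile_edges
        len(allowed_sizes) - 1 ascending probabilities partitioning the
        variance distribution into one band per window size.
    """

    allowed_sizes: tuple[int, ...] = (3, 8, 15)
    variance_grid: int | None = None
    num_heads: int = 4
    epsilon: float = 1e-8
    quantile_edges: tuple[float, ...] = (1 / 3, 2 / 3)
    zero_init_output_projection: bool = False
    focus_top_fraction: float = 0.25

    def __post_init__(self):
        self.allowed_sizes = tuple(sorted(int(s) for s in self.allowed_sizes))
        if any(s < 1 for s in self.allowed_sizes):
            raise ValueError("window sizes must be >= 1")
        if self.variance_grid is None:
            self.variance_grid = max(self.allowed_sizes)
        if self.variance_grid <= 0:
            raise ValueError("variance_grid must be positive")
        if len(self.quantile_edges) != len(self.allowed_sizes) - 1:
            raise ValueError(
                f"need {len(self.allowed_sizes) - 1} quantile edges for "
                f"{len(self.allowed_sizes)} window sizes, got {len(self.quantile_edges)}")
        if not 0 < self.focus_top_fraction <= 1:
            raise ValueError("focus_top_fraction must be in (0, 1]")


def _as_array(x) -> np.ndarray:
    return x.data if isinstance(x, Tensor) else np.asarray(x, dtype=float)


def _pad_reflect_to_multiple(a: np.ndarray, g: int) -> np.ndarray:
    _, _, H, W = a.shape
    ph = (-H) % g
    pw = (-W) % g
    if ph or pw:
        a = np.pad(a, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="reflect")
    return a


def local_variance(x, g: int) -> np.ndarray:
    """Per-cell population variance of all C*g*g activations.

    ``x`` is (B, C, H, W) (Tensor or array); returns (B, H'/g, W'/g) where
    H', W' are reflect-padded up to multiples of g.  Adding a constant to x
    leaves the map unchanged; a constant cell has variance exactly 0.
    """
    if g <= 0:
        raise ValueError(f"grid size must be positive, got {g}")
    a = _as_array(x)
    if a.ndim != 4:
        raise ValueError(f"expected (B, C, H, W), got shape {a.shape}")
    a = _pad_reflect_to_multiple(a, g)
    B, C, H, W = a.shape
    cells = a.reshape(B, C, H // g, g, W // g, g)
    return cells.var(axis=(1, 3, 5), ddof=0)


def assign_windows(v: np.ndarray, cfg: DwamConfig) -> np.ndarray:
    """Map variance to window size: quantile-banded, inverse-monotone.

    Cells at or above the upper edge get the smallest window, cells below the
    lowest edge the largest; ties break toward the smaller window (favouring
    detail).  An all-equal map degenerates to max(allowed_sizes) everywhere.
    Accepts a single (nH, nW) map or a batch (B, nH, nW); each map is ranked
    independently.
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("variance map must be finite")
    batched = v.ndim == 3
    maps = v if batched else v[None]
    sizes_desc = np.array(sorted(cfg.allowed_sizes, reverse=True))
    out = np.empty(maps.shape, dtype=int)
    for i, m in enumerate(maps):
        if np.ptp(m) <= cfg.epsilon:
            out[i] = sizes_desc[0]
            continue
        thresholds = np.quantile(m, cfg.quantile_edges)
        band = (m[..., None] >= thresholds).sum(axis=-1)
        out[i] = sizes_desc[band]
    return out if batched else out[0]


def derive_focus_regions(v: np.ndarray, top_fraction: float) -> list[tuple[int, int, int, int]]:
    """Rectangles (in cell coordinates) covering the top-variance cells.

    Cells with variance in the top ``top_fraction`` quantile are selected and
    merged into the bounding boxes of their connected components.  Rectangles
    are half-open (row0, col0, row1, col1), sorted for determinism.
    """
    v = np.asarray(v, dtype=float)
    if v.size == 0:
        raise ValueError("variance map is empty")
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    thr = np.quantile(v, 1.0 - top_fraction)
    mask = v >= thr
    labels = measure.label(mask, connectivity=1)
    rects = []
    for region in measure.regionprops(labels):
        r0, c0, r1, c1 = region.bbox
        rects.append((int(r0), int(c0), int(r1), int(c1)))
    return sorted(rects)


def focus_region(x: Tensor, regions: list[tuple[int, int, int, int]]) -> list[Tensor]:
    """Crop the listed rectangles out of a (B, C, H, W) feature map."""
    H, W = x.shape[-2], x.shape[-1]
    patches = []
    for reg in regions:
        r0, c0, r1, c1 = reg
        if not (0 <= r0 < r1 <= H and 0 <= c0 < c1 <= W):
            raise IndexError(f"region {reg} out of bounds for {H}x{W} feature map")
        patches.append(x[:, :, r0:r1, c0:c1])
    return patches


def _window_partition(cells: Tensor, g: int, s: int) -> tuple[Tensor, np.ndarray, int]:
    """(N, C, g, g) cells -> (N*ns*ns, s*s, C) token windows plus key padding mask."""
    gp = -(-g // s) * s
    if gp != g:
        cells = nn.pad2d(cells, (0, gp - g, 0, gp - g))
    ns = gp // s
    N, C = cells.shape[0], cells.shape[1]
    tokens = (cells.reshape(N, C, ns, s, ns, s)
              .transpose(0, 2, 4, 3, 5, 1)
              .reshape(N * ns * ns, s * s, C))
    valid = np.zeros((gp, gp), dtype=bool)
    valid[:g, :g] = True
    pad_mask = ~(valid.reshape(ns, s, ns, s).transpose(0, 2, 1, 3)
                 .reshape(ns * ns, s * s))
    pad_mask = np.tile(pad_mask, (N, 1))
    return tokens, pad_mask, gp


def _window_merge(tokens: Tensor, N: int, C: int, g: int, gp: int, s: int) -> Tensor:
    ns = gp // s
    cells = (tokens.reshape(N, ns, ns, s, s, C)
             .transpose(0, 5, 1, 3, 2, 4)
             .reshape(N, C, gp, gp))
    if gp != g:
        cells = cells[:, :, :g, :g]
    return cells


class WindowProjections(nn.Module):
    """Shared QKV and output projections used across all window sizes."""

    def __init__(self, channels: int, num_heads: int, rng: np.random.Generator,
                 zero_init_output: bool = False):
        super().__init__()
        if channels % num_heads != 0:
            raise ValueError(
                f"num_heads={num_heads} does not divide channels={channels}")
        self.channels = channels
        self.num_heads = num_heads
        self.head_dim = channels // num_heads
        self.qkv = nn.Linear(channels, 3 * channels, rng)
        self.out = nn.Linear(channels, channels, rng, zero_init=zero_init_output)
        if zero_init_output:
            self.out.bias.data[:] = 0.0


def windowed_attention(x: Tensor, sizes: np.ndarray, cfg: DwamConfig,
                       proj: WindowProjections,
                       active_cells: np.ndarray | None = None,
                       apply_output_projection: bool = True) -> Tensor:
    """Heterogeneous windowed multi-head attention.

    ``sizes`` assigns one window size per variance-grid cell, per sample
    (shape (B, nH, nW)).  Cells are processed grouped by size; partial
    windows are zero-padded with padded tokens masked out of the softmax.
    Inactive cells (``active_cells`` False) contribute exactly zero, so with
    the residual shortcut they pass through unchanged.  No information flows
    between windows.
    """
    B, C, H, W = x.shape
    g = cfg.variance_grid
    ph, pw = (-H) % g, (-W) % g
    xp = pad2d_reflect(x, ph, pw)
    Hp, Wp = H + ph, W + pw
    nH, nW = Hp // g, Wp // g
    cells = (xp.reshape(B, C, nH, g, nW, g)
             .transpose(0, 2, 4, 1, 3, 5)
             .reshape(B * nH * nW, C, g, g))
    flat_sizes = np.asarray(sizes).reshape(-1)
    if flat_sizes.shape[0] != B * nH * nW:
        raise ValueError("window assignment does not match the cell grid")
    active = (np.ones_like(flat_sizes, dtype=bool) if active_cells is None
              else np.asarray(active_cells, dtype=bool).reshape(-1))
    h, dk = proj.num_heads, proj.head_dim
    pieces = []
    for s in np.unique(flat_sizes[active]):
        rows = np.nonzero(active & (flat_sizes == s))[0]
        sub = nn.take_rows(cells, rows)
        N = len(rows)
        tokens, pad_mask, gp = _window_partition(sub, g, int(s))
        qkv = proj.qkv(tokens)                                   # (M, T, 3C)
        M, T = qkv.shape[0], qkv.shape[1]
        qkv = qkv.reshape(M, T, 3, h, dk).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]                         # (M, h, T, dk)
        out, _ = nn.scaled_dot_attention(q, k, v,
                                         key_mask=pad_mask[:, None, None, :])
        out = out.transpose(0, 2, 1, 3).reshape(M, T, C)
        if apply_output_projection:
            out = proj.out(out)
        merged = _window_merge(out, N, C, g, gp, int(s))
        pieces.append(nn.scatter_rows(merged, rows, B * nH * nW))
    if not pieces:
        return Tensor(np.zeros((B, C, H, W)))
    total = pieces[0]
    for p in pieces[1:]:
        total = total + p
    out_map = (total.reshape(B, nH, nW, C, g, g)
               .transpose(0, 3, 1, 4, 2, 5)
               .reshape(B, C, Hp, Wp))
    if ph or pw:
        out_map = out_map[:, :, :H, :W]
    return out_map


def pad2d_reflect(x: Tensor, ph: int, pw: int) -> Tensor:
    """Reflect-pad bottom/right of a (B, C, H, W) Tensor (constant w.r.t. grad
    of interior values is wrong for reflect — so this mirrors indices and
    routes gradients back through a gather)."""
    if ph == 0 and pw == 0:
        return x
    H, W = x.shape[-2], x.shape[-1]
    ridx = np.concatenate([np.arange(H), H - 2 - np.arange(ph)])
    cidx = np.concatenate([np.arange(W), W - 2 - np.arange(pw)])
    return x[:, :, ridx][:, :, :, cidx]


@dataclass
class _Inspection:
    """What the block computed on the last forward (for tests and plots)."""
    variance: np.ndarray | None = None
    sizes: np.ndarray | None = None
    focus_cells: np.ndarray | None = None


class DwamBlock(nn.Module):
    """variance -> window assignment -> windowed attention -> residual merge.

    ``adaptive_windows=False`` freezes every cell at max(allowed_sizes)
    (the plain fixed-window regime); ``focus=True`` restricts attention to
    the top-variance cells, leaving the rest on the identity path.
    """

    def __init__(self, channels: int, cfg: DwamConfig, rng: np.random.Generator,
                 adaptive_windows: bool = True, focus: bool = False):
        super().__init__()
        self.cfg = cfg
        self.channels = channels
        self.adaptive_windows = adaptive_windows
        self.focus = focus
        self.proj = WindowProjections(channels, cfg.num_heads, rng,
                                      zero_init_output=cfg.zero_init_output_projection)
        self.last = _Inspection()

    def forward(self, x: Tensor, variance_source: Tensor | None = None) -> Tensor:
        cfg = self.cfg
        src = x if variance_source is None else variance_source
        v = local_variance(src, cfg.variance_grid)          # (B, nH, nW)
        if self.adaptive_windows:
            sizes = assign_windows(v, cfg)
        else:
            sizes = np.full(v.shape, max(cfg.allowed_sizes), dtype=int)
        active = None
        if self.focus:
            active = np.zeros(v.shape, dtype=bool)
            for b in range(v.shape[0]):
                for r0, c0, r1, c1 in derive_focus_regions(v[b], cfg.focus_top_fraction):
                    active[b, r0:r1, c0:c1] = True
        self.last = _Inspection(variance=v, sizes=sizes, focus_cells=active)
        attn = windowed_attention(x, sizes, cfg, self.proj, active_cells=active)
        return attn + x
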