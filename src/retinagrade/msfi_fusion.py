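"""Multi-scale convolutional feature fusion.

Parallel same-padding convolutions at several odd kernel sizes (default
3/5/7) run on the same input feature map, their outputs are concatenated
along channels, and a pointwise convolution + batch normalisation + ReLU
compresses the stack back to a configured width.  Small kernels pick up
microaneurysm-scale detail, large ones exudate-scale context; kernels above
7x7 are deliberately not offered (diminishing accuracy return for a steep
cost increase at these lesion scales).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

__all__ = ["MsfiConfig", "MsfiBlock", "multiscale_conv", "concat_channels",
           "fusion_layer"]


@dataclass
class MsfiConfig:
    kernel_sizes: tuple[int, ...] = (3, 5, 7)
    branch_channels: int = 32
    fused_channels: int = 64

    def __post_init__(self):
        self.kernel_sizes = tuple(int(k) for k in self.kernel_sizes)
        if len(self.kernel_sizes) < 1:
            raise ValueError("need at least one kernel size")
        for k in self.kernel_sizes:
            if k % 2 == 0:
                raise ValueError(f"kernel sizes must be odd (got {k}); "
                                 "even kernels cannot preserve spatial dims")
            if k > 7:
                raise ValueError(f"kernel size {k} > 7 is not supported")

    @property
    def paddings(self) -> tuple[int, ...]:
        return tuple((k - 1) // 2 for k in self.kernel_sizes)


class MsfiBlock(nn.Module):
    """Parallel branches -> channel concat -> 1x1 conv + BN + ReLU."""

    def __init__(self, in_channels: int, cfg: MsfiConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.branches = [
            nn.Conv2d(in_channels, cfg.branch_channels, k, rng, padding=p)
            for k, p in zip(cfg.kernel_sizes, cfg.paddings)
        ]
        total = cfg.branch_channels * len(cfg.kernel_sizes)
        self.fuse_conv = nn.Conv2d(total, cfg.fused_channels, 1, rng)
        self.fuse_bn = nn.BatchNorm2d(cfg.fused_channels)

    def forward(self, x: Tensor) -> Tensor:
        outs = multiscale_conv(x, self.branches)
        fused = concat_channels(outs)
        return fusion_layer(fused, self.fuse_conv, self.fuse_bn)


def multiscale_conv(x: Tensor, branches: list[nn.Conv2d]) -> list[Tensor]:
    """Run every branch convolution on the same input (stride 1, same padding)."""
    return [branch(x) for branch in branches]


def concat_channels(outs: list[Tensor]) -> Tensor:
    """Concatenate branch outputs along the channel axis, order preserved."""
    if not outs:
        raise ValueError("no branch outputs to concatenate")
    ref = outs[0].shape
    for i, o in enumerate(outs):
        if o.shape[0] != ref[0] or o.shape[2:] != ref[2:]:
            raise ValueError(
                f"branch {i} has shape {o.shape}, incompatible with branch 0 {ref}")
    if len(outs) == 1:
        return outs[0]
    return nn.concat(outs, axis=1)


def fusion_layer(x_fused: Tensor, fuse_conv: nn.Conv2d,
                 fuse_bn: nn.BatchNorm2d) -> Tensor:
    """1x1 conv + batch norm + ReLU channel compression."""
    expected = fuse_conv.weight.shape[1]
    if x_fused.shape[1] != expected:
        raise ValueError(
            f"fusion layer expects {expected} channels, got {x_fused.shape[1]}")
    return fuse_bn(fuse_conv(x_fused)).relu()
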