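"""Building blocks of the detector.

Each block exists in two forms:

* a trainable :class:`~fruitdet.nn.Module` (with batch normalization,
  used by the assembled network), and
* a pure functional application on numpy arrays (no normalization),
  whose semantics are pinned against brute-force convolution oracles in
  the test suite.

Conventions: "same" padding (output spatial size = ceil(input/stride))
for every KxK convolution; activation is Hard-Swish throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "ConvSpec",
    "BlockConfig",
    "hard_swish",
    "depthwise_separable_conv",
    "inverted_bottleneck_block",
    "ghost_conv",
    "ConvBNAct",
    "DepthwiseSeparableConv",
    "InvertedBottleneckBlock",
    "InvertedBottleneckStage",
    "GhostConv",
]


@dataclass(frozen=True)
class ConvSpec:
    """Dimensions of a single 2-D convolution."""

    height: int
    width: int
    in_channels: int
    out_channels: int
    kernel: int
    stride: int = 1
    groups: int = 1

    def __post_init__(self):
        for name in ("height", "width", "in_channels", "out_channels",
                     "kernel", "stride", "groups"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.kernel % 2 == 0:
            raise ValueError(f"kernel must be odd, got {self.kernel}")
        if self.in_channels % self.groups:
            raise ValueError(
                f"in_channels ({self.in_channels}) not divisible by groups ({self.groups})")

    @property
    def padding(self) -> int:
        return self.kernel // 2

    @property
    def out_hw(self) -> tuple[int, int]:
        return nn.conv_output_hw(self.height, self.width, self.kernel,
                                 self.stride, self.padding)


@dataclass(frozen=True)
class BlockConfig:
    """Hyperparameters of one inverted-bottleneck residual block."""

    in_channels: int
    out_channels: int
    expansion: float = 4.0
    kernel: int = 3
    stride: int = 1

    def __post_init__(self):
        if self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("channel counts must be >= 1")
        if self.kernel % 2 == 0:
            raise ValueError("kernel must be odd")
        if self.stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        if self.expansion <= 0:
            raise ValueError("expansion must be positive")
        if self.expanded_channels < 1:
            raise ValueError("expanded channel count must be >= 1")

    @property
    def expanded_channels(self) -> int:
        return max(1, int(round(self.expansion * self.in_channels)))

    @property
    def residual(self) -> bool:
        # identity shortcut is only addable at stride 1 with matching channels
        return self.stride == 1 and self.in_channels == self.out_channels


# ---------------------------------------------------------------------
# functional forms (numpy in, numpy out)
# ---------------------------------------------------------------------

def hard_swish(x):
    """Elementwise x * ReLU6(x + 3) / 6.

    Accepts scalars, numpy arrays, or autograd tensors; returns the same
    kind. Rejects non-finite input.
    """
    if isinstance(x, Tensor):
        if not np.all(np.isfinite(x.data)):
            raise ValueError("hard_swish: input contains non-finite values")
        return x.hardswish()
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("hard_swish: input contains non-finite values")
    # (clip/6) first so the saturated branches are exact: x*1 and x*0
    out = arr * (np.clip(arr + 3.0, 0.0, 6.0) / 6.0)
    return out if arr.shape else float(out)


def _as_batched(x: np.ndarray) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=float)
    if x.ndim == 3:
        return x[None], True
    if x.ndim == 4:
        return x, False
    raise ValueError(f"expected (C,H,W) or (N,C,H,W) input, got shape {x.shape}")


def depthwise_separable_conv(x, spec: ConvSpec, dw_weight, pw_weight,
                             dw_bias=None, pw_bias=None) -> np.ndarray:
    """Depthwise KxK followed by pointwise 1x1, plain numpy.

    `dw_weight`: (Cin, 1, K, K) — one kernel per input channel.
    `pw_weight`: (Cout, Cin, 1, 1).
    """
    xb, squeeze = _as_batched(x)
    if xb.shape[1] != spec.in_channels:
        raise ValueError(
            f"input has {xb.shape[1]} channels, spec expects {spec.in_channels}")
    dw = nn.conv2d_forward(xb, dw_weight, stride=spec.stride,
                           padding=spec.padding, groups=spec.in_channels,
                           bias=dw_bias)
    out = nn.conv2d_forward(dw, pw_weight, stride=1, padding=0, bias=pw_bias)
    return out[0] if squeeze else out


def inverted_bottleneck_block(x, cfg: BlockConfig, weights: dict) -> np.ndarray:
    """Functional inverted-bottleneck residual block.

    weights keys: ``expand`` (Ce,Cin,1,1), ``depthwise`` (Ce,1,K,K),
    ``compress`` (Cout,Ce,1,1). Computes
    hard_swish(f3(f2(f1(x))) + shortcut) with hard-swish after the first
    two stages, identity shortcut when addable.
    """
    xb, squeeze = _as_batched(x)
    if xb.shape[1] != cfg.in_channels:
        raise ValueError(
            f"input has {xb.shape[1]} channels, config expects {cfg.in_channels}")
    h = nn.conv2d_forward(xb, weights["expand"], stride=1, padding=0)
    h = hard_swish(h)
    h = nn.conv2d_forward(h, weights["depthwise"], stride=cfg.stride,
                          padding=cfg.kernel // 2, groups=cfg.expanded_channels)
    h = hard_swish(h)
    h = nn.conv2d_forward(h, weights["compress"], stride=1, padding=0)
    if cfg.residual:
        h = h + xb
    out = hard_swish(h)
    return out[0] if squeeze else out


def ghost_conv(x, out_channels: int, primary_weight, cheap_weight,
               stride: int = 1) -> np.ndarray:
    """Functional ghost convolution: Y = [F_conv(X); F_cheap(F_conv(X))].

    Primary half is a standard convolution producing out_channels/2 maps;
    cheap half is a depthwise transform of the primary maps. Output
    channels 0..C/2-1 are the primary maps, C/2..C-1 the cheap maps.
    """
    if out_channels % 2:
        raise ValueError(f"ghost_conv out_channels must be even, got {out_channels}")
    xb, squeeze = _as_batched(x)
    half = out_channels // 2
    pk = primary_weight.shape[-1]
    primary = nn.conv2d_forward(xb, primary_weight, stride=stride, padding=pk // 2)
    if primary.shape[1] != half:
        raise ValueError("primary weight must produce out_channels/2 maps")
    ck = cheap_weight.shape[-1]
    cheap = nn.conv2d_forward(primary, cheap_weight, stride=1, padding=ck // 2,
                              groups=half)
    out = np.concatenate([primary, cheap], axis=1)
    return out[0] if squeeze else out


# ---------------------------------------------------------------------
# trainable modules
# ---------------------------------------------------------------------

class ConvBNAct(nn.Module):
    """Conv -> BatchNorm -> (optional) Hard-Swish."""

    def __init__(self, in_channels, out_channels, kernel, stride=1, groups=1,
                 act=True, norm=True):
        super().__init__()
        self.conv = nn.Conv2d(in_channels, out_channels, kernel, stride,
                              groups=groups, bias=not norm)
        self.bn = nn.BatchNorm2d(out_channels) if norm else None
        self.act = act

    def forward(self, x):
        x = self.conv(x)
        if self.bn is not None:
            x = self.bn(x)
        return x.hardswish() if self.act else x


class DepthwiseSeparableConv(nn.Module):
    """Depthwise KxK + pointwise 1x1, each followed by BN; Hard-Swish at the end."""

    def __init__(self, in_channels, out_channels, kernel=3, stride=1,
                 act=True, norm=True):
        super().__init__()
        self.dw = ConvBNAct(in_channels, in_channels, kernel, stride,
                            groups=in_channels, act=False, norm=norm)
        self.pw = ConvBNAct(in_channels, out_channels, 1, 1, act=act, norm=norm)

    def forward(self, x):
        return self.pw(self.dw(x))


class InvertedBottleneckBlock(nn.Module):
    """Pointwise expand -> depthwise -> pointwise compress, residual add,
    Hard-Swish on the sum. Intermediate activations after expand and
    depthwise stages; the compress stage is linear."""

    def __init__(self, cfg: BlockConfig, norm=True):
        super().__init__()
        self.cfg = cfg
        ce = cfg.expanded_channels
        self.expand = ConvBNAct(cfg.in_channels, ce, 1, act=True, norm=norm)
        self.depthwise = ConvBNAct(ce, ce, cfg.kernel, cfg.stride, groups=ce,
                                   act=True, norm=norm)
        self.compress = ConvBNAct(ce, cfg.out_channels, 1, act=False, norm=norm)

    def forward(self, x):
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"input has {x.shape[1]} channels, block expects {self.cfg.in_channels}")
        y = self.compress(self.depthwise(self.expand(x)))
        if self.cfg.residual:
            y = y + x
        return y.hardswish()


class InvertedBottleneckStage(nn.Module):
    """Stack of inverted-bottleneck blocks: the first may change channels
    and stride, the rest are residual stride-1 blocks."""

    def __init__(self, in_channels, out_channels, n_blocks, expansion=4.0,
                 kernel=3, stride=1, norm=True):
        super().__init__()
        if n_blocks < 1:
            raise ValueError(f"n_blocks must be >= 1, got {n_blocks}")
        blocks = [InvertedBottleneckBlock(
            BlockConfig(in_channels, out_channels, expansion, kernel, stride),
            norm=norm)]
        for _ in range(n_blocks - 1):
            blocks.append(InvertedBottleneckBlock(
                BlockConfig(out_channels, out_channels, expansion, kernel, 1),
                norm=norm))
        self.blocks = nn.ModuleList(blocks)

    def forward(self, x):
        for b in self.blocks:
            x = b(x)
        return x


class GhostConv(nn.Module):
    """Half the output maps from a standard conv, the other half from a
    cheap 5x5 depthwise transform of the first half; concatenated
    primary-first."""

    def __init__(self, in_channels, out_channels, kernel=1, stride=1,
                 cheap_kernel=5, act=True, norm=True):
        super().__init__()
        if out_channels % 2:
            raise ValueError(f"GhostConv out_channels must be even, got {out_channels}")
        half = out_channels // 2
        self.primary = ConvBNAct(in_channels, half, kernel, stride,
                                 act=act, norm=norm)
        self.cheap = ConvBNAct(half, half, cheap_kernel, 1, groups=half,
                               act=act, norm=norm)

    def forward(self, x):
        p = self.primary(x)
        return nn.concat([p, self.cheap(p)], axis=1)
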