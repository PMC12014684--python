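"""Analytic parameter and FLOP accounting.

FLOPs are counted as multiply-accumulates (1 MAC = 1 FLOP) over output
positions, excluding bias adds, normalization and activations — the
convention under which detection papers print GFLOPs tables. For a
standard convolution the count is Ho*Wo*Cin*Cout*K^2; a depthwise
separable convolution splits into a depthwise term Ho*Wo*Cin*K^2 and a
pointwise term Ho*Wo*Cin*Cout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .blocks import ConvSpec

__all__ = [
    "ComplexityReport",
    "flops_standard_conv",
    "flops_depthwise_separable",
    "flops_conv2d",
    "model_complexity",
    "relative_change",
]


@dataclass
class ComplexityReport:
    """Per-layer and total parameter / FLOP counts at a given input size."""

    per_layer: list = field(default_factory=list)  # (name, params, flops)
    input_size: int = 0

    @property
    def total_params(self) -> int:
        return int(sum(p for _, p, _ in self.per_layer))

    @property
    def total_flops(self) -> int:
        return int(sum(f for _, _, f in self.per_layer))

    @property
    def params_m(self) -> float:
        return round(self.total_params / 1e6, 3)

    @property
    def gflops(self) -> float:
        return round(self.total_flops / 1e9, 3)

    def to_dict(self) -> dict:
        return {
            "input_size": self.input_size,
            "total_params": self.total_params,
            "total_flops": self.total_flops,
            "params_M": self.params_m,
            "gflops": self.gflops,
            "per_layer": [
                {"name": n, "params": int(p), "flops": int(f)}
                for n, p, f in self.per_layer
            ],
        }


def flops_standard_conv(spec: ConvSpec) -> int:
    """MAC count of a standard (groups=1) convolution: Ho*Wo*Cin*Cout*K^2."""
    if spec.groups != 1:
        raise ValueError("flops_standard_conv requires groups=1")
    ho, wo = spec.out_hw
    return ho * wo * spec.in_channels * spec.out_channels * spec.kernel ** 2


def flops_depthwise_separable(spec: ConvSpec) -> tuple[int, int, int]:
    """(depthwise, pointwise, total) MAC counts for the separable factorization.

    depthwise: Ho*Wo*Cin*K^2; pointwise: Ho*Wo*Cin*Cout; total: their sum.
    """
    ho, wo = spec.out_hw
    dw = ho * wo * spec.in_channels * spec.kernel ** 2
    pw = ho * wo * spec.in_channels * spec.out_channels
    return dw, pw, dw + pw


def flops_conv2d(spec: ConvSpec) -> int:
    """MAC count of a (possibly grouped) convolution:
    Ho*Wo*(Cin/groups)*Cout*K^2. Reduces to the standard formula at
    groups=1 and to the depthwise formula at groups=Cin=Cout."""
    ho, wo = spec.out_hw
    return ho * wo * (spec.in_channels // spec.groups) * spec.out_channels \
        * spec.kernel ** 2


def model_complexity(model: nn.Module, input_size: int,
                     in_channels: int = 3) -> ComplexityReport:
    """Walk every convolution in `model`, tracking spatial sizes through a
    real forward pass at `input_size`, and tally exact parameter counts
    plus analytic MAC counts per layer.

    Parameters include conv weights/biases and normalization affine
    parameters; FLOPs cover convolutions only (see module docstring).
    """
    report = ComplexityReport(input_size=input_size)
    convs = {id(m): name for name, m in model.named_modules()
             if isinstance(m, nn.Conv2d)}
    norm_params = {}
    for name, m in model.named_modules():
        if isinstance(m, nn.BatchNorm2d):
            # attach BN affine params to the layer entry of their conv sibling
            norm_params[name] = int(m.gamma.size + m.beta.size)

    entries = []
    orig_forward = nn.Conv2d.forward

    def traced_forward(self, x):
        spec = ConvSpec(x.shape[2], x.shape[3], self.in_channels,
                        self.out_channels, self.kernel, self.stride,
                        self.groups)
        params = int(self.weight.size + (self.bias.size if self.bias is not None else 0))
        entries.append((convs.get(id(self), "conv"), params, flops_conv2d(spec)))
        return orig_forward(self, x)

    was_training = model.training
    model.eval()
    nn.Conv2d.forward = traced_forward
    try:
        x = nn.Tensor(np.zeros((1, in_channels, input_size, input_size), np.float32))
        model(x)
    except Exception as exc:
        raise ValueError(f"model not instantiable at input size {input_size}: {exc}") from exc
    finally:
        nn.Conv2d.forward = orig_forward
        model.train(was_training)

    report.per_layer = entries
    for bn_name, n in norm_params.items():
        report.per_layer.append((bn_name, n, 0))
    # parameters owned by neither a conv nor a norm (e.g. fusion weights)
    conv_or_norm = set()
    for name, m in model.named_modules():
        if isinstance(m, (nn.Conv2d, nn.BatchNorm2d)):
            for pname, p in m.named_parameters(name):
                conv_or_norm.add(id(p))
    for pname, p in model.named_parameters():
        if id(p) not in conv_or_norm:
            report.per_layer.append((pname, int(p.size), 0))
    return report


def relative_change(before: float, after: float) -> float:
    """Signed percent change 100*(after-before)/before, rounded to 3 decimals."""
    if not np.isfinite(before) or before <= 0:
        raise ValueError(f"'before' must be a positive finite number, got {before}")
    return round(100.0 * (after - before) / before, 3)
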