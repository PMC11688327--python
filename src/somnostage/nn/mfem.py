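"""Multi-scale feature extraction over time-frequency maps.

A cascade of dilated 3x3 convolutions covers receptive fields from fine to
coarse: the first branch convolves the input directly, every later branch
convolves the input summed with the previous branch's output, at a larger
dilation rate.  Multi-Scale Selection Fusion (MSF) then weights the branches:
global average pooling over the time axis gives one descriptor per frequency
position and scale, a sigmoid squashes it to (0, 1), and a softmax across
scales turns the descriptors into convex weights at each frequency position.
The weighted sum of branch maps is added back to the input (residual output).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from somnostage.autodiff import Tensor, concat, conv2d_same, index_select, sigmoid, softmax
from somnostage.nn.core import Module


@dataclass
class MfemConfig:
    """Dilation schedule and kernel of the multi-scale block."""

    dilation_rates: list[int] = field(default_factory=lambda: [1, 4, 8, 16])
    kernel: int = 3

    def __post_init__(self):
        rates = list(self.dilation_rates)
        if not rates or any(r < 1 for r in rates):
            raise ValueError(f"dilation rates must be >= 1, got {rates}")
        if any(b <= a for a, b in zip(rates, rates[1:])):
            raise ValueError(f"dilation rates must be strictly increasing, got {rates}")
        if self.kernel % 2 != 1:
            raise ValueError(f"kernel must be odd, got {self.kernel}")
        self.dilation_rates = rates

    @property
    def n_scales(self) -> int:
        return len(self.dilation_rates)


class Mfem(Module):
    """Dilated cascade + MSF fusion with residual output.

    Operates on maps of shape (batch, T, F) treated as one-channel 2-D images;
    frequency positions act as the "channel" axis for the fusion weights.
    ``last_weights`` keeps the (batch, n_scales, F) fusion weights of the most
    recent forward pass for inspection.
    """

    def __init__(self, cfg: MfemConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        k = cfg.kernel
        std = 1.0 / k
        self.conv_weights = [
            Tensor(rng.normal(0.0, std, size=(k, k)), requires_grad=True)
            for _ in cfg.dilation_rates
        ]
        self.conv_biases = [Tensor(np.zeros(()), requires_grad=True) for _ in cfg.dilation_rates]
        self.last_weights: np.ndarray | None = None

    def dilated_cascade(self, x: Tensor) -> list[Tensor]:
        """Branch maps X_1..X_n; X_i convolves (x + X_{i-1}) at rate r_i."""
        scales: list[Tensor] = []
        prev: Tensor | None = None
        for w, b, rate in zip(self.conv_weights, self.conv_biases, self.cfg.dilation_rates):
            inp = x if prev is None else x + prev
            prev = conv2d_same(inp, w, b, dilation=rate)
            scales.append(prev)
        return scales

    def msf_fuse(self, scales: list[Tensor], x: Tensor) -> Tensor:
        """Adaptive weighted fusion of branch maps, added to the input."""
        B, _, F = x.shape
        # (batch, n_scales, F): temporal GAP per scale, sigmoid, softmax over scales
        gap = concat([s.mean(axis=-2, keepdims=True) for s in scales], axis=-2)
        weights = softmax(sigmoid(gap), axis=-2)
        self.last_weights = weights.data
        fused = None
        for i, s in enumerate(scales):
            w_i = index_select(weights, np.array([i]), axis=-2)  # (B, 1, F), broadcasts over T
            term = w_i * s
            fused = term if fused is None else fused + term
        return x + fused

    def forward(self, x: Tensor) -> Tensor:
        return self.msf_fuse(self.dilated_cascade(x), x)
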