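"""Dual-task residual encoder-decoder for sO2 estimation + segmentation.

One shared residual encoder (two 3x3x3 convolutions with leaky-ReLU
activations per level, 1x1x1 shortcut, 2x2x2 max pooling between levels),
a bottleneck attention block combining channel squeeze-excitation with a
single-channel spatial gate, and two task-specific decoders (2x2x2
transposed-convolution upsampling, encoder skip concatenation, residual
decoding blocks). Each decoder head ends in a 1x1x1 convolution and a
sigmoid, so both outputs live in (0, 1): a whole-volume sO2 map and a
target-structure segmentation probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = ["NetworkConfig", "DualTaskNet", "build_network"]


@dataclass(frozen=True)
class NetworkConfig:
    levels: int = 5
    base_channels: int = 16
    input_channels: int = 3
    leaky_slope: float = 0.1
    attention: bool = True
    se_reduction: int = 4
    max_channels: int = 256
    seed: int = 0

    def channels(self, level: int) -> int:
        return min(self.base_channels * 2**level, self.max_channels)


def _he(rng, shape, fan_in):
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


class _ResBlock:
    """conv3 -> lrelu -> conv3, plus a 1x1x1 shortcut, lrelu on the sum."""

    def __init__(self, rng, c_in, c_out, slope):
        self.slope = slope
        self.w1 = Tensor(_he(rng, (c_out, c_in, 3, 3, 3), c_in * 27), requires_grad=True)
        self.b1 = Tensor(np.zeros(c_out), requires_grad=True)
        self.w2 = Tensor(_he(rng, (c_out, c_out, 3, 3, 3), c_out * 27), requires_grad=True)
        self.b2 = Tensor(np.zeros(c_out), requires_grad=True)
        self.ws = Tensor(_he(rng, (c_out, c_in), c_in), requires_grad=True)
        self.bs = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        h = ag.leaky_relu(ag.conv3d(x, self.w1, self.b1), self.slope)
        h = ag.conv3d(h, self.w2, self.b2)
        s = ag.conv1x1(x, self.ws, self.bs)
        return ag.leaky_relu(ag.add(h, s), self.slope)

    def params(self):
        return [self.w1, self.b1, self.w2, self.b2, self.ws, self.bs]


class _Attention:
    """Channel squeeze-excitation followed by a single-channel spatial gate."""

    def __init__(self, rng, c, reduction, slope):
        self.slope = slope
        cr = max(1, c // reduction)
        self.w_down = Tensor(_he(rng, (cr, c), c), requires_grad=True)
        self.b_down = Tensor(np.zeros(cr), requires_grad=True)
        self.w_up = Tensor(_he(rng, (c, cr), cr), requires_grad=True)
        self.b_up = Tensor(np.zeros(c), requires_grad=True)
        self.w_sp = Tensor(_he(rng, (1, c), c), requires_grad=True)
        self.b_sp = Tensor(np.zeros(1), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        z = ag.global_avg_pool(x)
        z = ag.leaky_relu(ag.conv1x1(z, self.w_down, self.b_down), self.slope)
        scale = ag.sigmoid(ag.conv1x1(z, self.w_up, self.b_up))
        x = ag.mul(x, scale)
        gate = ag.sigmoid(ag.conv1x1(x, self.w_sp, self.b_sp))
        return ag.mul(x, gate)

    def params(self):
        return [self.w_down, self.b_down, self.w_up, self.b_up, self.w_sp, self.b_sp]


class _Decoder:
    def __init__(self, rng, config: NetworkConfig):
        L = config.levels
        self.slope = config.leaky_slope
        self.ups = []
        self.blocks = []
        for lvl in range(L - 2, -1, -1):
            c_lo = config.channels(lvl + 1)
            c_hi = config.channels(lvl)
            wu = Tensor(_he(rng, (c_lo, c_hi, 2, 2, 2), c_lo * 8), requires_grad=True)
            bu = Tensor(np.zeros(c_hi), requires_grad=True)
            self.ups.append((wu, bu))
            self.blocks.append(_ResBlock(rng, 2 * c_hi, c_hi, self.slope))
        c0 = config.channels(0)
        self.w_head = Tensor(_he(rng, (1, c0), c0), requires_grad=True)
        self.b_head = Tensor(np.zeros(1), requires_grad=True)

    def __call__(self, bottom: Tensor, skips: list[Tensor]) -> Tensor:
        h = bottom
        for (wu, bu), block, skip in zip(self.ups, self.blocks, reversed(skips)):
            h = ag.conv_transpose3d(h, wu, bu)
            h = block(ag.concat([skip, h], axis=1))
        return ag.sigmoid(ag.conv1x1(h, self.w_head, self.b_head))

    def params(self):
        ps = []
        for wu, bu in self.ups:
            ps += [wu, bu]
        for b in self.blocks:
            ps += b.params()
        return ps + [self.w_head, self.b_head]


class DualTaskNet:
    """Callable mapping (N, 3, D, H, W) -> (so2, seg_prob) of the same shape."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.enc_blocks = []
        c_in = config.input_channels
        for lvl in range(config.levels):
            c_out = config.channels(lvl)
            self.enc_blocks.append(_ResBlock(rng, c_in, c_out, config.leaky_slope))
            c_in = c_out
        self.attention = (_Attention(rng, c_in, config.se_reduction,
                                     config.leaky_slope) if config.attention else None)
        self.dec_so2 = _Decoder(rng, config)
        self.dec_seg = _Decoder(rng, config)

    def _check_shape(self, shape):
        div = 2 ** (self.config.levels - 1)
        bad = [s for s in shape if s % div != 0]
        if bad:
            raise ValueError(
                f"input spatial dims {tuple(shape)} must be divisible by {div} "
                f"for {self.config.levels} levels; pad each offending axis up to "
                f"the next multiple of {div}"
            )

    def forward(self, x) -> tuple[Tensor, Tensor]:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        if x.data.ndim == 4:
            x = Tensor(x.data[None], requires_grad=x.requires_grad)
        self._check_shape(x.shape[2:])
        skips = []
        h = x
        for lvl, block in enumerate(self.enc_blocks):
            h = block(h)
            if lvl < self.config.levels - 1:
                skips.append(h)
                h = ag.maxpool3d(h)
        if self.attention is not None:
            h = self.attention(h)
        return self.dec_so2(h, skips), self.dec_seg(h, skips)

    __call__ = forward

    def params(self) -> list[Tensor]:
        ps = []
        for b in self.enc_blocks:
            ps += b.params()
        if self.attention is not None:
            ps += self.attention.params()
        return ps + self.dec_so2.params() + self.dec_seg.params()

    def n_params(self) -> int:
        return sum(p.data.size for p in self.params())

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params(), state, strict=True):
            p.data[...] = s


def build_network(config: NetworkConfig) -> DualTaskNet:
    """Construct a seeded dual-task network from a validated config."""
    if config.levels < 2:
        raise ValueError("network needs at least 2 levels")
    return DualTaskNet(config)
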