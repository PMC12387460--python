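"""Squeeze-and-excitation channel attention.

Functional reference API on NumPy arrays (squeeze → excitation → recalibrate)
plus the :class:`SEBlock` network module used inside the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .exceptions import ShapeMismatch
from .nn.tensor import Tensor, _sigmoid

DEFAULT_REDUCTION = 16  # standard SE choice; the ratio is never stated in-source


def hidden_width(channels: int, reduction: int) -> int:
    return max(channels // reduction, 1)


@dataclass
class ChannelDescriptor:
    """Per-channel spatial mean, length C."""

    z: np.ndarray

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=np.float64).reshape(-1)


@dataclass
class ExcitationWeights:
    """Two-layer bottleneck weights: W1 [C/r, C], W2 [C, C/r]."""

    W1: np.ndarray
    W2: np.ndarray
    reduction_ratio: int = DEFAULT_REDUCTION
    b1: np.ndarray | None = None
    b2: np.ndarray | None = None

    def __post_init__(self):
        self.W1 = np.asarray(self.W1, dtype=np.float64)
        self.W2 = np.asarray(self.W2, dtype=np.float64)
        if self.W1.ndim != 2 or self.W2.ndim != 2:
            raise ShapeMismatch("W1/W2 must be matrices")
        if self.W2.shape[1] != self.W1.shape[0] or self.W2.shape[0] != self.W1.shape[1]:
            raise ShapeMismatch(
                f"inconsistent excitation shapes {self.W1.shape} / {self.W2.shape}")

    @property
    def channels(self) -> int:
        return self.W1.shape[1]


@dataclass
class AttentionScores:
    """Per-channel gains in [0, 1]."""

    s: np.ndarray

    def __post_init__(self):
        self.s = np.asarray(self.s, dtype=np.float64).reshape(-1)
        if self.s.size and (self.s.min() < 0.0 or self.s.max() > 1.0):
            raise ValueError("attention scores must lie in [0, 1]")


def init_excitation_weights(channels: int, reduction: int = DEFAULT_REDUCTION,
                            rng: np.random.Generator | None = None,
                            bias: bool = False) -> ExcitationWeights:
    """Kaiming-uniform (fan-in) initialization of the two-layer bottleneck."""
    rng = rng or np.random.default_rng()
    hid = hidden_width(channels, reduction)
    w1 = nn.kaiming_uniform(rng, (hid, channels), channels).astype(np.float64)
    w2 = nn.kaiming_uniform(rng, (channels, hid), hid).astype(np.float64)
    b1 = np.zeros(hid) if bias else None
    b2 = np.zeros(channels) if bias else None
    return ExcitationWeights(w1, w2, reduction, b1, b2)


def squeeze_gap(x) -> ChannelDescriptor:
    """Global average pooling: z_c = mean over spatial positions of channel c."""
    values = x.values if hasattr(x, "values") else np.asarray(x, dtype=np.float64)
    if values.ndim != 3:
        raise ShapeMismatch("expected a [C, H, W] map")
    return ChannelDescriptor(values.mean(axis=(1, 2)))


def excitation(z: ChannelDescriptor, w: ExcitationWeights) -> AttentionScores:
    """s = sigmoid(W2 · relu(W1 · z))."""
    if z.z.shape[0] != w.channels:
        raise ShapeMismatch(f"descriptor length {z.z.shape[0]} != channels {w.channels}")
    h = w.W1 @ z.z
    if w.b1 is not None:
        h = h + w.b1
    h = np.maximum(h, 0.0)
    pre = w.W2 @ h
    if w.b2 is not None:
        pre = pre + w.b2
    return AttentionScores(_sigmoid(pre))


def recalibrate(x, s: AttentionScores):
    """Scale channel c of the map by the scalar gain s_c."""
    values = x.values if hasattr(x, "values") else np.asarray(x, dtype=np.float64)
    if values.shape[0] != s.s.shape[0]:
        raise ShapeMismatch("channel count mismatch between map and scores")
    return values * s.s[:, None, None]


def se_block(x, w: ExcitationWeights):
    """Full block: recalibrate(x, excitation(squeeze_gap(x), w))."""
    return recalibrate(x, excitation(squeeze_gap(x), w))


class SEBlock(nn.Module):
    """Differentiable batched SE block: [B,C,H,W] → [B,C,H,W]."""

    def __init__(self, channels: int, reduction: int = DEFAULT_REDUCTION,
                 bias: bool = False, *, rng: np.random.Generator):
        super().__init__()
        hid = hidden_width(channels, reduction)
        self.fc1 = nn.Linear(channels, hid, bias=bias, rng=rng)
        self.fc2 = nn.Linear(hid, channels, bias=bias, rng=rng)

    def scores(self, x: Tensor) -> Tensor:
        z = x.mean(axis=(2, 3))                       # [B, C]
        return self.fc2(self.fc1(z).relu()).sigmoid()  # [B, C]

    def forward(self, x: Tensor) -> Tensor:
        s = self.scores(x)
        b, c = s.shape
        return x * s.reshape(b, c, 1, 1)
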