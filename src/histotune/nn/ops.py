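"""Core feature-map operations of the lightweight extractor.

These are the reference, single-feature-map (C, H, W) forms of the
building blocks: depthwise convolution, the depthwise-separable cost
model, channel shuffle and efficient channel attention (ECA). The
trainable, batched layers in :mod:`histotune.nn.layers` are built on the
same arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "depthwise_conv",
    "ConvCostSpec",
    "separable_conv_cost",
    "count_macs_separable",
    "count_macs_standard",
    "channel_shuffle",
    "shuffle_permutation",
    "eca_module",
    "sigmoid",
]


def depthwise_conv(x: np.ndarray, kernels: np.ndarray) -> np.ndarray:
    """Channel-wise (depthwise) 2-D convolution, valid padding, stride 1.

    Each channel of ``x`` (C, H, W) is convolved with its own kernel from
    ``kernels`` (C, kH, kW); there is no cross-channel mixing:
    ``G[m, i, j] = sum_{w,h} K[m, w, h] * X[m, i+w, j+h]``.
    """
    x = np.asarray(x, dtype=float)
    kernels = np.asarray(kernels, dtype=float)
    if x.ndim != 3 or kernels.ndim != 3:
        raise ValueError("expected x (C,H,W) and kernels (C,kH,kW)")
    c, h, w = x.shape
    ck, kh, kw = kernels.shape
    if ck != c:
        raise ValueError(f"kernel channel count {ck} != input channels {c}")
    if kh > h or kw > w:
        raise ValueError("kernel larger than input")
    oh, ow = h - kh + 1, w - kw + 1
    # gather all kH*kW shifted views and contract against the kernels
    windows = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(1, 2))
    # windows: (C, oh, ow, kh, kw)
    return np.einsum("cijwh,cwh->cij", windows, kernels)


@dataclass(frozen=True)
class ConvCostSpec:
    """Shape parameters of one convolution: feature side ``df``, kernel side
    ``dk``, input channels ``m``, output channels ``n``."""

    df: int
    dk: int
    m: int
    n: int

    def __post_init__(self) -> None:
        if min(self.df, self.dk, self.m, self.n) < 1:
            raise ValueError("all cost-spec fields must be >= 1")


def separable_conv_cost(spec: ConvCostSpec) -> tuple[int, int, float]:
    """Multiplication counts of depthwise-separable vs standard convolution.

    Returns ``(Q1, Q2, Q1/Q2)`` where ``Q1 = Df^2 Dk^2 M + Df^2 M N`` is
    the depthwise-separable cost (depthwise pass plus 1x1 pointwise pass)
    and ``Q2 = Df^2 Dk^2 M N`` the standard-convolution cost, so the ratio
    collapses to ``1/N + 1/Dk^2``. With a 3x3 kernel and many output
    channels the ratio approaches 1/9.
    """
    q1 = spec.df**2 * spec.dk**2 * spec.m + spec.df**2 * spec.m * spec.n
    q2 = spec.df**2 * spec.dk**2 * spec.m * spec.n
    return q1, q2, q1 / q2


def count_macs_separable(spec: ConvCostSpec) -> int:
    """Multiply-accumulates of an actual depthwise-separable pass.

    Counts one MAC per kernel tap per output position: the depthwise stage
    has ``Df^2`` positions x ``Dk^2`` taps x ``M`` channels; the pointwise
    stage has ``Df^2`` positions x ``M`` taps x ``N`` outputs. Output kept
    at ``Df`` per side (same padding).
    """
    depthwise = spec.df**2 * spec.dk**2 * spec.m
    pointwise = spec.df**2 * spec.m * spec.n
    return depthwise + pointwise


def count_macs_standard(spec: ConvCostSpec) -> int:
    """Multiply-accumulates of a standard convolution on the same shape."""
    return spec.df**2 * spec.dk**2 * spec.m * spec.n


def shuffle_permutation(c: int, groups: int) -> np.ndarray:
    """Channel order after a shuffle: reshape (g, c/g) -> transpose -> flatten."""
    if c % groups != 0:
        raise ValueError(f"channel count {c} not divisible by groups {groups}")
    return np.arange(c).reshape(groups, c // groups).T.ravel()


def channel_shuffle(x: np.ndarray, groups: int) -> np.ndarray:
    """Interleave channels across groups; spatial content untouched.

    The operation is a fixed permutation of channels (bijective), so
    shuffling with ``g`` then ``C/g`` groups restores the original order.
    """
    x = np.asarray(x)
    perm = shuffle_permutation(x.shape[0], groups)
    return x[perm]


def sigmoid(z: np.ndarray) -> np.ndarray:
    # numerically stable on both tails
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def eca_module(x: np.ndarray, conv1d_weights: np.ndarray) -> np.ndarray:
    """Efficient channel attention: pool -> short 1-D conv -> sigmoid -> scale.

    The per-channel global average pool gives a length-C descriptor; a 1-D
    convolution of odd length k (zero padding, same length out) mixes each
    channel with its k-1 neighbors; the sigmoid maps the result into (0, 1)
    attention weights that rescale the corresponding channel of ``x``.
    With all-zero conv weights every attention weight is sigmoid(0) = 0.5.
    """
    x = np.asarray(x, dtype=float)
    w = np.asarray(conv1d_weights, dtype=float)
    if w.ndim != 1 or w.size % 2 == 0:
        raise ValueError("conv1d weights must be a vector of odd length")
    favg = x.mean(axis=(1, 2))
    attn = sigmoid(_conv1d_same(favg, w))
    return x * attn[:, None, None], attn


def _conv1d_same(signal: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Cross-correlation with zero padding, output length == input length."""
    k = weights.size
    pad = k // 2
    padded = np.pad(signal, pad)
    windows = np.lib.stride_tricks.sliding_window_view(padded, k)
    return windows @ weights
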