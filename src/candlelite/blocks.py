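"""Primitive building blocks and convolution cost formulas.

The lightweighting idea the detector is built on: a standard ``k x k``
convolution with ``m`` input channels and ``N`` kernels costs
``Sc = m * k^2 * p^2 * N`` (with ``p`` kernel slides per spatial axis), while
a depth-wise separable replacement — one ``k x k`` per-channel convolution
plus one ``1 x 1`` channel-mixing convolution — costs
``Sd = m * k^2 * p^2 + m * p^2 * N``.  The ratio ``Sd / Sc = 1/N + 1/k^2``
is independent of ``m`` and ``p``; for a 3x3 conv with many kernels it
approaches 1/9.

Fragment builders append layers to a :class:`~candlelite.graphspec.GraphBuilder`
and return the output node id.  All convolutions are 'same'-padded
(pad = k // 2; pool pad = k // 2), so spatial bookkeeping is pure stride
arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
import math

from .graphspec import GraphBuilder

__all__ = [
    "ConvCost",
    "conv_param_costs",
    "build_cbs",
    "build_dws",
    "build_conv_block",
    "build_focus",
    "build_spp",
    "build_eca",
    "eca_kernel_size",
]


@dataclass(frozen=True)
class ConvCost:
    """Evaluated parameter costs of a normal vs. depth-wise separable conv."""

    m: int  # input channels
    k: int  # kernel size
    p: int  # kernel slides per spatial axis
    N: int  # kernel (output channel) count
    Sc: int  # normal-convolution cost  m * k^2 * p^2 * N
    Sd: int  # separable cost  m * k^2 * p^2  +  m * p^2 * N

    @property
    def ratio(self) -> Fraction:
        """Sd / Sc as an exact rational; always equals 1/N + 1/k^2."""
        return Fraction(self.Sd, self.Sc)


def conv_param_costs(m: int, k: int, p: int, N: int) -> ConvCost:
    """Evaluate the normal vs. depth-wise separable convolution costs.

    All arguments must be >= 1.  The returned ratio ``Sd/Sc`` equals
    ``1/N + 1/k^2`` exactly, independent of ``m`` and ``p``.
    """
    for name, v in (("m", m), ("k", k), ("p", p), ("N", N)):
        if not isinstance(v, int) or v < 1:
            raise ValueError(f"{name} must be a positive integer, got {v!r}")
    sc = m * k**2 * p**2 * N
    sd = m * k**2 * p**2 + m * p**2 * N
    return ConvCost(m=m, k=k, p=p, N=N, Sc=sc, Sd=sd)


# ----------------------------------------------------------------------
# graph fragments


def build_cbs(
    b: GraphBuilder,
    x: str,
    c_in: int,
    c_out: int,
    k: int = 1,
    stride: int = 1,
    name: str = "cbs",
) -> str:
    """Conv -> BatchNorm -> SiLU, the network's basic composition.

    The conv carries no bias; its shift is folded into the batchnorm affine.
    """
    if k not in (1, 3):
        raise ValueError(f"kernel must be 1 or 3, got {k}")
    if stride not in (1, 2):
        raise ValueError(f"stride must be 1 or 2, got {stride}")
    with b.scoped(name):
        h = b.add("conv2d", "conv", inputs=x, c_in=c_in, c_out=c_out, kernel=k, stride=stride)
        h = b.add("batchnorm", "bn", inputs=h, c_in=c_out, c_out=c_out)
        h = b.add("silu", "act", inputs=h, c_in=c_out, c_out=c_out)
    return h


def build_dws(
    b: GraphBuilder,
    x: str,
    c_in: int,
    c_out: int,
    k: int = 3,
    stride: int = 1,
    name: str = "dws",
) -> str:
    """Depth-wise separable block: DWConv-BN-SiLU then 1x1 Conv-BN-SiLU.

    Only 3x3 convolutions are ever substituted; requesting k=1 is refused
    because the substitution is the identity there.
    """
    if k != 3:
        raise ValueError("depth-wise separable substitution applies to k=3 only")
    with b.scoped(name):
        h = b.add("dwconv2d", "dw", inputs=x, c_in=c_in, c_out=c_in, kernel=k, stride=stride)
        h = b.add("batchnorm", "dw_bn", inputs=h, c_in=c_in, c_out=c_in)
        h = b.add("silu", "dw_act", inputs=h, c_in=c_in, c_out=c_in)
        h = b.add("conv2d", "pw", inputs=h, c_in=c_in, c_out=c_out, kernel=1, stride=1)
        h = b.add("batchnorm", "pw_bn", inputs=h, c_in=c_out, c_out=c_out)
        h = b.add("silu", "pw_act", inputs=h, c_in=c_out, c_out=c_out)
    return h


def build_conv_block(
    b: GraphBuilder,
    x: str,
    c_in: int,
    c_out: int,
    k: int,
    stride: int = 1,
    dw: bool = False,
    name: str = "conv",
) -> str:
    """CBS, or its depth-wise separable substitute when ``dw`` and k == 3."""
    if dw and k == 3:
        return build_dws(b, x, c_in, c_out, k, stride, name=name)
    return build_cbs(b, x, c_in, c_out, k, stride, name=name)


def build_focus(
    b: GraphBuilder, x: str, c_out: int = 24, dw: bool = False, name: str = "focus"
) -> str:
    """Stem: space-to-depth (3 -> 12 channels, half resolution) + 3x3 CBS.

    The backbones keep the stem conv standard in every build (the published
    depth-wise model sizes are only reproduced with it untouched); the
    ``dw`` form exists for completeness.
    """
    with b.scoped(name):
        h = b.add("slice_space_to_depth", "slice", inputs=x, c_in=3, c_out=12)
        h = build_conv_block(b, h, 12, c_out, k=3, stride=1, dw=dw, name="stem")
    return h


def build_spp(
    b: GraphBuilder,
    x: str,
    c_in: int = 384,
    c_out: int = 384,
    pool_sizes: tuple[int, ...] = (5, 9, 13),
    name: str = "spp",
) -> str:
    """Spatial pyramid pooling: widen the receptive field at the backbone end.

    1x1 CBS to c_in/2, parallel stride-1 same-padded max-pools plus identity,
    concat, 1x1 CBS to c_out.  Pooling is parameter-free.
    """
    if c_in % 2:
        raise ValueError("SPP input channels must be even")
    c_mid = c_in // 2
    with b.scoped(name):
        h = build_cbs(b, x, c_in, c_mid, k=1, name="reduce")
        branches = [h]
        for ks in pool_sizes:
            branches.append(
                b.add("maxpool", f"pool{ks}", inputs=h, c_in=c_mid, c_out=c_mid, kernel=ks, stride=1)
            )
        cat = b.add(
            "concat", "cat", inputs=tuple(branches),
            c_in=c_mid * len(branches), c_out=c_mid * len(branches),
        )
        out = build_cbs(b, cat, c_mid * len(branches), c_out, k=1, name="expand")
    return out


def eca_kernel_size(channels: int, gamma: int = 2, b: int = 1) -> int:
    """Adaptive 1-D kernel size for efficient channel attention.

    The nearest odd integer to ``log2(C)/gamma + b/gamma``; 3 at C=96
    (attention over each channel's 3 neighbours), 5 at C=192 and C=384.
    """
    if channels < 1:
        raise ValueError("channels must be >= 1")
    t = abs(math.log2(channels) / gamma + b / gamma)
    k = int(round((t - 1) / 2)) * 2 + 1  # nearest odd
    return max(k, 1)


def build_eca(b: GraphBuilder, x: str, channels: int, name: str = "eca") -> str:
    """Efficient channel attention gate on a feature map.

    Global average pool -> channel-wise 1-D conv (adaptive odd kernel) ->
    sigmoid -> channel-wise multiply with the input.  Adds exactly k
    parameters; output shape equals input shape.
    """
    k = eca_kernel_size(channels)
    with b.scoped(name):
        g = b.add("global_avg_pool", "gap", inputs=x, c_in=channels, c_out=channels)
        g = b.add("conv1d_channelwise", "conv1d", inputs=g, c_in=channels, c_out=channels, kernel=k)
        g = b.add("sigmoid", "gate", inputs=g, c_in=channels, c_out=channels)
        out = b.add("mul", "scale", inputs=(x, g), c_in=channels, c_out=channels)
    return out
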