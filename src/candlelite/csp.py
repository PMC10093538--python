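"""Cross-stage-partial (CSP) blocks and their reduced-depth variants.

A CSP block splits its input through two parallel 1x1 transitions into two
half-width paths: one left untouched, the other refined by a chain of
residual bottlenecks; the paths are concatenated and fused by a 1x1
convolution.  The three variants differ only in bottleneck count:
3 (the original), 2 (the M variant) and 1 (the S variant).

At 96 channels the parameter counts are 88,512 / 65,280 / 42,048 with
standard convolutions and 34,800 / 29,472 / 24,144 with the depth-wise
separable substitution; consecutive variants differ by exactly one
bottleneck at half width.
"""

from __future__ import annotations

from dataclasses import dataclass

from .graphspec import GraphBuilder, NetGraph
from .blocks import build_cbs, build_conv_block

__all__ = ["CspConfig", "build_bottleneck", "build_csp_layer", "build_cspnet"]


@dataclass(frozen=True)
class CspConfig:
    """Configuration of one CSP block (channel-preserving form)."""

    channels: int
    n_bottlenecks: int = 3
    dw: bool = False
    residual_add: bool = True

    def __post_init__(self) -> None:
        if self.channels % 2:
            raise ValueError("CSP channels must be even")
        if self.n_bottlenecks not in (1, 2, 3):
            raise ValueError("n_bottlenecks must be 1, 2 or 3")


def build_bottleneck(
    b: GraphBuilder,
    x: str,
    c: int,
    dw: bool = False,
    residual: bool = True,
    name: str = "bottleneck",
) -> str:
    """Residual bottleneck: 1x1 CBS -> 3x3 conv block (-> add input)."""
    with b.scoped(name):
        h = build_cbs(b, x, c, c, k=1, name="reduce")
        h = build_conv_block(b, h, c, c, k=3, dw=dw, name="conv3")
        if residual:
            h = b.add("add", "add", inputs=(x, h), c_in=c, c_out=c)
    return h


def build_csp_layer(
    b: GraphBuilder,
    x: str,
    c_in: int,
    c_out: int,
    n: int,
    dw: bool = False,
    residual: bool = True,
    name: str = "csp",
) -> str:
    """General CSP layer with ``n`` bottlenecks at hidden width c_out/2.

    The channel-changing form (c_in != c_out) is used by the feature-fusion
    neck; the backbone uses the channel-preserving form.
    """
    if c_out % 2:
        raise ValueError("CSP output channels must be even")
    c_mid = c_out // 2
    with b.scoped(name):
        main = build_cbs(b, x, c_in, c_mid, k=1, name="trans_main")
        short = build_cbs(b, x, c_in, c_mid, k=1, name="trans_short")
        h = main
        for i in range(n):
            h = build_bottleneck(b, h, c_mid, dw=dw, residual=residual, name=f"b{i}")
        cat = b.add("concat", "cat", inputs=(h, short), c_in=2 * c_mid, c_out=2 * c_mid)
        out = build_cbs(b, cat, 2 * c_mid, c_out, k=1, name="fuse")
    return out


def build_cspnet(
    channels: int,
    n_bottlenecks: int = 3,
    dw: bool = False,
    residual_add: bool = True,
) -> NetGraph:
    """Stand-alone channel-preserving CSP block as a complete graph.

    ``n_bottlenecks`` 3/2/1 gives the original, M and S variants.  The
    default audit input for the published per-block figures is an 80x80
    map at 96 channels.
    """
    cfg = CspConfig(channels=channels, n_bottlenecks=n_bottlenecks, dw=dw, residual_add=residual_add)
    b = GraphBuilder()
    out = build_csp_layer(
        b, "input", cfg.channels, cfg.channels, cfg.n_bottlenecks,
        dw=cfg.dw, residual=cfg.residual_add,
    )
    return b.graph([out], input_spec=(channels, 80, 80))
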