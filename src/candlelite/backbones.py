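"""Feature-extraction backbones emitting three multi-scale outputs.

Three variants of a tiny CSP-Darknet (width multiplier 0.375):

* ``tiny``  — the baseline: Focus stem, four stages with CSP depths
  (1, 3, 3, 1) at channels (48, 96, 192, 384), SPP before the last CSP.
* ``lda_m`` — first-stage CSP removed (the stride-2 conv alone expands the
  channels) and the two middle stages thinned to 2 bottlenecks.
* ``lda_s`` — as lda_m but middle stages thinned to 1 bottleneck; the final
  stage is untouched in both.

Outputs are the last CSP of stages at strides 8, 16 and 32, at channels
(96, 192, 384).  With standard convolutions the three variants hold
2.372 / 2.246 / 2.130 M parameters; depth-wise separable builds hold
1.024 / 0.992 / 0.967 M.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .graphspec import GraphBuilder, NetGraph
from .blocks import build_conv_block, build_focus, build_spp
from .csp import build_csp_layer

__all__ = ["BackboneConfig", "build_backbone_fragment", "build_backbone", "forward_shapes"]

VARIANTS = ("tiny", "lda_m", "lda_s")

#: bottleneck count per stage (None = stage has no CSP block)
_STAGE_DEPTHS: dict[str, tuple[int | None, int, int, int]] = {
    "tiny": (1, 3, 3, 1),
    "lda_m": (None, 2, 2, 1),
    "lda_s": (None, 1, 1, 1),
}


@dataclass(frozen=True)
class BackboneConfig:
    variant: str = "lda_s"
    dw: bool = True
    stage_channels: tuple[int, ...] = (24, 48, 96, 192, 384)

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown backbone variant {self.variant!r}")

    @property
    def stage_bottlenecks(self) -> tuple[int | None, int, int, int]:
        return _STAGE_DEPTHS[self.variant]


def build_backbone_fragment(b: GraphBuilder, x: str, cfg: BackboneConfig) -> tuple[str, str, str]:
    """Append the backbone to a builder; return the three output node ids."""
    c0, c1, c2, c3, c4 = cfg.stage_channels
    n1, n2, n3, n4 = cfg.stage_bottlenecks
    h = build_focus(b, x, c_out=c0)

    with b.scoped("stage2"):
        h = build_conv_block(b, h, c0, c1, k=3, stride=2, dw=cfg.dw, name="down")
        if n1 is not None:
            h = build_csp_layer(b, h, c1, c1, n1, dw=cfg.dw, residual=True, name="csp")

    with b.scoped("stage3"):
        h = build_conv_block(b, h, c1, c2, k=3, stride=2, dw=cfg.dw, name="down")
        h = build_csp_layer(b, h, c2, c2, n2, dw=cfg.dw, residual=True, name="csp")
    out8 = h

    with b.scoped("stage4"):
        h = build_conv_block(b, h, c2, c3, k=3, stride=2, dw=cfg.dw, name="down")
        h = build_csp_layer(b, h, c3, c3, n3, dw=cfg.dw, residual=True, name="csp")
    out16 = h

    with b.scoped("stage5"):
        h = build_conv_block(b, h, c3, c4, k=3, stride=2, dw=cfg.dw, name="down")
        h = build_spp(b, h, c4, c4, name="spp")
        # final stage: no residual adds inside the bottleneck (upstream convention)
        h = build_csp_layer(b, h, c4, c4, n4, dw=cfg.dw, residual=False, name="csp")
    out32 = h

    return out8, out16, out32


def build_backbone(cfg: BackboneConfig, input_size: int = 640) -> NetGraph:
    """Complete backbone graph with the three multi-scale outputs declared."""
    if input_size % 32:
        raise ValueError("input size must be divisible by 32")
    b = GraphBuilder()
    outs = build_backbone_fragment(b, "input", cfg)
    return b.graph(list(outs), input_spec=(3, input_size, input_size))


def forward_shapes(cfg: BackboneConfig, input_size: int = 640) -> tuple[tuple[int, int, int], ...]:
    """(C, H, W) of the three outputs for a square input; strides 8/16/32."""
    g = build_backbone(cfg, input_size)
    shp = g.shapes()
    return tuple(shp[o] for o in g.outputs)
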