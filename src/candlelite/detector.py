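"""Full lightweight detector: backbone -> channel attention -> feature
pyramid -> decoupled anchor-free head, plus box decode and NMS.

The model family:

* ``yolox-tiny`` — baseline tiny detector (5.033 M parameters).
* ``yolox-tiny`` with ``dw`` — every 3x3 conv (except the stem) replaced by a
  depth-wise separable block (1.991 M).
* ``lda`` — the final lightweight architecture: lda_s backbone, depth-wise
  separable convolutions and an efficient-channel-attention gate on each of
  the three backbone outputs (1.935 M).

The head is anchor-free: each grid cell at stride ``s`` predicts a center
offset ``(dx, dy)``, log sizes ``(dw, dh)``, an objectness logit and one
logit per class.  A 640x640 input yields 80^2 + 40^2 + 20^2 = 8,400
candidate cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graphspec import GraphBuilder, NetGraph
from .blocks import build_cbs, build_conv_block, build_eca
from .csp import build_csp_layer
from .backbones import BackboneConfig, build_backbone_fragment

__all__ = [
    "CLASS_NAMES",
    "GTBox",
    "DetBox",
    "ModelConfig",
    "MODEL_PRESETS",
    "build_model",
    "head_output_ids",
    "decode",
    "box_iou",
    "nms",
]

CLASS_NAMES = ("fertile", "infertile")
STRIDES = (8, 16, 32)
FPN_CHANNELS = (96, 192, 384)


@dataclass(frozen=True)
class GTBox:
    """Ground-truth axis-aligned box, 0-based pixel corner coordinates."""

    class_id: int
    x1: float
    y1: float
    x2: float
    y2: float

    def __post_init__(self) -> None:
        if not (self.x1 < self.x2 and self.y1 < self.y2):
            raise ValueError(f"degenerate box {self}")

    @property
    def area(self) -> float:
        return (self.x2 - self.x1) * (self.y2 - self.y1)


@dataclass(frozen=True)
class DetBox:
    """Scored detection; score is the objectness-class product in [0, 1]."""

    class_id: int
    score: float
    x1: float
    y1: float
    x2: float
    y2: float

    @property
    def area(self) -> float:
        return (self.x2 - self.x1) * (self.y2 - self.y1)


@dataclass(frozen=True)
class ModelConfig:
    backbone_variant: str = "lda_s"
    dw: bool = True
    use_eca: bool = True
    num_classes: int = 2
    head_width: int = 96
    input_size: int = 640


#: name -> config used by the audit and predict interfaces
MODEL_PRESETS: dict[str, ModelConfig] = {
    "yolox-tiny": ModelConfig("tiny", dw=False, use_eca=False),
    "yolox-tiny-dw": ModelConfig("tiny", dw=True, use_eca=False),
    "lda-m": ModelConfig("lda_m", dw=True, use_eca=False),
    "lda-s": ModelConfig("lda_s", dw=True, use_eca=False),
    "lda": ModelConfig("lda_s", dw=True, use_eca=True),
}


def _build_fpn(b: GraphBuilder, feats: tuple[str, str, str], dw: bool) -> tuple[str, str, str]:
    """Path-aggregation neck: top-down then bottom-up fusion at (96,192,384)."""
    c3, c4, c5 = FPN_CHANNELS
    f8, f16, f32 = feats
    with b.scoped("fpn"):
        lat32 = build_cbs(b, f32, c5, c4, k=1, name="lateral32")
        up16 = b.add("upsample2x", "up16", inputs=lat32, c_in=c4, c_out=c4)
        cat16 = b.add("concat", "cat16", inputs=(up16, f16), c_in=2 * c4, c_out=2 * c4)
        p16 = build_csp_layer(b, cat16, 2 * c4, c4, n=1, dw=dw, residual=False, name="td16")

        lat16 = build_cbs(b, p16, c4, c3, k=1, name="lateral16")
        up8 = b.add("upsample2x", "up8", inputs=lat16, c_in=c3, c_out=c3)
        cat8 = b.add("concat", "cat8", inputs=(up8, f8), c_in=2 * c3, c_out=2 * c3)
        p8 = build_csp_layer(b, cat8, 2 * c3, c3, n=1, dw=dw, residual=False, name="td8")

        d16 = build_conv_block(b, p8, c3, c3, k=3, stride=2, dw=dw, name="down8")
        catn16 = b.add("concat", "catn16", inputs=(d16, lat16), c_in=2 * c3, c_out=2 * c3)
        n16 = build_csp_layer(b, catn16, 2 * c3, c4, n=1, dw=dw, residual=False, name="bu16")

        d32 = build_conv_block(b, n16, c4, c4, k=3, stride=2, dw=dw, name="down16")
        catn32 = b.add("concat", "catn32", inputs=(d32, lat32), c_in=2 * c4, c_out=2 * c4)
        n32 = build_csp_layer(b, catn32, 2 * c4, c5, n=1, dw=dw, residual=False, name="bu32")
    return p8, n16, n32


def _build_head(
    b: GraphBuilder, feats: tuple[str, str, str], cfg: ModelConfig
) -> list[str]:
    """Decoupled anchor-free head; one 7-channel output map per level.

    Channel layout of each output: [dx, dy, dw, dh, obj, cls_0 .. cls_{K-1}].
    Prediction convs are the only biased convolutions in the network.
    """
    w = cfg.head_width
    outs = []
    for level, (feat, c_in) in enumerate(zip(feats, FPN_CHANNELS)):
        with b.scoped(f"head{STRIDES[level]}"):
            stem = build_cbs(b, feat, c_in, w, k=1, name="stem")
            h = stem
            for i in range(2):
                h = build_conv_block(b, h, w, w, k=3, dw=cfg.dw, name=f"cls{i}")
            cls_pred = b.add(
                "conv2d", "cls_pred", inputs=h, c_in=w, c_out=cfg.num_classes,
                kernel=1, has_bias=True,
            )
            h = stem
            for i in range(2):
                h = build_conv_block(b, h, w, w, k=3, dw=cfg.dw, name=f"reg{i}")
            reg_pred = b.add("conv2d", "reg_pred", inputs=h, c_in=w, c_out=4, kernel=1, has_bias=True)
            obj_pred = b.add("conv2d", "obj_pred", inputs=h, c_in=w, c_out=1, kernel=1, has_bias=True)
            out = b.add(
                "concat", "out", inputs=(reg_pred, obj_pred, cls_pred),
                c_in=5 + cfg.num_classes, c_out=5 + cfg.num_classes,
            )
        outs.append(out)
    return outs


def build_model(cfg: ModelConfig) -> NetGraph:
    """Assemble the full detector graph for a configuration."""
    if cfg.input_size % 32:
        raise ValueError("input size must be divisible by 32")
    bb_cfg = BackboneConfig(variant=cfg.backbone_variant, dw=cfg.dw)
    b = GraphBuilder()
    feats = build_backbone_fragment(b, "input", bb_cfg)
    if cfg.use_eca:
        feats = tuple(
            build_eca(b, f, c, name=f"eca{s}")
            for f, c, s in zip(feats, FPN_CHANNELS, STRIDES)
        )
    feats = _build_fpn(b, feats, cfg.dw)
    outs = _build_head(b, feats, cfg)
    return b.graph(outs, input_spec=(3, cfg.input_size, cfg.input_size))


def head_output_ids(g: NetGraph) -> list[str]:
    return list(g.outputs)


# ----------------------------------------------------------------------
# decode / NMS


def decode(
    raw_outputs: list[np.ndarray],
    input_size: int | tuple[int, int],
    strides: tuple[int, ...] = STRIDES,
    score_thresh: float = 0.0,
) -> list[DetBox]:
    """Turn raw head maps for one image into pixel-space detections.

    Each ``raw_outputs[l]`` has shape (5 + K, H_l, W_l) with channel layout
    [dx, dy, dw, dh, obj, cls...].  For grid cell (gx, gy) at stride s the
    box center is ((gx + dx) * s, (gy + dy) * s) and the size is
    (exp(dw) * s, exp(dh) * s); the score is sigmoid(obj) * sigmoid(cls),
    maximized over classes.  Boxes are corner-form and clipped to the image.
    """
    if isinstance(input_size, int):
        in_h = in_w = input_size
    else:
        in_h, in_w = input_size
    if len(raw_outputs) != len(strides):
        raise ValueError("one raw output map per stride required")
    dets: list[DetBox] = []
    for out, s in zip(raw_outputs, strides):
        _, h, w = out.shape
        if h * s != in_h or w * s != in_w:
            raise ValueError(f"grid {h}x{w} at stride {s} mismatches input {in_h}x{in_w}")
        gy, gx = np.mgrid[0:h, 0:w]
        cx = (gx + out[0]) * s
        cy = (gy + out[1]) * s
        bw = np.exp(np.clip(out[2], -40.0, 40.0)) * s
        bh = np.exp(np.clip(out[3], -40.0, 40.0)) * s
        obj = _sigmoid(out[4])
        cls = _sigmoid(out[5:])
        cid = np.argmax(cls, axis=0)
        score = obj * np.take_along_axis(cls, cid[None], axis=0)[0]
        x1 = np.clip(cx - bw / 2, 0, in_w)
        x2 = np.clip(cx + bw / 2, 0, in_w)
        y1 = np.clip(cy - bh / 2, 0, in_h)
        y2 = np.clip(cy + bh / 2, 0, in_h)
        keep = score >= score_thresh
        for yy, xx in zip(*np.nonzero(keep)):
            dets.append(
                DetBox(
                    class_id=int(cid[yy, xx]),
                    score=float(score[yy, xx]),
                    x1=float(x1[yy, xx]),
                    y1=float(y1[yy, xx]),
                    x2=float(x2[yy, xx]),
                    y2=float(y2[yy, xx]),
                )
            )
    return dets


def _sigmoid(x: np.ndarray) -> np.ndarray:
    z = np.exp(-np.abs(x))
    return np.where(x >= 0, 1.0 / (1.0 + z), z / (1.0 + z))


def box_iou(a, b) -> float:
    """Intersection-over-union of two corner-form boxes."""
    ix = max(0.0, min(a.x2, b.x2) - max(a.x1, b.x1))
    iy = max(0.0, min(a.y2, b.y2) - max(a.y1, b.y1))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


def nms(
    boxes: list[DetBox],
    iou_thresh: float = 0.45,
    score_thresh: float = 0.01,
) -> list[DetBox]:
    """Class-wise greedy non-maximum suppression.

    Candidates are visited in descending score order with deterministic
    tie-breaks (score, then box area, then x1); a candidate is kept if its
    IoU with every kept box of the same class is below ``iou_thresh``.
    """
    cand = [d for d in boxes if d.score >= score_thresh]
    cand.sort(key=lambda d: (-d.score, -d.area, d.x1))
    kept: list[DetBox] = []
    for d in cand:
        if all(box_iou(d, k) < iou_thresh for k in kept if k.class_id == d.class_id):
            kept.append(d)
    return kept
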