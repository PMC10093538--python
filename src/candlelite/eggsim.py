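"""Seeded synthetic candled-tray image generator.

A candled incubation tray photographed in a dark box shows a grid of glowing
ovoid eggs on a near-black background.  Around day five of incubation a
fertile egg shows a dark embryo spot with a branching network of blood
vessels radiating from it, while an infertile egg glows uniformly.  The
generator emulates exactly that: it samples a :class:`TrayScene` (grid
layout, per-egg geometry, fertility, glow, vessel-tree parameters) from a
seeded RNG and renders it deterministically — identical arguments and seed
give a bit-identical raster and box list.

Supported grids are 3x5, 5x7 and 7x9 (rows x cols); the default canvas is
1092x1080 like the acquisition camera, downscalable to any size.  The
default infertile fraction 840/2111 mirrors the stock the detector's
dataset was built from.

Augmentation reproduces the dataset-expansion protocol: each image yields
itself plus a right-angle rotation, a mirror and a contrast change — a x4
expansion with exactly remapped boxes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import line as _draw_line

from .detector import GTBox

__all__ = [
    "EggSpec",
    "TrayScene",
    "SUPPORTED_GRIDS",
    "INFERTILE_FRACTION",
    "sample_scene",
    "render_scene",
    "generate_tray",
    "augment",
    "expand_dataset",
]

SUPPORTED_GRIDS = ((3, 5), (5, 7), (7, 9))

#: default infertile-egg fraction: 840 infertile of 2111 eggs
INFERTILE_FRACTION = 840 / 2111

FERTILE, INFERTILE = 0, 1


@dataclass(frozen=True)
class EggSpec:
    """Geometry and appearance of one egg on the tray."""

    cx: float
    cy: float
    ax: float  # semi-axis along image x
    ay: float  # semi-axis along image y (eggs sit upright: ay > ax)
    angle: float  # radians, small tilt
    fertile: bool
    glow: float  # peak brightness, 0..255
    spot_dx: float = 0.0  # embryo spot offset, fraction of semi-axes
    spot_dy: float = 0.0
    spot_r: float = 0.0  # embryo spot radius, pixels
    n_vessels: int = 0
    tortuosity: float = 0.25
    vessel_seed: int = 0


@dataclass
class TrayScene:
    """Generative description of one synthetic tray."""

    rows: int
    cols: int
    width: int
    height: int
    eggs: list[EggSpec] = field(default_factory=list)
    background: float = 12.0
    noise: float = 3.0
    seed: int = 0


def sample_scene(
    rows: int,
    cols: int,
    seed: int,
    width: int = 1092,
    height: int = 1080,
    infertile_frac: float = INFERTILE_FRACTION,
    margin: float = 0.10,
    background: float = 12.0,
    noise: float = 3.0,
) -> TrayScene:
    """Draw a random tray layout; eggs stay inside their grid cells."""
    if (rows, cols) not in SUPPORTED_GRIDS:
        raise ValueError(f"unsupported grid {rows}x{cols}; use one of {SUPPORTED_GRIDS}")
    cell_w, cell_h = width / cols, height / rows
    if min(cell_w, cell_h) < 12:
        raise ValueError(f"grid {rows}x{cols} too dense for a {width}x{height} image")
    rng = np.random.default_rng(seed)
    eggs: list[EggSpec] = []
    for r in range(rows):
        for c in range(cols):
            cx = (c + 0.5) * cell_w + rng.uniform(-0.03, 0.03) * cell_w
            cy = (r + 0.5) * cell_h + rng.uniform(-0.03, 0.03) * cell_h
            ay = 0.5 * cell_h * (1 - margin) * rng.uniform(0.88, 0.98)
            ax = ay * rng.uniform(0.68, 0.78)
            ax = min(ax, 0.5 * cell_w * (1 - margin))
            fertile = rng.random() >= infertile_frac
            glow = rng.uniform(190.0, 240.0)
            spot_r = 0.0
            spot_dx = spot_dy = 0.0
            n_vessels = 0
            if fertile:
                spot_r = rng.uniform(0.16, 0.24) * ax
                spot_dx = rng.uniform(-0.3, 0.3)
                spot_dy = rng.uniform(-0.35, 0.1)
                n_vessels = int(rng.integers(3, 6))
            eggs.append(
                EggSpec(
                    cx=cx, cy=cy, ax=ax, ay=ay,
                    angle=rng.uniform(-0.12, 0.12),
                    fertile=fertile, glow=glow,
                    spot_dx=spot_dx, spot_dy=spot_dy, spot_r=spot_r,
                    n_vessels=n_vessels,
                    tortuosity=rng.uniform(0.15, 0.35),
                    vessel_seed=int(rng.integers(0, 2**31 - 1)),
                )
            )
    return TrayScene(rows=rows, cols=cols, width=width, height=height, eggs=eggs,
                     background=background, noise=noise, seed=seed)


# candling transmits mostly red/orange light
_TINT = np.array([1.0, 0.52, 0.16])


def render_scene(scene: TrayScene) -> tuple[np.ndarray, list[GTBox]]:
    """Rasterize a scene; returns (H, W, 3) uint8 image and tight boxes."""
    h, w = scene.height, scene.width
    img = np.zeros((h, w), dtype=np.float64)
    boxes: list[GTBox] = []
    for egg in scene.eggs:
        _render_egg(img, egg, h, w)
        boxes.append(_egg_box(egg, h, w))
    rng = np.random.default_rng(scene.seed ^ 0x5EED)
    img += scene.background + rng.normal(0.0, scene.noise, size=img.shape)
    rgb = np.clip(img[..., None] * _TINT[None, None], 0, 255).astype(np.uint8)
    return rgb, boxes


def _egg_frame(egg: EggSpec):
    ca, sa = np.cos(egg.angle), np.sin(egg.angle)
    return ca, sa


def _egg_box(egg: EggSpec, h: int, w: int) -> GTBox:
    """Tight axis-aligned bounds of the rotated ellipse, clipped."""
    ca, sa = _egg_frame(egg)
    half_w = np.hypot(egg.ax * ca, egg.ay * sa)
    half_h = np.hypot(egg.ax * sa, egg.ay * ca)
    return GTBox(
        class_id=FERTILE if egg.fertile else INFERTILE,
        x1=max(0.0, egg.cx - half_w),
        y1=max(0.0, egg.cy - half_h),
        x2=min(float(w), egg.cx + half_w),
        y2=min(float(h), egg.cy + half_h),
    )


def _render_egg(img: np.ndarray, egg: EggSpec, h: int, w: int) -> None:
    box = _egg_box(egg, h, w)
    x0, x1 = int(np.floor(box.x1)), int(np.ceil(box.x2))
    y0, y1 = int(np.floor(box.y1)), int(np.ceil(box.y2))
    ys, xs = np.mgrid[y0:y1, x0:x1]
    ca, sa = _egg_frame(egg)
    dx, dy = xs - egg.cx, ys - egg.cy
    u = ((dx * ca + dy * sa) / egg.ax) ** 2 + ((-dx * sa + dy * ca) / egg.ay) ** 2
    inside = u < 1.0
    # translucent glow: bright center, soft rim
    shade = np.zeros_like(u)
    shade[inside] = egg.glow * (1.0 - 0.30 * u[inside]) * np.clip((1.0 - u[inside]) * 6.0, 0.0, 1.0)
    if egg.fertile:
        _shade_embryo(shade, egg, xs, ys, u)
    img[y0:y1, x0:x1] += shade


def _shade_embryo(shade: np.ndarray, egg: EggSpec, xs, ys, u) -> None:
    """Dark embryo spot plus a branching random-walk vessel tree."""
    sx = egg.cx + egg.spot_dx * egg.ax
    sy = egg.cy + egg.spot_dy * egg.ay
    d2 = (xs - sx) ** 2 + (ys - sy) ** 2
    spot = np.clip(1.0 - d2 / (egg.spot_r**2 + 1e-9), 0.0, 1.0)
    shade *= 1.0 - 0.72 * np.sqrt(spot)
    rng = np.random.default_rng(egg.vessel_seed)
    mask = np.zeros(shade.shape, dtype=bool)
    x_off, y_off = xs[0, 0], ys[0, 0]
    hh, ww = shade.shape
    step = max(2.0, 0.09 * egg.ay)
    for _ in range(egg.n_vessels):
        theta = rng.uniform(0, 2 * np.pi)
        px, py = sx, sy
        for _ in range(int(rng.integers(6, 12))):
            theta += rng.normal(0.0, egg.tortuosity)
            nx, ny = px + step * np.cos(theta), py + step * np.sin(theta)
            # stop near the shell
            ue = (((nx - egg.cx)) / egg.ax) ** 2 + (((ny - egg.cy)) / egg.ay) ** 2
            if ue > 0.80:
                break
            rr, cc = _draw_line(int(round(py - y_off)), int(round(px - x_off)),
                                int(round(ny - y_off)), int(round(nx - x_off)))
            ok = (rr >= 0) & (rr < hh) & (cc >= 0) & (cc < ww)
            mask[rr[ok], cc[ok]] = True
            if rng.random() < 0.25:  # spawn a side branch
                _branch(mask, rng, nx, ny, theta + rng.choice([-1, 1]) * rng.uniform(0.6, 1.2),
                        egg, step, x_off, y_off)
            px, py = nx, ny
    # thicken by one pixel down-right and darken
    thick = mask.copy()
    thick[1:, :] |= mask[:-1, :]
    thick[:, 1:] |= mask[:, :-1]
    shade[thick] *= 0.45


def _branch(mask, rng, px, py, theta, egg, step, x_off, y_off) -> None:
    hh, ww = mask.shape
    for _ in range(int(rng.integers(3, 7))):
        theta += rng.normal(0.0, egg.tortuosity)
        nx, ny = px + step * np.cos(theta), py + step * np.sin(theta)
        ue = ((nx - egg.cx) / egg.ax) ** 2 + ((ny - egg.cy) / egg.ay) ** 2
        if ue > 0.80:
            break
        rr, cc = _draw_line(int(round(py - y_off)), int(round(px - x_off)),
                            int(round(ny - y_off)), int(round(nx - x_off)))
        ok = (rr >= 0) & (rr < hh) & (cc >= 0) & (cc < ww)
        mask[rr[ok], cc[ok]] = True
        px, py = nx, ny


def generate_tray(rows: int, cols: int, seed: int, **options) -> tuple[np.ndarray, list[GTBox]]:
    """Sample and render one tray; returns (image, ground-truth boxes)."""
    scene = sample_scene(rows, cols, seed, **options)
    return render_scene(scene)


# ----------------------------------------------------------------------
# augmentation


def augment(
    image: np.ndarray,
    boxes: list[GTBox],
    op: str,
    params: dict | None = None,
) -> tuple[np.ndarray, list[GTBox]]:
    """Apply one augmentation with exact box remapping.

    ``rotate`` (params: angle in {90, 180, 270}, counter-clockwise),
    ``mirror`` (horizontal flip) or ``contrast`` (params: factor, linear
    stretch about mid-grey; boxes untouched).
    """
    params = params or {}
    h, w = image.shape[:2]
    if op == "rotate":
        angle = params.get("angle", 90)
        if angle not in (90, 180, 270):
            raise ValueError(f"unsupported rotation angle {angle}")
        k = angle // 90
        out = np.rot90(image, k=k).copy()
        new = list(boxes)
        cur_w = w
        for _ in range(k):
            new = [_rot90_box(b, cur_w) for b in new]
            cur_w, h = h, cur_w  # canvas transposes each quarter turn
        return out, new
    if op == "mirror":
        out = image[:, ::-1].copy()
        return out, [
            GTBox(b.class_id, w - b.x2, b.y1, w - b.x1, b.y2) for b in boxes
        ]
    if op == "contrast":
        factor = params.get("factor", 1.3)
        arr = image.astype(np.float64)
        out = np.clip((arr - 127.5) * factor + 127.5, 0, 255).astype(image.dtype)
        return out, list(boxes)
    raise ValueError(f"unknown augmentation op {op!r}")


def _rot90_box(b: GTBox, w: int) -> GTBox:
    """Counter-clockwise quarter turn: (x, y) -> (y, w - x)."""
    return GTBox(b.class_id, b.y1, w - b.x2, b.y2, w - b.x1)


def expand_dataset(
    records: list[tuple[np.ndarray, list[GTBox]]],
    seed: int = 0,
) -> list[tuple[np.ndarray, list[GTBox]]]:
    """x4 expansion: each record plus one rotation, one mirror, one contrast.

    Augmentation parameters are drawn per record from ``seed``, so the
    expansion is deterministic.  Output order is original-major.
    """
    rng = np.random.default_rng(seed)
    out = []
    for image, boxes in records:
        angle = int(rng.choice([90, 180, 270]))
        factor = float(rng.uniform(1.15, 1.45))
        out.append((image, list(boxes)))
        out.append(augment(image, boxes, "rotate", {"angle": angle}))
        out.append(augment(image, boxes, "mirror"))
        out.append(augment(image, boxes, "contrast", {"factor": factor}))
    return out
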