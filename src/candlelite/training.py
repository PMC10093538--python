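"""Training: cosine-annealing schedule with a switch-off tail, anchor-free
detection loss, and an SGD loop over synthetic trays.

The learning rate follows cosine annealing with warm restarts,
``eta = eta_min + (eta_max - eta_min) * (1 + cos(pi * T_cur / T_i)) / 2``,
restarting every ``T_i`` epochs so the rate climbs back to its maximum and
can pull the model off saddle plateaus.  For the final
``cosine_off_tail`` epochs annealing is switched off and the rate is held
constant at ``eta_min`` so the model settles near the optimum.

The loss is the standard anchor-free trio: an IoU loss (1 - IoU) on
positive cells, binary cross-entropy on objectness over all cells, and
binary cross-entropy on class scores over positives.  A cell is positive
for a ground-truth box when its center lies inside the box and within a
fixed radius of 2.5 strides of the box center (a deterministic
center-prior assignment); cells qualifying for several boxes take the
smallest one.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .detector import DetBox, GTBox, ModelConfig, build_model, decode, nms, STRIDES
from .evaluation import evaluate_detections
from .nn import Network

__all__ = [
    "SchedulerConfig",
    "TrainConfig",
    "cosine_lr",
    "lr_schedule",
    "assign_cells",
    "detection_loss",
    "to_input",
    "synthetic_dataset",
    "train",
]


@dataclass
class SchedulerConfig:
    eta_min: float = 1e-5
    eta_max: float = 1e-3  # = initial learning rate
    T_i: int = 50  # restart cycle length, epochs
    T_cur: int = 0  # position within the cycle
    total_epochs: int = 600
    cosine_off_tail: int = 70  # final epochs with annealing disabled
    tail_mode: str = "eta_min"  # or "last_cosine"

    def __post_init__(self) -> None:
        if self.T_i <= 0:
            raise ValueError("cycle length T_i must be positive")
        if not (0 <= self.eta_min <= self.eta_max):
            raise ValueError("need 0 <= eta_min <= eta_max")
        if not (0 <= self.T_cur <= self.T_i):
            raise ValueError("T_cur must lie in [0, T_i]")


@dataclass
class TrainConfig:
    lr: float = 0.001
    weight_decay: float = 0.0005
    momentum: float = 0.9
    epochs: int = 600
    batch_size: int = 2
    optimizer: str = "sgd"
    input_size: int = 640


def cosine_lr(cfg: SchedulerConfig, t_cur: int | None = None) -> float:
    """Annealed rate at cycle position ``t_cur`` (defaults to cfg.T_cur)."""
    t = cfg.T_cur if t_cur is None else t_cur
    if not 0 <= t <= cfg.T_i:
        raise ValueError(f"T_cur {t} outside [0, {cfg.T_i}]")
    return cfg.eta_min + 0.5 * (cfg.eta_max - cfg.eta_min) * (1 + math.cos(math.pi * t / cfg.T_i))


def lr_schedule(epoch: int, train_cfg: TrainConfig, sched_cfg: SchedulerConfig) -> float:
    """Learning rate for an epoch: cosine with restarts, then a flat tail."""
    total = sched_cfg.total_epochs
    if not 0 <= epoch < total:
        raise ValueError(f"epoch {epoch} outside [0, {total})")
    tail_start = total - sched_cfg.cosine_off_tail
    if epoch >= tail_start:
        if sched_cfg.tail_mode == "last_cosine":
            return cosine_lr(sched_cfg, (tail_start - 1) % sched_cfg.T_i)
        return sched_cfg.eta_min
    return cosine_lr(sched_cfg, epoch % sched_cfg.T_i)


# ----------------------------------------------------------------------
# label assignment and loss


def assign_cells(
    gts: list[GTBox],
    input_size: int,
    strides: tuple[int, ...] = STRIDES,
    center_radius: float = 2.5,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per level: (positive mask (H,W), assigned gt index (H,W), -1 if none).

    A cell is positive for a box when the cell center lies inside the box
    and within ``center_radius * stride`` of the box center (Chebyshev
    distance); ties go to the smallest box.
    """
    out = []
    if gts:
        gx1 = np.array([g.x1 for g in gts])
        gy1 = np.array([g.y1 for g in gts])
        gx2 = np.array([g.x2 for g in gts])
        gy2 = np.array([g.y2 for g in gts])
        gcx, gcy = (gx1 + gx2) / 2, (gy1 + gy2) / 2
        areas = (gx2 - gx1) * (gy2 - gy1)
    for s in strides:
        n = input_size // s
        cy, cx = (np.mgrid[0:n, 0:n] + 0.5) * s
        if not gts:
            out.append((np.zeros((n, n), bool), np.full((n, n), -1)))
            continue
        inside = (
            (cx[None] >= gx1[:, None, None]) & (cx[None] < gx2[:, None, None])
            & (cy[None] >= gy1[:, None, None]) & (cy[None] < gy2[:, None, None])
        )
        near = (
            (np.abs(cx[None] - gcx[:, None, None]) <= center_radius * s)
            & (np.abs(cy[None] - gcy[:, None, None]) <= center_radius * s)
        )
        qual = inside & near
        cost = np.where(qual, areas[:, None, None], np.inf)
        assigned = np.argmin(cost, axis=0)
        pos = qual.any(axis=0)
        assigned = np.where(pos, assigned, -1)
        out.append((pos, assigned))
    return out


def _stable_bce(z: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Elementwise binary cross-entropy with logits."""
    return np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))


def detection_loss(
    outputs: list[np.ndarray],
    gts: list[list[GTBox]],
    input_size: int,
    strides: tuple[int, ...] = STRIDES,
    center_radius: float = 2.5,
    num_classes: int = 2,
):
    """Loss, per-component values, and analytic gradients w.r.t. raw maps.

    ``outputs[l]`` is (N, 5 + K, H_l, W_l) with channels
    [dx, dy, dw, dh, obj, cls...].  Returns
    ``(total, components, grads)`` where components reports the IoU,
    objectness and class terms plus the positive count, and ``grads``
    mirrors ``outputs``.  All terms are normalized by the number of
    positive cells in the batch (an image with no ground truth contributes
    an objectness-only loss).
    """
    n_img = outputs[0].shape[0]
    if len(gts) != n_img:
        raise ValueError("one ground-truth list per image required")
    assigns = [assign_cells(g, input_size, strides, center_radius) for g in gts]
    n_pos = sum(int(a[l][0].sum()) for a in assigns for l in range(len(strides)))
    norm = max(n_pos, 1)
    grads = [np.zeros_like(o) for o in outputs]
    loss_iou = loss_obj = loss_cls = 0.0
    for l, s in enumerate(strides):
        out = outputs[l]
        g = grads[l]
        for i in range(n_img):
            pos, assigned = assigns[i][l]
            # objectness over every cell
            z = out[i, 4]
            t = pos.astype(out.dtype)
            loss_obj += float(_stable_bce(z, t).sum()) / norm
            g[i, 4] = (_sigmoid(z) - t) / norm
            if not pos.any():
                continue
            yy, xx = np.nonzero(pos)
            idx = assigned[yy, xx]
            boxes = [gts[i][j] for j in idx]
            gx1 = np.array([b.x1 for b in boxes])
            gy1 = np.array([b.y1 for b in boxes])
            gx2 = np.array([b.x2 for b in boxes])
            gy2 = np.array([b.y2 for b in boxes])
            dx, dy = out[i, 0, yy, xx], out[i, 1, yy, xx]
            dw, dh = out[i, 2, yy, xx], out[i, 3, yy, xx]
            cx, cy = (xx + dx) * s, (yy + dy) * s
            pw, ph = np.exp(dw) * s, np.exp(dh) * s
            x1, x2 = cx - pw / 2, cx + pw / 2
            y1, y2 = cy - ph / 2, cy + ph / 2
            iw = np.minimum(x2, gx2) - np.maximum(x1, gx1)
            ih = np.minimum(y2, gy2) - np.maximum(y1, gy1)
            iwp, ihp = np.maximum(iw, 0), np.maximum(ih, 0)
            inter = iwp * ihp
            area_p = pw * ph
            area_g = (gx2 - gx1) * (gy2 - gy1)
            union = area_p + area_g - inter + 1e-9
            iou = inter / union
            loss_iou += float((1 - iou).sum()) / norm
            # partials of I and A w.r.t. the four predicted corners
            dI_x1 = -ihp * ((x1 > gx1) & (iw > 0))
            dI_x2 = ihp * ((x2 < gx2) & (iw > 0))
            dI_y1 = -iwp * ((y1 > gy1) & (ih > 0))
            dI_y2 = iwp * ((y2 < gy2) & (ih > 0))
            dA_x1, dA_x2 = -ph, ph
            dA_y1, dA_y2 = -pw, pw

            def diou(dI, dA):
                dU = dA - dI
                return (dI * union - inter * dU) / union**2

            di_x1, di_x2 = diou(dI_x1, dA_x1), diou(dI_x2, dA_x2)
            di_y1, di_y2 = diou(dI_y1, dA_y1), diou(dI_y2, dA_y2)
            # chain to (dx, dy, dw, dh); loss is -(iou)/norm
            g[i, 0, yy, xx] = -(di_x1 + di_x2) * s / norm
            g[i, 1, yy, xx] = -(di_y1 + di_y2) * s / norm
            g[i, 2, yy, xx] = -(di_x2 - di_x1) * (pw / 2) / norm
            g[i, 3, yy, xx] = -(di_y2 - di_y1) * (ph / 2) / norm
            # class scores on positives
            cls_z = out[i, 5:, yy, xx]  # (P, K): advanced dims lead
            onehot = np.zeros_like(cls_z)
            cls_ids = np.array([b.class_id for b in boxes])
            onehot[np.arange(len(boxes)), cls_ids] = 1.0
            loss_cls += float(_stable_bce(cls_z, onehot).sum()) / norm
            g[i, 5:, yy, xx] = (_sigmoid(cls_z) - onehot) / norm
    total = loss_iou + loss_obj + loss_cls
    comps = {"iou": loss_iou, "obj": loss_obj, "cls": loss_cls, "n_pos": n_pos}
    return total, comps, grads


def _sigmoid(x: np.ndarray) -> np.ndarray:
    z = np.exp(-np.abs(x))
    return np.where(x >= 0, 1.0 / (1.0 + z), z / (1.0 + z))


# ----------------------------------------------------------------------
# data plumbing


def to_input(image: np.ndarray) -> np.ndarray:
    """(H, W, 3) uint8 raster -> (3, H, W) float32 in [0, 1]."""
    return (image.astype(np.float32) / 255.0).transpose(2, 0, 1)


def synthetic_dataset(
    n_trays: int,
    rows: int,
    cols: int,
    seed: int,
    image_size: int,
    **options,
) -> list[tuple[np.ndarray, list[GTBox]]]:
    """Render ``n_trays`` seeded trays directly at a square training size."""
    from .eggsim import generate_tray

    data = []
    for i in range(n_trays):
        img, boxes = generate_tray(
            rows, cols, seed + i, width=image_size, height=image_size, **options
        )
        data.append((to_input(img), boxes))
    return data


# ----------------------------------------------------------------------
# training loop


def evaluate_model(
    net: Network,
    data: list[tuple[np.ndarray, list[GTBox]]],
    input_size: int,
    score_thresh: float = 0.05,
    iou_thresh: float = 0.45,
    match_iou: float = 0.5,
) -> float:
    """mAP@0.5 of a network over an in-memory dataset."""
    preds: list[list[DetBox]] = []
    gts: list[list[GTBox]] = []
    for x, g in data:
        outs = net.forward(x[None], train=False)
        dets = decode([o[0] for o in outs], input_size, score_thresh=score_thresh)
        preds.append(nms(dets, iou_thresh=iou_thresh, score_thresh=score_thresh))
        gts.append(g)
    return evaluate_detections(preds, gts, iou_thresh=match_iou).map


def train(
    model_cfg: ModelConfig,
    train_data: list[tuple[np.ndarray, list[GTBox]]],
    train_cfg: TrainConfig,
    sched_cfg: SchedulerConfig | None = None,
    val_data: list[tuple[np.ndarray, list[GTBox]]] | None = None,
    seed: int = 0,
    eval_every: int = 10,
    log_csv: str | Path | None = None,
    verbose: bool = False,
):
    """Train a detector; returns (network, history, best_val_map).

    Reproducible for a fixed seed: initialization, shuffling and the data
    are all driven by it.  Divergence (non-finite loss) aborts with a
    diagnostic.  The best checkpoint (by validation mAP) is restored into
    the returned network when validation data is given.
    """
    if sched_cfg is None:
        sched_cfg = SchedulerConfig(
            eta_max=train_cfg.lr, total_epochs=train_cfg.epochs,
            cosine_off_tail=min(70, max(0, train_cfg.epochs - 1)),
            T_i=min(50, train_cfg.epochs),
        )
    graph = build_model(model_cfg)
    rng = np.random.default_rng(seed)
    net = Network(graph, seed=int(rng.integers(0, 2**31 - 1)))
    vel = {nid: {k: np.zeros_like(v) for k, v in p.items()} for nid, p in net.params.items()}
    size = model_cfg.input_size
    history: list[dict] = []
    best_map, best_state = -1.0, None
    for epoch in range(train_cfg.epochs):
        lr = lr_schedule(epoch, train_cfg, sched_cfg)
        order = rng.permutation(len(train_data))
        ep_loss, ep_comps = 0.0, {"iou": 0.0, "obj": 0.0, "cls": 0.0}
        n_batches = 0
        for start in range(0, len(order), train_cfg.batch_size):
            idx = order[start:start + train_cfg.batch_size]
            xb = np.stack([train_data[i][0] for i in idx])
            gb = [train_data[i][1] for i in idx]
            outs = net.forward(xb, train=True)
            loss, comps, gouts = detection_loss(outs, gb, size, num_classes=model_cfg.num_classes)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"diverged at epoch {epoch}: loss={loss} components={comps}"
                )
            grads = net.backward(gouts)
            for nid, p in net.params.items():
                gp = grads.get(nid)
                if gp is None:
                    continue
                for k, w in p.items():
                    gk = gp[k] + train_cfg.weight_decay * w
                    vel[nid][k] = train_cfg.momentum * vel[nid][k] - lr * gk
                    w += vel[nid][k]
            ep_loss += loss
            for k in ep_comps:
                ep_comps[k] += comps[k]
            n_batches += 1
        row = {
            "epoch": epoch,
            "lr": lr,
            "loss": ep_loss / n_batches,
            **{k: v / n_batches for k, v in ep_comps.items()},
            "val_map": float("nan"),
        }
        last = epoch == train_cfg.epochs - 1
        if val_data is not None and (epoch % eval_every == eval_every - 1 or last):
            vmap = evaluate_model(net, val_data, size)
            row["val_map"] = vmap
            if vmap > best_map:
                best_map = vmap
                best_state = {k: v.copy() for k, v in net.state_dict().items()}
        history.append(row)
        if verbose:
            print(
                f"epoch {epoch:3d} lr {lr:.5f} loss {row['loss']:.3f} "
                f"(iou {row['iou']:.3f} obj {row['obj']:.3f} cls {row['cls']:.3f})"
                + (f" val mAP {row['val_map']:.3f}" if not math.isnan(row["val_map"]) else "")
            )
    if best_state is not None:
        net.load_state_dict(best_state)
    if log_csv is not None:
        path = Path(log_csv)
        with path.open("w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(history[0].keys()))
            writer.writeheader()
            writer.writerows(history)
    return net, history, best_map


def train_config_dict(model_cfg: ModelConfig, train_cfg: TrainConfig) -> dict:
    """JSON-serializable description saved next to checkpoints."""
    return {"model": asdict(model_cfg), "train": asdict(train_cfg)}
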