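"""Scheduler analytics, detection loss, and training-loop contracts."""

import math

import numpy as np
import pytest

from candlelite.detector import GTBox, ModelConfig
from candlelite.training import (
    SchedulerConfig,
    TrainConfig,
    assign_cells,
    cosine_lr,
    detection_loss,
    lr_schedule,
    synthetic_dataset,
    train,
)


class TestCosineSchedule:
    def test_start_at_eta_max(self):
        cfg = SchedulerConfig(eta_min=0.0, eta_max=0.001)
        assert cosine_lr(cfg, 0) == 0.001

    def test_end_of_cycle_at_eta_min(self):
        cfg = SchedulerConfig(eta_min=1e-5, eta_max=0.001)
        assert cosine_lr(cfg, cfg.T_i) == pytest.approx(1e-5)

    def test_midpoint(self):
        cfg = SchedulerConfig(eta_min=0.0, eta_max=0.001, T_i=50)
        assert cosine_lr(cfg, 25) == pytest.approx(0.0005)

    def test_monotone_decreasing_within_cycle(self):
        cfg = SchedulerConfig(eta_min=1e-5, eta_max=0.001, T_i=40)
        vals = [cosine_lr(cfg, t) for t in range(41)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_zero_cycle_length_rejected(self):
        with pytest.raises(ValueError):
            SchedulerConfig(T_i=0)


class TestLrSchedule:
    def test_epoch_zero_equals_initial_lr(self):
        tc, sc = TrainConfig(), SchedulerConfig()
        assert lr_schedule(0, tc, sc) == 0.001

    def test_tail_is_constant_eta_min(self):
        tc, sc = TrainConfig(), SchedulerConfig()
        tail = [lr_schedule(e, tc, sc) for e in range(600 - 70, 600)]
        assert len(set(tail)) == 1 and tail[0] == sc.eta_min

    def test_periodic_with_restarts_before_tail(self):
        tc, sc = TrainConfig(), SchedulerConfig(T_i=50)
        for e in range(0, 400):
            assert lr_schedule(e, tc, sc) == pytest.approx(
                lr_schedule(e % 50, tc, sc)
            )

    def test_epoch_out_of_range(self):
        with pytest.raises(ValueError):
            lr_schedule(600, TrainConfig(), SchedulerConfig())


def _blank_outputs(size, n=1, fill=-30.0):
    outs = []
    for s in (8, 16, 32):
        o = np.full((n, 7, size // s, size // s), fill)
        o[:, :4] = 0.0
        outs.append(o)
    return outs


class TestDetectionLoss:
    def test_perfect_prediction_is_zero(self):
        size = 64
        gt = GTBox(0, 8, 8, 40, 40)
        outs = _blank_outputs(size)
        assigns = assign_cells([gt], size)
        for l, s in enumerate((8, 16, 32)):
            pos, _ = assigns[l]
            yy, xx = np.nonzero(pos)
            cx, cy = (gt.x1 + gt.x2) / 2, (gt.y1 + gt.y2) / 2
            outs[l][0, 0, yy, xx] = cx / s - xx
            outs[l][0, 1, yy, xx] = cy / s - yy
            outs[l][0, 2, yy, xx] = np.log((gt.x2 - gt.x1) / s)
            outs[l][0, 3, yy, xx] = np.log((gt.y2 - gt.y1) / s)
            outs[l][0, 4, yy, xx] = 30.0  # saturated objectness
            outs[l][0, 5, yy, xx] = 30.0  # saturated fertile logit
        total, comps, _ = detection_loss(outs, [[gt]], size)
        assert total == pytest.approx(0.0, abs=1e-9)

    def test_background_only_limit(self):
        """No ground truth and strongly negative logits: loss tends to 0."""
        total, comps, _ = detection_loss(_blank_outputs(64, fill=-30.0), [[]], 64)
        assert comps["n_pos"] == 0
        assert total == pytest.approx(0.0, abs=1e-9)

    def test_iou_half_gives_component_half(self):
        size = 64
        # one tiny GT covering exactly one stride-8 cell center (12, 12)
        gt = GTBox(0, 10, 10, 14, 14)
        assigns = assign_cells([gt], size)
        n_pos = sum(int(a[0].sum()) for a in assigns)
        assert n_pos == 1
        outs = _blank_outputs(size)
        # predicted box: same center, same height, double width -> IoU 0.5
        outs[0][0, 0, 1, 1] = 12 / 8 - 1
        outs[0][0, 1, 1, 1] = 12 / 8 - 1
        outs[0][0, 2, 1, 1] = np.log(8 / 8)
        outs[0][0, 3, 1, 1] = np.log(4 / 8)
        _, comps, _ = detection_loss(outs, [[gt]], size)
        assert comps["iou"] == pytest.approx(0.5, abs=1e-9)

    def test_gradients_match_finite_differences(self, rng):
        size = 64
        outs = [rng.normal(size=(2, 7, size // s, size // s)) * 0.5 for s in (8, 16, 32)]
        gts = [[GTBox(0, 10, 8, 40, 30), GTBox(1, 30, 35, 60, 60)], []]
        _, _, grads = detection_loss(outs, gts, size)
        eps = 1e-6
        for l in range(3):
            for _ in range(15):
                i = rng.integers(0, 2)
                c = rng.integers(0, 7)
                y = rng.integers(0, outs[l].shape[2])
                x = rng.integers(0, outs[l].shape[3])
                outs[l][i, c, y, x] += eps
                lp, _, _ = detection_loss(outs, gts, size)
                outs[l][i, c, y, x] -= 2 * eps
                lm, _, _ = detection_loss(outs, gts, size)
                outs[l][i, c, y, x] += eps
                num = (lp - lm) / (2 * eps)
                ana = grads[l][i, c, y, x]
                assert abs(num - ana) <= 1e-5 * (abs(num) + abs(ana)) + 1e-9


class TestAssignment:
    def test_cells_inside_and_near_center_only(self):
        size = 64
        gt = GTBox(0, 0, 0, 64, 64)  # whole image
        (pos8, _), (pos16, _), (pos32, _) = assign_cells([gt], size)
        # stride 8: center prior limits positives to a 5-cell-radius window
        assert pos8.sum() > 0
        cy = cx = 32
        yy, xx = np.nonzero(pos8)
        assert np.all(np.abs((xx + 0.5) * 8 - cx) <= 2.5 * 8)
        assert np.all(np.abs((yy + 0.5) * 8 - cy) <= 2.5 * 8)

    def test_smallest_box_wins_ties(self):
        size = 64
        big = GTBox(0, 0, 0, 64, 64)
        small = GTBox(1, 24, 24, 40, 40)
        (pos8, a8), *_ = assign_cells([big, small], size)
        yy, xx = np.nonzero(pos8)
        for y, x in zip(yy, xx):
            cx, cy = (x + 0.5) * 8, (y + 0.5) * 8
            if small.x1 <= cx < small.x2 and small.y1 <= cy < small.y2:
                assert a8[y, x] == 1


@pytest.fixture(scope="module")
def tiny_setup():
    size = 64
    data = synthetic_dataset(4, 3, 5, seed=5, image_size=size)
    cfg = ModelConfig("lda_s", dw=True, use_eca=True, input_size=size)
    tc = TrainConfig(lr=0.01, epochs=2, batch_size=2, input_size=size)
    sc = SchedulerConfig(eta_max=0.01, T_i=2, total_epochs=2, cosine_off_tail=0)
    return size, data, cfg, tc, sc


class TestTrainLoop:
    def test_same_seed_reproduces_epoch_losses(self, tiny_setup):
        size, data, cfg, tc, sc = tiny_setup
        _, h1, _ = train(cfg, data, tc, sc, seed=3)
        _, h2, _ = train(cfg, data, tc, sc, seed=3)
        assert h1[0]["loss"] == h2[0]["loss"]
        assert h1[-1]["loss"] == h2[-1]["loss"]

    def test_lr_trace_equals_schedule(self, tiny_setup):
        size, data, cfg, tc, sc = tiny_setup
        _, hist, _ = train(cfg, data, tc, sc, seed=3)
        for row in hist:
            assert row["lr"] == lr_schedule(row["epoch"], tc, sc)

    def test_metric_log_written(self, tiny_setup, tmp_path):
        size, data, cfg, tc, sc = tiny_setup
        train(cfg, data, tc, sc, seed=1, log_csv=tmp_path / "log.csv")
        lines = (tmp_path / "log.csv").read_text().strip().splitlines()
        assert lines[0].startswith("epoch,lr,loss")
        assert len(lines) == 1 + tc.epochs
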