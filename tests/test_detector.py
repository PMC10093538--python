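"""Detector assembly, box decode and non-maximum suppression."""

import itertools

import numpy as np
import pytest

from candlelite.detector import (
    DetBox,
    MODEL_PRESETS,
    ModelConfig,
    box_iou,
    build_model,
    decode,
    nms,
)
from candlelite.graphspec import count_params

MODEL_PARAMS = {
    ModelConfig("tiny", dw=False, use_eca=False): 5_033_157,  # 5.033 M
    ModelConfig("tiny", dw=True, use_eca=False): 1_991_301,  # 1.991 M
    ModelConfig("lda_m", dw=True, use_eca=False): 1_959_789,  # 1.960 M
    ModelConfig("lda_s", dw=True, use_eca=False): 1_934_589,  # 1.935 M
    ModelConfig("lda_s", dw=True, use_eca=True): 1_934_602,  # 1.935 M
}


class TestModelSizes:
    @pytest.mark.parametrize("cfg,expected", list(MODEL_PARAMS.items()))
    def test_full_model_parameter_counts(self, cfg, expected):
        assert count_params(build_model(cfg)).params_total == expected

    def test_eca_adds_at_most_13_params(self):
        base = count_params(build_model(ModelConfig("lda_s", True, False))).params_total
        eca = count_params(build_model(ModelConfig("lda_s", True, True))).params_total
        assert 0 < eca - base <= 13

    def test_presets_cover_the_final_model(self):
        lda = MODEL_PRESETS["lda"]
        assert (lda.backbone_variant, lda.dw, lda.use_eca) == ("lda_s", True, True)


def _grids(size, strides=(8, 16, 32)):
    return [(size // s, size // s) for s in strides]


class TestDecode:
    def test_candidate_count_at_640(self):
        outs = [np.zeros((7, h, w)) for h, w in _grids(640)]
        dets = decode(outs, 640)
        assert len(dets) == 80**2 + 40**2 + 20**2 == 8_400

    def test_decode_rule_single_cell(self):
        outs = [np.full((7, h, w), -20.0) for h, w in _grids(64)]
        for o in outs:
            o[:4] = 0.0
        outs[0][0, 3, 4] = 0.5  # dx
        outs[0][1, 3, 4] = 0.25  # dy
        dets = decode(outs, 64)
        d = max(dets, key=lambda d: (d.x1 == 36 - 4))
        cell = [b for b in dets if b.x1 == pytest.approx(36 - 4) and b.y1 == pytest.approx(26 - 4)]
        assert cell, "decoded center (36, 26) with 8x8 box expected"
        b = cell[0]
        assert (b.x2 - b.x1, b.y2 - b.y1) == (pytest.approx(8.0), pytest.approx(8.0))

    def test_zero_cell_clipped_at_origin(self):
        outs = [np.zeros((7, h, w)) for h, w in _grids(64)]
        dets = decode(outs, 64)
        corner = min(dets, key=lambda d: (d.y1, d.x1))
        assert (corner.x1, corner.y1) == (0.0, 0.0)
        assert corner.x2 == pytest.approx(4.0)  # half of the stride-8 box survives clipping

    def test_encode_decode_identity_on_grid_centers(self):
        """Boxes synthesized on grid cells re-decode to themselves."""
        rng = np.random.default_rng(0)
        size, s = 128, 8
        h = w = size // s
        out8 = rng.normal(size=(7, h, w)) * 0.0
        dx, dy = rng.uniform(0, 1, (h, w)), rng.uniform(0, 1, (h, w))
        dwl, dhl = rng.uniform(-0.5, 1.5, (h, w)), rng.uniform(-0.5, 1.5, (h, w))
        out8[0], out8[1], out8[2], out8[3] = dx, dy, dwl, dhl
        out8[4] = 10.0
        outs = [out8] + [np.full((7, hh, ww), -30.0) for hh, ww in _grids(size)[1:]]
        dets = decode(outs, size)
        # reconstruct centers/sizes and compare to the synthesis
        for d in dets[: h * w]:
            cx, cy = (d.x1 + d.x2) / 2, (d.y1 + d.y2) / 2
            gx, gy = int(cx // s), int(cy // s)
            if 3 <= gx < w - 3 and 3 <= gy < h - 3:  # ignore clipped border cells
                assert cx == pytest.approx((gx + dx[gy, gx]) * s, rel=1e-6)
                assert d.x2 - d.x1 == pytest.approx(np.exp(dwl[gy, gx]) * s, rel=1e-6)

    def test_grid_mismatch_rejected(self):
        outs = [np.zeros((7, 9, 9)) for _ in range(3)]
        with pytest.raises(ValueError, match="stride"):
            decode(outs, 64)


def _brute_force_nms(boxes, iou_thresh):
    """Oracle: simulate suppression by exhaustive keep-set search.

    Enumerates all keep subsets and returns the unique subset that is
    (a) conflict-free, (b) maximal, and (c) greedily preferred: every
    discarded box conflicts with a kept higher-priority box.
    """
    order = sorted(boxes, key=lambda d: (-d.score, -d.area, d.x1))
    for size in range(len(order), -1, -1):
        for keep in itertools.combinations(range(len(order)), size):
            ok = True
            for a, b_ in itertools.combinations(keep, 2):
                if (
                    order[a].class_id == order[b_].class_id
                    and box_iou(order[a], order[b_]) >= iou_thresh
                ):
                    ok = False
                    break
            if not ok:
                continue
            # greedy preference: each dropped box must conflict with an
            # earlier kept box
            valid = all(
                any(
                    k < j
                    and order[k].class_id == order[j].class_id
                    and box_iou(order[k], order[j]) >= iou_thresh
                    for k in keep
                )
                for j in range(len(order))
                if j not in keep
            )
            if valid:
                return [order[i] for i in keep]
    return []


class TestNms:
    def test_identical_boxes_keep_highest_score(self):
        a = DetBox(0, 0.9, 0, 0, 10, 10)
        b = DetBox(0, 0.8, 0, 0, 10, 10)
        assert nms([a, b]) == [a]

    def test_disjoint_boxes_all_kept(self):
        boxes = [DetBox(0, 0.9, 0, 0, 10, 10), DetBox(0, 0.8, 20, 20, 30, 30)]
        assert len(nms(boxes)) == 2

    def test_chain_suppression_matches_brute_force(self):
        # pairwise IoUs (a,b)=0.6, (b,c)=0.6, (a,c)=0.1 approximately:
        a = DetBox(0, 0.9, 0, 0, 100, 10)
        b = DetBox(0, 0.8, 25, 0, 125, 10)
        c = DetBox(0, 0.7, 50, 0, 150, 10)
        assert box_iou(a, b) > 0.45 and box_iou(b, c) > 0.45 and box_iou(a, c) < 0.45
        kept = nms([a, b, c])
        assert kept == [a, c]
        assert kept == _brute_force_nms([a, b, c], 0.45)

    def test_random_instances_match_brute_force(self, rng):
        for _ in range(25):
            n = rng.integers(1, 6)
            boxes = []
            for _ in range(n):
                x1, y1 = rng.uniform(0, 60, 2)
                boxes.append(
                    DetBox(
                        int(rng.integers(0, 2)),
                        float(rng.uniform(0.1, 1)),
                        float(x1), float(y1),
                        float(x1 + rng.uniform(5, 40)), float(y1 + rng.uniform(5, 40)),
                    )
                )
            assert nms(boxes, score_thresh=0.0) == _brute_force_nms(boxes, 0.45)

    def test_score_threshold_filters(self):
        boxes = [DetBox(0, 0.005, 0, 0, 10, 10)]
        assert nms(boxes) == []
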