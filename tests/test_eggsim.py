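"""Synthetic tray generator, augmentation pipeline, VOC annotation I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from candlelite.detector import GTBox
from candlelite.eggsim import (
    INFERTILE_FRACTION,
    augment,
    expand_dataset,
    generate_tray,
    sample_scene,
)
from candlelite.voc import (
    VocError,
    VocObject,
    VocRecord,
    boxes_to_record,
    read_voc,
    record_to_boxes,
    write_voc,
)


class TestGenerateTray:
    @pytest.mark.parametrize("rows,cols,n", [(7, 9, 63), (3, 5, 15), (5, 7, 35)])
    def test_grid_product_box_counts(self, rows, cols, n):
        _, boxes = generate_tray(rows, cols, seed=1, width=360, height=300)
        assert len(boxes) == n

    def test_deterministic_for_fixed_seed(self):
        img1, b1 = generate_tray(3, 5, seed=42, width=200, height=160)
        img2, b2 = generate_tray(3, 5, seed=42, width=200, height=160)
        assert np.array_equal(img1, img2)
        assert b1 == b2

    def test_different_seed_changes_raster(self):
        img1, _ = generate_tray(3, 5, seed=1, width=200, height=160)
        img2, _ = generate_tray(3, 5, seed=2, width=200, height=160)
        assert not np.array_equal(img1, img2)

    def test_boxes_inside_image(self, small_tray):
        img, boxes = small_tray
        h, w = img.shape[:2]
        for b in boxes:
            assert 0 <= b.x1 < b.x2 <= w
            assert 0 <= b.y1 < b.y2 <= h

    def test_eggs_brighter_than_background(self, small_tray):
        img, boxes = small_tray
        grey = img.astype(float).mean(axis=2)
        bg = np.median(grey)
        for b in boxes:
            crop = grey[int(b.y1):int(b.y2), int(b.x1):int(b.x2)]
            assert crop.mean() > bg + 20

    def test_fertile_eggs_carry_dark_structures(self):
        """The embryo spot and vessels darken the egg interior."""
        scene = sample_scene(3, 5, seed=11, width=320, height=240)
        from candlelite.eggsim import render_scene

        img, boxes = render_scene(scene)
        grey = img.astype(float).mean(axis=2)
        fertile = [b for b, e in zip(boxes, scene.eggs) if e.fertile]
        infertile = [b for b, e in zip(boxes, scene.eggs) if not e.fertile]
        if fertile and infertile:
            def interior_cv(b):
                crop = grey[int(b.y1) + 3:int(b.y2) - 3, int(b.x1) + 3:int(b.x2) - 3]
                return crop.std() / (crop.mean() + 1e-9)
            f = np.mean([interior_cv(b) for b in fertile])
            i = np.mean([interior_cv(b) for b in infertile])
            assert f > i  # fertile interiors are more textured

    def test_unsupported_grid_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            generate_tray(2, 2, seed=0)

    def test_too_dense_grid_rejected(self):
        with pytest.raises(ValueError, match="dense"):
            generate_tray(7, 9, seed=0, width=64, height=64)


def _crop(img, b):
    return img[
        int(np.floor(b.y1)):int(np.ceil(b.y2)),
        int(np.floor(b.x1)):int(np.ceil(b.x2)),
    ]


class TestAugment:
    def test_rotate_180_twice_is_identity(self, small_tray):
        img, boxes = small_tray
        once = augment(img, boxes, "rotate", {"angle": 180})
        twice = augment(*once, "rotate", {"angle": 180})
        assert np.array_equal(twice[0], img)
        for a, b in zip(twice[1], boxes):
            assert a.class_id == b.class_id
            assert (a.x1, a.y1, a.x2, a.y2) == pytest.approx((b.x1, b.y1, b.x2, b.y2))

    def test_mirror_box_remap_formula(self, small_tray):
        img, boxes = small_tray
        w = img.shape[1]
        _, mirrored = augment(img, boxes, "mirror")
        for a, b in zip(mirrored, boxes):
            assert (a.x1, a.x2) == (w - b.x2, w - b.x1)
            assert (a.y1, a.y2) == (b.y1, b.y2)

    @pytest.mark.parametrize("angle", [90, 180, 270])
    def test_rotation_preserves_box_content(self, small_tray, angle):
        """Remapped boxes crop out exactly the rotated egg pixels."""
        img, boxes = small_tray
        out, new = augment(img, boxes, "rotate", {"angle": angle})
        for b_old, b_new in zip(boxes, new):
            assert np.array_equal(np.rot90(_crop(img, b_old), k=angle // 90), _crop(out, b_new))

    def test_mirror_preserves_box_content(self, small_tray):
        img, boxes = small_tray
        out, new = augment(img, boxes, "mirror")
        for b_old, b_new in zip(boxes, new):
            assert np.array_equal(_crop(img, b_old)[:, ::-1], _crop(out, b_new))

    def test_contrast_leaves_boxes_unchanged(self, small_tray):
        img, boxes = small_tray
        out, new = augment(img, boxes, "contrast", {"factor": 1.4})
        assert new == list(boxes)
        assert out.shape == img.shape and not np.array_equal(out, img)

    def test_unsupported_angle_rejected(self, small_tray):
        with pytest.raises(ValueError, match="angle"):
            augment(*small_tray, "rotate", {"angle": 45})


class TestExpandDataset:
    def test_single_image_yields_four(self, small_tray):
        out = expand_dataset([small_tray], seed=0)
        assert len(out) == 4

    def test_expansion_factor_always_four(self, rng):
        records = [
            (rng.integers(0, 255, size=(8, 8, 3)).astype(np.uint8),
             [GTBox(0, 1, 1, 6, 6)])
            for _ in range(7)
        ]
        assert len(expand_dataset(records, seed=1)) == 28

    def test_expansion_reproduces_published_split_counts(self, rng):
        """831 fertile + 628 infertile stand-ins -> 3324 + 2512 = 5836."""
        img = np.zeros((4, 4, 3), dtype=np.uint8)
        fertile = [(img, [GTBox(0, 0, 0, 4, 4)])] * 831
        infertile = [(img, [GTBox(1, 0, 0, 4, 4)])] * 628
        out = expand_dataset(fertile + infertile, seed=2)
        assert len(out) == 5_836
        n_fertile = sum(1 for _, bx in out if bx[0].class_id == 0)
        assert n_fertile == 3_324
        assert len(out) - n_fertile == 2_512


class TestVocIO:
    def test_conversion_convention(self):
        rec = boxes_to_record([GTBox(0, 10, 20, 50, 80)], "a.jpg", 100, 100)
        o = rec.objects[0]
        assert (o.xmin, o.ymin, o.xmax, o.ymax) == (11, 21, 50, 80)

    def test_roundtrip_through_file(self, small_tray, tmp_path):
        img, boxes = small_tray
        rec = boxes_to_record(boxes, "tray.jpg", img.shape[1], img.shape[0])
        write_voc(rec, tmp_path / "tray.xml")
        back = read_voc(tmp_path / "tray.xml")
        assert back.filename == rec.filename
        assert (back.width, back.height) == (rec.width, rec.height)
        assert back.objects == rec.objects

    @given(
        x1=st.integers(0, 200), y1=st.integers(0, 200),
        dw=st.integers(2, 100), dh=st.integers(2, 100),
        cid=st.integers(0, 1),
    )
    @settings(max_examples=50, deadline=None)
    def test_integer_box_roundtrip_identity(self, x1, y1, dw, dh, cid):
        b = GTBox(cid, x1, y1, x1 + dw, y1 + dh)
        rec = boxes_to_record([b], "x.jpg", 400, 400)
        (back,) = record_to_boxes(rec)
        assert back == b

    def test_unknown_class_rejected(self, tmp_path):
        xml = (tmp_path / "duck.xml")
        xml.write_text(
            "<annotation><filename>d.jpg</filename>"
            "<size><width>10</width><height>10</height><depth>3</depth></size>"
            "<object><name>duck</name><bndbox><xmin>1</xmin><ymin>1</ymin>"
            "<xmax>5</xmax><ymax>5</ymax></bndbox></object></annotation>"
        )
        with pytest.raises(VocError, match="duck"):
            read_voc(xml)

    def test_degenerate_box_rejected(self):
        with pytest.raises(VocError, match="degenerate"):
            VocObject("fertile", 5, 5, 5, 10)

    def test_malformed_xml_rejected(self, tmp_path):
        bad = tmp_path / "bad.xml"
        bad.write_text("<annotation><size>")
        with pytest.raises(VocError, match="malformed"):
            read_voc(bad)


class TestSceneStatistics:
    def test_default_infertile_fraction_matches_stock(self):
        assert INFERTILE_FRACTION == pytest.approx(840 / 2111)

    def test_fraction_configurable(self):
        scene = sample_scene(7, 9, seed=3, width=360, height=300, infertile_frac=1.0)
        assert all(not e.fertile for e in scene.eggs)
        scene = sample_scene(7, 9, seed=3, width=360, height=300, infertile_frac=0.0)
        assert all(e.fertile for e in scene.eggs)
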