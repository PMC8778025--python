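"""Detector geometry, loss, soft-NMS, decoding and construction."""

import numpy as np
import pytest

from semgdet import detector, nn
from semgdet.detector import (Box, Detection, DetectorConfig, box_iou,
                              detection_loss, soft_nms)
from semgdet.errors import ConfigError, ValidationError


def rasterized_iou(a: Box, b: Box, scale: int = 1) -> float:
    """Brute-force IoU by counting unit cells on an integer grid."""
    ax0, ay0, ax1, ay1 = (int(round(v * scale)) for v in a.corners)
    bx0, by0, bx1, by1 = (int(round(v * scale)) for v in b.corners)
    x0 = min(ax0, bx0)
    y0 = min(ay0, by0)
    x1 = max(ax1, bx1)
    y1 = max(ay1, by1)
    grid_a = np.zeros((y1 - y0, x1 - x0), dtype=bool)
    grid_b = np.zeros_like(grid_a)
    grid_a[ay0 - y0:ay1 - y0, ax0 - x0:ax1 - x0] = True
    grid_b[by0 - y0:by1 - y0, bx0 - x0:bx1 - x0] = True
    inter = np.sum(grid_a & grid_b)
    union = np.sum(grid_a | grid_b)
    return inter / union


def random_int_box(rng, lo=1, hi=60):
    return Box(cx=float(rng.integers(-50, 50)),
               cy=float(rng.integers(-50, 50)),
               half_w=float(rng.integers(lo, hi)),
               half_h=float(rng.integers(lo, hi)))


class TestIoU:
    def test_agrees_with_rasterization_on_many_random_pairs(self):
        rng = np.random.default_rng(0)
        worst = 0.0
        for _ in range(1000):
            a, b = random_int_box(rng), random_int_box(rng)
            worst = max(worst, abs(box_iou(a, b) - rasterized_iou(a, b)))
        assert worst < 1e-6

    def test_identical_boxes_have_iou_one(self):
        b = Box(10, 10, 5, 4)
        assert box_iou(b, b) == pytest.approx(1.0)


class TestDetectionLoss:
    def test_perfect_overlap_gives_zero(self):
        b = Box(100, 50, 30, 20)
        assert detection_loss(b, b) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_unit_squares(self):
        """Unit squares centred (0,0) and (10,0): IoU term is exactly 1."""
        a = Box(0, 0, 0.5, 0.5)
        b = Box(10, 0, 0.5, 0.5)
        loss = detection_loss(a, b)
        # term1 = 1 (IoU 0); term2 = 100 / c^2 with c the enclosing
        # diagonal sqrt(11^2 + 1^2); term3 = 0 (equal aspect)
        expected = 1.0 + 100.0 / (11.0**2 + 1.0**2) + 0.0
        assert loss == pytest.approx(expected, rel=1e-12)

    def test_worked_example_boxes_match_geometry_oracle(self):
        """Reference [175,97,68,68] vs prediction [183,116,78,65] (array
        order cx, cy, half_h, half_w): every term recomputed from
        first principles, IoU by rasterization."""
        gt = Box(cx=175, cy=97, half_h=68, half_w=68)
        pred = Box(cx=183, cy=116, half_h=78, half_w=65)
        iou = rasterized_iou(pred, gt)
        rho2 = (183 - 175) ** 2 + (116 - 97) ** 2
        ex0, ey0 = min(183 - 65, 175 - 68), min(116 - 78, 97 - 68)
        ex1, ey1 = max(183 + 65, 175 + 68), max(116 + 78, 97 + 68)
        c2 = (ex1 - ex0) ** 2 + (ey1 - ey0) ** 2
        aspect = abs(68 / 68 - 65 / 78)
        expected = 1 - iou + rho2 / c2 + aspect
        assert detection_loss(pred, gt) == pytest.approx(expected, abs=1e-6)

    def test_literal_mode_keeps_the_sign(self):
        gt = Box(0, 0, 10, 5)     # aspect 2
        pred = Box(0, 0, 5, 10)   # aspect 0.5
        lit = detection_loss(pred, gt, mode="literal")
        ab = detection_loss(pred, gt, mode="absolute_aspect")
        assert ab == pytest.approx(lit)           # positive difference here
        gt2 = Box(0, 0, 5, 10)
        pred2 = Box(0, 0, 10, 5)
        assert detection_loss(pred2, gt2, mode="literal") < \
            detection_loss(pred2, gt2, mode="absolute_aspect")

    def test_absolute_mode_non_negative_and_zero_iff_identical(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            a, b = random_int_box(rng), random_int_box(rng)
            loss = detection_loss(a, b)
            assert loss >= 0.0
            if (a.cx, a.cy, a.half_w, a.half_h) != \
                    (b.cx, b.cy, b.half_w, b.half_h):
                assert loss > 0.0

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValidationError):
            Box(0, 0, 0, 5)

    def test_unknown_mode_rejected(self):
        b = Box(0, 0, 1, 1)
        with pytest.raises(ConfigError):
            detection_loss(b, b, mode="bogus")


class TestSoftNms:
    def make(self, cx, conf, cls=1, path="a"):
        return Detection(Box(cx, 0, 5, 5), cls, conf, path)

    def test_disjoint_boxes_keep_their_scores(self):
        dets = [self.make(0, 0.9), self.make(100, 0.8)]
        out = soft_nms(dets, sigma=0.5, score_floor=0.0)
        assert sorted(d.confidence for d in out) == [0.8, 0.9]

    def test_duplicate_decayed_by_gaussian_at_iou_one(self):
        sigma = 0.5
        dets = [self.make(0, 0.9), self.make(0, 0.8)]
        out = soft_nms(dets, sigma=sigma, score_floor=0.0)
        decayed = [d for d in out if d.confidence != 0.9][0]
        assert decayed.confidence == pytest.approx(0.8 * np.exp(-1.0 / sigma))

    def test_sigma_to_zero_is_hard_suppression(self):
        dets = [self.make(0, 0.9), self.make(0, 0.8)]
        out = soft_nms(dets, sigma=0.0, score_floor=0.05)
        assert len(out) == 1 and out[0].confidence == 0.9

    def test_never_increases_confidence_and_sorted(self):
        rng = np.random.default_rng(2)
        dets = [self.make(float(rng.integers(0, 30)), float(rng.uniform(0.1, 1)))
                for _ in range(20)]
        before = {id(d): d.confidence for d in dets}
        out = soft_nms(dets, sigma=0.5, score_floor=0.0)
        confs = [d.confidence for d in out]
        assert confs == sorted(confs, reverse=True)
        assert all(d.confidence == before[id(d)] for d in dets)  # input intact

    def test_different_classes_do_not_suppress(self):
        dets = [self.make(0, 0.9, cls=1), self.make(0, 0.8, cls=2)]
        out = soft_nms(dets, sigma=0.5, score_floor=0.0)
        assert sorted(d.confidence for d in out) == [0.8, 0.9]


class TestDecode:
    def small_cfg(self):
        return DetectorConfig(input_size=64, anchors=(
            ((16.0, 8.0), (20.0, 10.0), (24.0, 12.0)),
            ((32.0, 16.0), (40.0, 20.0), (48.0, 24.0))),
            conf_threshold=0.2)

    def test_zero_tensor_decodes_to_cell_centres_with_anchor_extents(self):
        cfg = self.small_cfg()
        raw16 = np.zeros((1, 33, 4, 4), dtype=np.float32)
        raw32 = np.zeros((1, 33, 2, 2), dtype=np.float32)
        per_image = detector.decode_predictions([raw16, raw32], cfg,
                                                apply_nms=False)
        dets = per_image[0]
        assert len(dets) == (16 + 4) * 3
        d0 = [d for d in dets if d.box.cx == pytest.approx(8.0)
              and d.box.cy == pytest.approx(8.0)]
        assert d0, "expected a detection at the first stride-16 cell centre"
        assert all(d.confidence == pytest.approx(0.25) for d in dets)
        sizes = {(d.box.half_w * 2, d.box.half_h * 2) for d in dets}
        for scale_anchors in cfg.anchors:
            for a in scale_anchors:
                assert a in sizes

    def test_handcrafted_tensor_round_trips_one_box(self):
        cfg = self.small_cfg()
        raw16 = np.full((1, 33, 4, 4), -20.0, dtype=np.float32)
        raw32 = np.full((1, 33, 2, 2), -20.0, dtype=np.float32)
        # encode a box at stride-16 cell (1, 2), anchor 1 (20 x 10)
        a, k = 3, 6
        r = raw16.reshape(1, a, 5 + k, 4, 4)
        tx, ty = 0.3, 0.7
        def logit(p):
            return float(np.log(p / (1 - p)))
        r[0, 1, 0, 2, 1] = logit(tx)
        r[0, 1, 1, 2, 1] = logit(ty)
        r[0, 1, 2, 2, 1] = np.log(1.5)   # t_h
        r[0, 1, 3, 2, 1] = np.log(0.8)   # t_w
        r[0, 1, 4, 2, 1] = 10.0          # objectness ~ 1
        r[0, 1, 5 + 3, 2, 1] = 10.0      # class 4
        per_image = detector.decode_predictions([raw16, raw32], cfg)
        assert len(per_image[0]) == 1
        d = per_image[0][0]
        assert d.class_id == 4
        assert d.box.cx == pytest.approx((1 + tx) * 16, abs=1e-4)
        assert d.box.cy == pytest.approx((2 + ty) * 16, abs=1e-4)
        assert d.box.half_w == pytest.approx(10 * 0.8, abs=1e-4)
        assert d.box.half_h == pytest.approx(5 * 1.5, abs=1e-4)

    def test_nothing_above_threshold_gives_empty_list(self):
        cfg = self.small_cfg()
        raw16 = np.full((1, 33, 4, 4), -20.0, dtype=np.float32)
        raw32 = np.full((1, 33, 2, 2), -20.0, dtype=np.float32)
        per_image = detector.decode_predictions([raw16, raw32], cfg)
        assert per_image[0] == []

    def test_bad_head_shape_rejected(self):
        cfg = self.small_cfg()
        with pytest.raises(ConfigError):
            detector.decode_predictions(
                [np.zeros((1, 30, 4, 4), np.float32),
                 np.zeros((1, 33, 2, 2), np.float32)], cfg)


class TestBuild:
    def test_grids_at_416_are_26_and_13(self):
        """The two fused scales of a 416x416 input."""
        net = detector.build_detector(
            cfg=DetectorConfig(input_size=416), width_multiplier=0.25, seed=0)
        x = np.zeros((1, 3, 416, 416), dtype=np.float32)
        raw16, raw32 = net.forward(x)
        assert raw16.shape[2:] == (26, 26)
        assert raw32.shape[2:] == (13, 13)
        assert raw16.shape[2] == 2 * raw32.shape[2]

    def test_head_channel_count_is_anchors_times_eleven(self):
        cfg = DetectorConfig(input_size=160)
        net = detector.build_detector(cfg=cfg, width_multiplier=0.25, seed=0)
        x = np.zeros((1, 3, 160, 160), dtype=np.float32)
        raw16, raw32 = net.forward(x)
        assert raw16.shape[1] == 3 * (4 + 1 + 6) == 33
        assert raw32.shape[1] == 33

    def test_forward_is_deterministic(self):
        cfg = DetectorConfig(input_size=160)
        a = detector.build_detector(cfg=cfg, width_multiplier=0.25, seed=3)
        b = detector.build_detector(cfg=cfg, width_multiplier=0.25, seed=3)
        x = np.random.default_rng(0).standard_normal(
            (1, 3, 160, 160)).astype(np.float32)
        np.testing.assert_array_equal(a.forward(x)[0], b.forward(x)[0])

    def test_indivisible_input_size_rejected(self):
        with pytest.raises(ConfigError):
            DetectorConfig(input_size=100)


class TestTrainValidation:
    def test_mosaic_flag_rejected(self, demo_detection_set):
        data = [(img, lab) for img, lab, _ in demo_detection_set[:2]]
        with pytest.raises(ConfigError):
            detector.train_detector(
                data, detector.DetectorTrainSpec(mosaic=True))

    def test_label_outside_image_rejected(self, demo_detection_set):
        img, lab, _ = demo_detection_set[0]
        from dataclasses import replace
        bad = replace(lab, cx=4000)
        with pytest.raises(ValidationError):
            detector.train_detector(
                [(img, bad)], detector.DetectorTrainSpec(iterations=1))

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValidationError):
            detector.train_detector([], detector.DetectorTrainSpec())


class TestAnchors:
    def test_kmeans_covers_label_sizes(self, demo_detection_set):
        labels = [lab for _, lab, _ in demo_detection_set]
        small, large = detector.kmeans_anchors(labels, k=6, seed=0)
        assert len(small) == 3 and len(large) == 3
        areas = [w * h for w, h in small + large]
        assert areas == sorted(areas)
        label_ws = {2 * l.half_w for l in labels}
        assert min(label_ws) * 0.5 <= small[0][0] <= max(label_ws) * 1.5
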