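"""Rendering, auto-labelling, JSON label files and augmentation."""

import numpy as np
import pytest

from semgdet import imaging
from semgdet.errors import LabelSchemaError, NoLabelError, ValidationError
from semgdet.synth import MOTION_CLASSES, SemgRecord


def single_channel_record(x, fs=2000.0, burst=(0.0, 1.0), peak=None):
    x = np.asarray(x, dtype=float)
    return SemgRecord(samples=x[None, :], fs=fs, motion=MOTION_CLASSES[5],
                      angle_fraction=0.8, burst_extent=burst,
                      peak=peak if peak is not None else float(np.max(np.abs(x))),
                      channel_names=("fused",))


class TestRender:
    def test_flat_record_draws_only_baseline_rows(self):
        rec = single_channel_record(np.zeros(2000), peak=0.0)
        img = imaging.render_signal_image(rec, size=128)
        dark = np.argwhere(img.pixels[:, :, 0] < 128)
        rows = np.unique(dark[:, 0])
        baseline = img.axis.baseline_row
        assert np.all(np.abs(rows - baseline) <= 1.5)

    def test_rendering_is_deterministic(self, rendered_example):
        img, _, rec = rendered_example
        again = imaging.render_signal_image(rec, size=448, amp_range=0.5)
        np.testing.assert_array_equal(img.pixels, again.pixels)

    def test_peak_row_matches_axis_map(self):
        t = np.linspace(0, 1, 2000)
        x = 0.8 * np.sin(2 * np.pi * 3 * t)
        rec = single_channel_record(x)
        img = imaging.render_signal_image(rec, size=256, amp_range=1.0)
        dark_rows = np.argwhere(img.pixels[:, :, 0] < 128)[:, 0]
        expected_top = img.axis.y_of_amp(0.8)
        assert abs(dark_rows.min() - expected_top) <= 2

    def test_empty_record_rejected(self):
        rec = single_channel_record(np.zeros(10))
        rec.samples = rec.samples[:, :0]
        with pytest.raises(ValidationError):
            imaging.render_signal_image(rec, size=64)

    def test_multichannel_record_rejected(self, synth_config):
        from semgdet import synth
        r = synth.generate_record(1, 0.5, synth_config)
        with pytest.raises(ValidationError):
            imaging.render_signal_image(r, size=64)


class TestAutoLabel:
    def test_label_geometry_follows_axis_maps(self):
        n = 2000
        x = np.zeros(n)
        burst = (0.25, 0.75)   # seconds, of a 1 s record
        i0, i1 = int(burst[0] * 2000), int(burst[1] * 2000)
        x[i0:i1] = 0.6 * np.sin(np.linspace(0, 40 * np.pi, i1 - i0))
        rec = single_channel_record(x, burst=burst, peak=0.6)
        img = imaging.render_signal_image(rec, size=200, amp_range=1.0)
        lab = imaging.auto_label(img, rec)
        ax = img.axis
        exp_x0, exp_x1 = ax.x_of_time(burst[0]), ax.x_of_time(burst[1])
        assert abs(lab.cx - (exp_x0 + exp_x1) / 2) <= 2
        assert abs(2 * lab.half_w - (exp_x1 - exp_x0)) <= 4
        # centre ordinate encodes half the peak excursion
        extreme = x[np.argmax(np.abs(x))]
        exp_cy = (ax.baseline_row + ax.y_of_amp(extreme)) / 2
        assert abs(lab.cy - exp_cy) <= 2

    def test_zero_amplitude_record_has_no_label(self):
        rec = single_channel_record(np.zeros(1000), peak=0.0)
        img = imaging.render_signal_image(rec, size=100)
        with pytest.raises(NoLabelError):
            imaging.auto_label(img, rec)

    def test_label_array_form(self, rendered_example):
        _, lab, _ = rendered_example
        arr = lab.to_array()
        assert len(arr) == 4
        assert all(isinstance(v, int) for v in arr)
        assert arr == [lab.cx, lab.cy, lab.half_h, lab.half_w]
        assert 1 <= lab.class_id <= 6

    def test_label_inside_image(self, rendered_example):
        img, lab, _ = rendered_example
        assert lab.inside(*img.size)


class TestLabelsJson:
    def test_round_trip(self, tmp_path, rendered_example):
        _, lab, _ = rendered_example
        labels = [imaging.BoxLabel(cx=10 + i, cy=20, half_h=5, half_w=7,
                                   class_id=1 + i % 6, image_path=f"i{i}.png")
                  for i in range(10)]
        path = tmp_path / "labels.json"
        imaging.write_labels_json(labels, path)
        assert imaging.read_labels_json(path) == labels

    def test_missing_key_names_the_key(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('[{"image_path": "x", "class_id": 1, "cx": 5, '
                        '"half_h": 2, "half_w": 2}]')
        with pytest.raises(LabelSchemaError, match="cy"):
            imaging.read_labels_json(path)

    def test_empty_list_round_trip(self, tmp_path):
        path = tmp_path / "empty.json"
        imaging.write_labels_json([], path)
        assert imaging.read_labels_json(path) == []

    def test_malformed_json_reports_position(self, tmp_path):
        path = tmp_path / "broken.json"
        path.write_text("[{]")
        with pytest.raises(LabelSchemaError, match="line"):
            imaging.read_labels_json(path)


class TestAugment:
    def test_horizontal_flip_is_involution(self, rendered_example):
        img, lab, _ = rendered_example
        once = imaging.horizontal_flip(img, lab)
        twice = imaging.horizontal_flip(*once)
        np.testing.assert_array_equal(twice[0].pixels, img.pixels)
        assert twice[1] == lab

    def test_identity_transforms(self, rendered_example):
        img, lab, _ = rendered_example
        r_img, r_lab = imaging.rotate(img, lab, 0.0)
        s_img, s_lab = imaging.random_scale(img, lab, 1.0)
        np.testing.assert_array_equal(r_img.pixels, img.pixels)
        np.testing.assert_array_equal(s_img.pixels, img.pixels)
        assert r_lab == lab and s_lab == lab

    def test_shift_moves_box_exactly(self, rendered_example):
        img, lab, _ = rendered_example
        _, moved = imaging.shift(img, lab, 10, 0)
        assert moved.cx == lab.cx + 10
        assert (moved.cy, moved.half_h, moved.half_w) == \
            (lab.cy, lab.half_h, lab.half_w)

    def test_color_jitter_leaves_label_alone(self, rendered_example):
        img, lab, _ = rendered_example
        j_img, j_lab = imaging.color_jitter(img, lab, (0.9, 1.0, 1.1))
        assert j_lab == lab
        assert j_img.pixels.shape == img.pixels.shape

    def test_augment_reproducible_for_fixed_seed(self, rendered_example):
        img, lab, _ = rendered_example
        spec = imaging.AugmentSpec(seed=5)
        a = imaging.augment(img, lab, spec)
        b = imaging.augment(img, lab, spec)
        np.testing.assert_array_equal(a[0].pixels, b[0].pixels)
        assert a[1] == b[1]

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_transformed_label_matches_transformed_mask(self, rendered_example,
                                                        seed):
        """IoU between the transformed label and the bounding box of the
        brute-force transformed box mask must be >= 0.95."""
        img, lab, _ = rendered_example
        rng = np.random.default_rng(seed)
        # dark box on white background, matching the rendering convention
        # (geometric ops fill uncovered pixels with white)
        mask = np.full(img.pixels.shape[:2] + (3,), 255, dtype=np.uint8)
        x0, y0, x1, y1 = lab.corners
        mask[y0:y1 + 1, x0:x1 + 1] = 0
        mask_img = imaging.SignalImage(pixels=mask, axis=img.axis)
        op = rng.choice(["shift", "rotate", "scale"])
        if op == "shift":
            dx, dy = int(rng.integers(-15, 16)), int(rng.integers(-15, 16))
            _, new_lab = imaging.shift(img, lab, dx, dy)
            m_img, _ = imaging.shift(mask_img, lab, dx, dy)
        elif op == "rotate":
            deg = float(rng.uniform(-5, 5))
            _, new_lab = imaging.rotate(img, lab, deg)
            m_img, _ = imaging.rotate(mask_img, lab, deg)
        else:
            f = float(rng.uniform(0.9, 1.1))
            _, new_lab = imaging.random_scale(img, lab, f)
            m_img, _ = imaging.random_scale(mask_img, lab, f)
        on = np.argwhere(m_img.pixels[:, :, 0] < 128)
        my0, mx0 = on.min(axis=0)
        my1, mx1 = on.max(axis=0)
        ax0, ay0, ax1, ay1 = new_lab.corners
        ix0, iy0 = max(ax0, mx0), max(ay0, my0)
        ix1, iy1 = min(ax1, mx1), min(ay1, my1)
        inter = max(ix1 - ix0, 0) * max(iy1 - iy0, 0)
        area_a = (ax1 - ax0) * (ay1 - ay0)
        area_b = (mx1 - mx0) * (my1 - my0)
        iou = inter / (area_a + area_b - inter)
        assert iou >= 0.95

    def test_out_of_image_rejection_mode(self, rendered_example):
        img, lab, _ = rendered_example
        with pytest.raises(ValidationError):
            imaging.shift(img, lab, img.size[1] + 50, 0, mode="reject")
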