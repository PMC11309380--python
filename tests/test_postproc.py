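import numpy as np
import pytest

from azapick import (
    DetectionBox,
    box_to_original,
    detect_pipeline,
    iou,
    letterbox,
    nms,
    read_yolo_labels,
    top1,
    write_yolo_labels,
)
from azapick.errors import InvalidArgumentError

from ._oracles import brute_nms


def random_boxes(rng, n):
    out = []
    for _ in range(n):
        w, h = rng.uniform(0.05, 0.4, size=2)
        x = rng.uniform(w / 2, 1 - w / 2)
        y = rng.uniform(h / 2, 1 - h / 2)
        out.append(DetectionBox(x, y, w, h, rng.uniform(0, 1), rng.choice(["low", "high"])))
    return out


class TestLetterbox:
    def test_square_input_is_identity_content(self, rng):
        img = rng.integers(0, 256, size=(640, 640, 3), dtype=np.uint8)
        lb = letterbox(img)
        assert lb.scale == 1.0 and (lb.pad_x, lb.pad_y) == (0, 0)
        assert np.array_equal(lb.canvas, img)

    def test_wide_input_scaled_half_with_symmetric_bands(self):
        img = np.full((640, 1280, 3), 200, dtype=np.uint8)
        lb = letterbox(img)
        assert lb.scale == 0.5
        assert lb.canvas.shape == (640, 640, 3)
        assert (lb.pad_x, lb.pad_y) == (0, 160)
        assert (lb.canvas[:160] == 114).all() and (lb.canvas[-160:] == 114).all()
        assert (lb.canvas[160:480] == 200).all()

    def test_tensor_is_chw_rgb_in_unit_range(self, rng):
        img = rng.integers(0, 256, size=(123, 457, 3), dtype=np.uint8)
        lb = letterbox(img, input_order="BGR")
        assert lb.tensor.shape == (3, 640, 640)
        assert lb.tensor.min() >= 0.0 and lb.tensor.max() <= 1.0
        # BGR->RGB: channel 0 of the tensor is the input's channel 2
        ij = (50 + lb.pad_y, 60 + lb.pad_x)
        assert lb.tensor[0][ij] == pytest.approx(lb.canvas[ij][2] / 255.0)

    def test_idempotent_on_letterboxed_input(self, rng):
        img = rng.integers(0, 256, size=(320, 640, 3), dtype=np.uint8)
        once = letterbox(img)
        twice = letterbox(once.canvas)
        assert twice.scale == 1.0 and (twice.pad_x, twice.pad_y) == (0, 0)
        assert np.array_equal(twice.canvas, once.canvas)

    def test_box_roundtrip_recovers_original_coordinates(self, rng):
        h, w = 480, 1280
        lb = letterbox(np.zeros((h, w, 3), dtype=np.uint8))
        for _ in range(20):
            xc, yc = rng.uniform(100, w - 100), rng.uniform(100, h - 100)
            bw, bh = rng.uniform(10, 80, size=2)
            t = lb.canvas.shape[0]
            box = DetectionBox(
                (xc * lb.scale + lb.pad_x) / t, (yc * lb.scale + lb.pad_y) / t,
                bw * lb.scale / t, bh * lb.scale / t, 0.9, "high",
            )
            rx, ry, rw, rh = box_to_original(box, lb)
            assert abs(rx - xc) < 0.5 and abs(ry - yc) < 0.5
            assert abs(rw - bw) < 0.5 and abs(rh - bh) < 0.5

    def test_zero_dimension_rejected(self):
        with pytest.raises(InvalidArgumentError):
            letterbox(np.zeros((0, 10, 3), dtype=np.uint8))


class TestNms:
    def test_single_confident_box_survives(self):
        b = DetectionBox(0.5, 0.5, 0.2, 0.2, 0.9, "high")
        assert nms([b]) == [b]

    def test_identical_boxes_keep_highest_confidence(self):
        hi = DetectionBox(0.5, 0.5, 0.2, 0.2, 0.9, "high")
        lo = DetectionBox(0.5, 0.5, 0.2, 0.2, 0.8, "high")
        assert nms([lo, hi]) == [hi]

    def test_below_confidence_threshold_dropped(self):
        b = DetectionBox(0.5, 0.5, 0.2, 0.2, 0.1, "low")
        assert nms([b]) == []

    def test_different_classes_do_not_suppress(self):
        a = DetectionBox(0.5, 0.5, 0.2, 0.2, 0.9, "high")
        b = DetectionBox(0.5, 0.5, 0.2, 0.2, 0.8, "low")
        assert set(nms([a, b])) == {a, b}

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(30):
            boxes = random_boxes(rng, int(rng.integers(1, 50)))
            assert nms(boxes) == brute_nms(boxes, 0.25, 0.45)

    def test_no_surviving_pair_overlaps(self, rng):
        boxes = random_boxes(rng, 80)
        kept = nms(boxes, iou_threshold=0.3)
        assert all(b in boxes for b in kept)
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                if a.cls == b.cls:
                    assert iou(a, b) <= 0.3


class TestTop1:
    def test_empty_gives_none(self):
        assert top1([]) is None

    def test_highest_confidence_wins(self):
        boxes = [
            DetectionBox(0.3, 0.3, 0.1, 0.1, 0.3, "low"),
            DetectionBox(0.5, 0.5, 0.1, 0.1, 0.7, "high"),
            DetectionBox(0.7, 0.7, 0.1, 0.1, 0.5, "low"),
        ]
        assert top1(boxes) == boxes[1]

    def test_ties_go_to_first_input(self):
        a = DetectionBox(0.3, 0.3, 0.1, 0.1, 0.5, "low")
        b = DetectionBox(0.7, 0.7, 0.1, 0.1, 0.5, "high")
        assert top1([a, b]) == a

    def test_full_pipeline(self, rng):
        boxes = random_boxes(rng, 20)
        best = detect_pipeline(boxes)
        if best is not None:
            assert best.confidence >= 0.25


class TestYoloIo:
    def test_roundtrip(self, tmp_path, rng):
        boxes = random_boxes(rng, 7)
        path = tmp_path / "labels.txt"
        write_yolo_labels(path, boxes, with_confidence=True)
        back = read_yolo_labels(path)
        assert len(back) == len(boxes)
        for a, b in zip(boxes, back):
            assert a.cls == b.cls
            for f in ("x_center", "y_center", "width", "height", "confidence"):
                assert getattr(a, f) == pytest.approx(getattr(b, f), abs=1e-6)

    def test_malformed_line_names_location(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("0 0.5 0.5 0.1\n")
        with pytest.raises(InvalidArgumentError, match="bad.txt:1"):
            read_yolo_labels(path)
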