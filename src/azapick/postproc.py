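"""Mobile-pipeline image pre-processing and detection post-processing.

The phone App feeds camera frames to the on-device detector after an
aspect-fit *letterbox* to 640×640 (grey fill 114,114,114), then transposes
to channel-first, swaps BGR→RGB and rescales 0–255 → 0–1. Raw detector
output (many candidate boxes with confidences) is filtered at confidence
0.25, merged by class-wise greedy non-max suppression, and only the top
box is kept for the class call. This module replicates those deterministic
stages so they can be validated against fixtures without any network
inference.

Boxes use the five-coordinate YOLO convention: class, then normalized
(x_center, y_center, width, height) in [0, 1] with the pixel origin at the
image's top-left.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from .errors import InvalidArgumentError

DEFAULT_TARGET = 640
DEFAULT_FILL = 114
DEFAULT_CONF = 0.25
DEFAULT_IOU = 0.45   # detector-family default; only the confidence cutoff is pipeline-fixed

CLASS_NAMES = ("low", "high")


@dataclass(frozen=True)
class DetectionBox:
    """One detection in normalized center format."""

    x_center: float
    y_center: float
    width: float
    height: float
    confidence: float
    cls: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise InvalidArgumentError(f"confidence {self.confidence} outside [0, 1]")
        for v in (self.x_center, self.y_center, self.width, self.height):
            if not 0.0 <= v <= 1.0:
                raise InvalidArgumentError(f"coordinate {v} outside [0, 1]")

    def corners(self) -> tuple[float, float, float, float]:
        """(x1, y1, x2, y2) in normalized units."""
        return (
            self.x_center - self.width / 2.0,
            self.y_center - self.height / 2.0,
            self.x_center + self.width / 2.0,
            self.y_center + self.height / 2.0,
        )


@dataclass(frozen=True)
class LetterboxResult:
    """Letterboxed image plus the metadata needed to undo it.

    ``tensor`` is the model input after the full pre-processing chain:
    channel-first float32 RGB in [0, 1]. ``canvas`` is the intermediate
    letterboxed uint8 image in the input's own channel order (kept for
    inspection and for pasting annotations). ``scale`` and the pad offsets
    map original pixel coordinates onto the canvas:
    ``canvas_xy = orig_xy * scale + (pad_x, pad_y)``.
    """

    tensor: np.ndarray
    canvas: np.ndarray
    scale: float
    pad_x: int
    pad_y: int
    orig_height: int
    orig_width: int
    channel_order: str = "RGB"
    value_range: str = "0-1"


def letterbox(
    image: np.ndarray,
    target: int = DEFAULT_TARGET,
    fill: int = DEFAULT_FILL,
    input_order: str = "BGR",
) -> LetterboxResult:
    """Aspect-fit ``image`` onto a ``target``×``target`` grey canvas.

    The content is scaled by ``s = target / max(h, w)`` (aspect ratio
    preserved), pasted centred, and the remaining bands filled with
    ``(fill, fill, fill)``. The returned tensor has then been transposed
    to channel-first, converted ``input_order``→RGB, and rescaled to
    [0, 1].
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise InvalidArgumentError(f"expected an HxWx3 image, got shape {img.shape}")
    h, w = img.shape[:2]
    if h == 0 or w == 0:
        raise InvalidArgumentError("zero-dimension image")
    if input_order not in ("BGR", "RGB"):
        raise InvalidArgumentError(f"unknown channel order {input_order!r}")

    s = target / max(h, w)
    nw, nh = max(1, round(w * s)), max(1, round(h * s))
    if (nw, nh) != (w, h):
        resized = np.asarray(
            Image.fromarray(img.astype(np.uint8)).resize((nw, nh), Image.BILINEAR)
        )
    else:
        resized = img.astype(np.uint8)

    canvas = np.full((target, target, 3), fill, dtype=np.uint8)
    pad_x = (target - nw) // 2
    pad_y = (target - nh) // 2
    canvas[pad_y:pad_y + nh, pad_x:pad_x + nw] = resized

    tensor = canvas.transpose(2, 0, 1).astype(np.float32)   # HWC -> CHW
    if input_order == "BGR":
        tensor = tensor[::-1].copy()                        # BGR -> RGB
    tensor /= 255.0                                         # 0-255 -> 0-1
    return LetterboxResult(
        tensor=tensor, canvas=canvas, scale=s, pad_x=pad_x, pad_y=pad_y,
        orig_height=h, orig_width=w,
    )


def box_to_original(box: DetectionBox, meta: LetterboxResult) -> tuple[float, float, float, float]:
    """Map a box normalized on the letterboxed canvas back to original pixels.

    Returns (x_center, y_center, width, height) in original-image pixels.
    """
    t = meta.canvas.shape[0]
    xc = (box.x_center * t - meta.pad_x) / meta.scale
    yc = (box.y_center * t - meta.pad_y) / meta.scale
    return xc, yc, box.width * t / meta.scale, box.height * t / meta.scale


def iou(a: DetectionBox, b: DetectionBox) -> float:
    """Intersection-over-union of two normalized boxes."""
    ax1, ay1, ax2, ay2 = a.corners()
    bx1, by1, bx2, by2 = b.corners()
    iw = max(0.0, min(ax2, bx2) - max(ax1, bx1))
    ih = max(0.0, min(ay2, by2) - max(ay1, by1))
    inter = iw * ih
    union = a.width * a.height + b.width * b.height - inter
    return inter / union if union > 0 else 0.0


def nms(
    boxes: Sequence[DetectionBox],
    conf_threshold: float = DEFAULT_CONF,
    iou_threshold: float = DEFAULT_IOU,
) -> list[DetectionBox]:
    """Confidence filter + class-wise greedy non-max suppression.

    Boxes below ``conf_threshold`` are dropped; the rest are visited in
    descending confidence (ties kept in input order) and a box is kept
    unless it overlaps an already-kept box of the same class with
    IoU > ``iou_threshold``. The result is sorted by descending confidence.
    """
    kept: list[DetectionBox] = []
    candidates = [b for b in boxes if b.confidence >= conf_threshold]
    order = sorted(range(len(candidates)), key=lambda i: (-candidates[i].confidence, i))
    for i in order:
        box = candidates[i]
        if any(k.cls == box.cls and iou(k, box) > iou_threshold for k in kept):
            continue
        kept.append(box)
    return kept


def top1(boxes: Sequence[DetectionBox]) -> DetectionBox | None:
    """Highest-confidence box, or ``None``; ties go to the earliest box."""
    best = None
    for b in boxes:
        if best is None or b.confidence > best.confidence:
            best = b
    return best


def read_yolo_labels(path, class_names: Sequence[str] = CLASS_NAMES) -> list[DetectionBox]:
    """Read YOLO-format txt labels (class x_c y_c w h [confidence], one box per line)."""
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        parts = line.split()
        if not parts:
            continue
        if len(parts) not in (5, 6):
            raise InvalidArgumentError(
                f"{path}:{lineno}: expected 5 or 6 fields, got {len(parts)}"
            )
        try:
            cls_idx = int(parts[0])
            vals = [float(v) for v in parts[1:]]
        except ValueError as exc:
            raise InvalidArgumentError(f"{path}:{lineno}: {exc}") from exc
        if not 0 <= cls_idx < len(class_names):
            raise InvalidArgumentError(f"{path}:{lineno}: class index {cls_idx} out of range")
        conf = vals[4] if len(vals) == 5 else 1.0
        out.append(DetectionBox(vals[0], vals[1], vals[2], vals[3], conf, class_names[cls_idx]))
    return out


def write_yolo_labels(
    path, boxes: Sequence[DetectionBox],
    class_names: Sequence[str] = CLASS_NAMES,
    with_confidence: bool = False,
) -> None:
    """Write boxes in YOLO txt format (confidence as an optional sixth column)."""
    lines = []
    for b in boxes:
        fields = [str(class_names.index(b.cls))] + [
            f"{v:.6f}" for v in (b.x_center, b.y_center, b.width, b.height)
        ]
        if with_confidence:
            fields.append(f"{b.confidence:.6f}")
        lines.append(" ".join(fields))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def detect_pipeline(
    boxes: Sequence[DetectionBox],
    conf_threshold: float = DEFAULT_CONF,
    iou_threshold: float = DEFAULT_IOU,
) -> DetectionBox | None:
    """Full post-processing chain: confidence filter → NMS → top-1."""
    return top1(nms(boxes, conf_threshold, iou_threshold))
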