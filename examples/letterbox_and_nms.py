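"""Mobile-pipeline pre/post-processing on a synthetic camera frame.

Letterboxes a 1280x640 frame to the detector's 640x640 input (grey-114
padding, BGR->RGB, 0-1 scaling), then filters and merges synthetic
detections with confidence threshold 0.25 and class-wise NMS, keeping the
top box for the class call.
"""

import numpy as np

from azapick import DetectionBox, letterbox, nms, top1

frame = np.full((640, 1280, 3), 90, dtype=np.uint8)   # wide BGR frame
lb = letterbox(frame)
print(f"letterbox: scale={lb.scale}, pad=({lb.pad_x},{lb.pad_y}), "
      f"tensor shape={lb.tensor.shape}, range=[{lb.tensor.min():.3f},{lb.tensor.max():.3f}]")

detections = [
    DetectionBox(0.50, 0.50, 0.20, 0.20, 0.91, "high"),
    DetectionBox(0.51, 0.50, 0.20, 0.20, 0.74, "high"),   # overlaps the 0.91 box
    DetectionBox(0.20, 0.30, 0.10, 0.10, 0.40, "low"),
    DetectionBox(0.80, 0.70, 0.10, 0.10, 0.12, "low"),    # below the 0.25 cutoff
]
kept = nms(detections)
print(f"NMS kept {len(kept)} of {len(detections)} boxes:")
for b in kept:
    print(f"  {b.cls:<5} conf={b.confidence:.2f} at ({b.x_center:.2f},{b.y_center:.2f})")

best = top1(kept)
print(f"top-1 class call: {best.cls} (confidence {best.confidence:.2f})")

# The two overlapping 'high' boxes merge into one, the 0.12-confidence box
# is filtered, and the class relayed to the decision stage is the top
# box's: high.
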