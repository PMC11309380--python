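"""Independent brute-force reference implementations used only by tests.

These deliberately share no code with the package: mining is nested loops
over itertools-enumerated patterns and per-row dict comparisons; NMS is
repeated argmax selection with its own corner-format IoU.
"""

from itertools import combinations, product


def brute_mine(tables, model_ids, min_support=1):
    """All complete-specificity, direction-consistent patterns.

    Returns {(members, assigned): (implied_class, support)} over the
    per-shuffle test tables (DataFrames with pred_<model> and true_A).
    """
    out = {}
    table_rows = [t.to_dict("records") for t in tables]
    for k in range(1, len(model_ids) + 1):
        for members in combinations(model_ids, k):
            for assigned in product(("low", "high"), repeat=k):
                directions = []
                support = 0
                pure = True
                for rows in table_rows:
                    ml = mh = 0
                    for row in rows:
                        if all(row[f"pred_{m}"] == c for m, c in zip(members, assigned)):
                            if row["true_A"] == "low":
                                ml += 1
                            else:
                                mh += 1
                    if ml and mh:
                        pure = False
                        break
                    if ml or mh:
                        support += 1
                        directions.append("low" if ml else "high")
                if pure and directions and len(set(directions)) == 1 and support >= min_support:
                    out[(members, assigned)] = (directions[0], support)
    return out


def _corner_iou(a, b):
    ax1, ay1 = a.x_center - a.width / 2, a.y_center - a.height / 2
    ax2, ay2 = a.x_center + a.width / 2, a.y_center + a.height / 2
    bx1, by1 = b.x_center - b.width / 2, b.y_center - b.height / 2
    bx2, by2 = b.x_center + b.width / 2, b.y_center + b.height / 2
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = a.width * a.height + b.width * b.height - inter
    return inter / union if union > 0 else 0.0


def brute_nms(boxes, conf_threshold, iou_threshold):
    """Greedy NMS by repeated best-confidence selection (ties: input order)."""
    remaining = [(i, b) for i, b in enumerate(boxes) if b.confidence >= conf_threshold]
    kept = []
    while remaining:
        j = min(range(len(remaining)), key=lambda j: (-remaining[j][1].confidence, remaining[j][0]))
        _, best = remaining.pop(j)
        kept.append(best)
        remaining = [
            (i, b) for i, b in remaining
            if not (b.cls == best.cls and _corner_iou(b, best) > iou_threshold)
        ]
    return kept
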