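"""From mined patterns to the orchard decision: Pick or Do not Pick.

Mines patterns on a small planted-rule experiment, then walks three
prediction rows through boosting and the final decision rule: a boosted
*high* call means Pick; abstains fall back to the raw fruit-A model.
"""

from azapick import Pattern, boost_predictions, decide_pick

# two patterns as mining would return them
mined = [
    Pattern(("D_f", "S_f"), ("high", "high"), implied_A_class="high"),
    Pattern(("D_f", "S_f"), ("low", "low"), implied_A_class="low"),
]

rows = [
    {"pred_A_f": "low", "pred_D_f": "high", "pred_S_f": "high"},   # pattern says high
    {"pred_A_f": "high", "pred_D_f": "low", "pred_S_f": "low"},    # pattern says low
    {"pred_A_f": "high", "pred_D_f": "high", "pred_S_f": "low"},   # no pattern fires
]

for i, row in enumerate(rows):
    boosted = boost_predictions(row, mined)
    d = decide_pick(boosted, fallback=row["pred_A_f"])
    note = "fallback to fruit-A model" if d.used_fallback else "pattern-based"
    print(f"tree {i}: boosted={boosted:<8} decision={d.decision:<12} ({note})")

# Tree 0 is picked although its fruit-A model said low: the multi-analyte
# pattern overrides the single model. Tree 2 matches no pattern, so the
# raw fruit-A call decides.
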