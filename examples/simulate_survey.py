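"""Generate a synthetic tree survey and form the low/high classes.

Draws n = 1045 trees with five correlated metabolite concentrations inside
the published ranges, then binarises each metabolite at its empirical mean
— the same labeling rule the field survey used.
"""

from azapick import (
    METABOLITES,
    assign_classes,
    default_metabolite_specs,
    mean_thresholds,
    simulate_concentrations,
)

records = simulate_concentrations(1045, seed=1)
thresholds = mean_thresholds(records)
labels = assign_classes(records, thresholds)

print("metabolite  min     mean    max     threshold  n_low  n_high")
for spec in default_metabolite_specs():
    m = spec.name
    vals = records[m]
    n_low = (labels[m] == "low").sum()
    print(f"{m:>10}  {vals.min():.3f}  {vals.mean():.3f}  {vals.max():.3f}  "
          f"{thresholds[m]:9.3f}  {n_low:5d}  {1045 - n_low:6d}")

# Every concentration stays inside its published range by construction;
# the class split is uneven because the Beta marginals are skewed, so the
# mean sits off-centre — exactly why 'low' usually outnumbers 'high'.
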