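"""Step through model selection on a hand-built soft-matching example.

One animal fitted by several worm models must end up as a single row with
the best-fitting (largest-ranked) model; a repeated best fit marks a
cluster of overlapping animals.
"""

import pandas as pd

from wormwell import rank_models_by_frequency, select_models

# a dataset where L1 is fitted most often and Adult least often
rows = []
for model, count in [("L1", 40), ("L2L3", 30), ("L4", 20), ("Adult", 10)]:
    for i in range(count):
        rows.append({"Metadata_Plate": "p01", "Metadata_Well": "A01",
                     "primary_object_id": 100 + i, "model_name": model,
                     "centroid_x": 1000.0, "centroid_y": 1000.0,
                     "worm_length": {"L1": 250, "L2L3": 450, "L4": 700, "Adult": 1000}[model]})
ranking = rank_models_by_frequency(pd.DataFrame(rows))
print("ranking (smallest to largest):", ranking.models)

# one animal covered by two L1 fits, one L2L3 fit and one L4 fit
animal = pd.DataFrame(rows[:0])
animal = pd.DataFrame([
    {"Metadata_Plate": "p05", "Metadata_Well": "C03", "primary_object_id": 1,
     "model_name": m, "centroid_x": 1000.0, "centroid_y": 1000.0, "worm_length": L}
    for m, L in [("L1", 210.0), ("L1", 240.0), ("L2L3", 430.0), ("L4", 690.0)]
])
out = select_models(animal, ranking)
print(out[["model_select", "cluster_flag", "worm_length"]].to_string(index=False))
# The L4 model wins (largest-ranked model present) and no cluster flag is
# set because it was fitted only once; the kept length is the L4 fit.
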