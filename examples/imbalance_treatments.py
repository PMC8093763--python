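"""Effect of inverse-frequency class weights on the minority city.

The reference scenario's fourth city has only 8 samples. A random forest
fitted with per-sample weights w_c = 1/n_c should recover more of its
held-out samples than the unweighted fit, at little cost elsewhere.
"""

import numpy as np

import microgeo as mg
from microgeo.ensemble import FittedCandidate

spec = next(c for c in mg.standard_roster() if c.id == "rf")
minority = "city03"
recalls = {"standard": [], "weighted": []}
overall = {"standard": [], "weighted": []}

for seed in range(10):
    table, _ = mg.generate_dataset(mg.SyntheticConfig(seed=seed))
    rel = mg.filter_and_renormalize(table)
    y = rel.label_array()
    tr, te = mg.stratified_holdout(y, 0.8, 3, seed=seed)
    print(f"seed {seed}: class weights "
          f"{ {c: round(w, 3) for c, w in mg.compute_class_weights(y[tr]).items()} }")
    for mode, w in (("standard", None), ("weighted", mg.sample_weights(y[tr]))):
        fc = FittedCandidate(spec, seed).fit(rel.values[tr], y[tr], w)
        pred = fc.predict(rel.values[te])
        mask = y[te] == minority
        recalls[mode].append((pred[mask] == minority).mean())
        overall[mode].append((pred == y[te]).mean())

for mode in ("standard", "weighted"):
    print(f"{mode:9s} minority recall {np.mean(recalls[mode]):.3f}  "
          f"overall accuracy {np.mean(overall[mode]):.3f}")

# the weighted fit should raise minority recall; overall accuracy moves
# little because weighting reshapes errors rather than adding information.
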