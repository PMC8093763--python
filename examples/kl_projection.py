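"""City prediction by Kullback-Leibler projection.

Each held-out sample is assigned the city of the training sample whose
composition minimises KL divergence from it; the three nearest cities give
a top-3 candidate set.
"""

import microgeo as mg

table, _ = mg.generate_dataset(mg.SyntheticConfig(seed=3))
rel = mg.filter_and_renormalize(table)
y = rel.label_array()
tr, te = mg.stratified_holdout(y, 0.8, 3, seed=3)
train = rel.subset_samples(tr)

top1 = top3 = 0
for i in te:
    ranked = mg.kl_predict(rel.values[i], train, top_m=3)
    top1 += ranked[0] == y[i]
    top3 += y[i] in ranked

print(f"top-1 accuracy     {top1 / len(te):.3f}  ({top1}/{len(te)})")
print(f"top-3 containment  {top3 / len(te):.3f}  ({top3}/{len(te)})")
# top-3 containment always bounds top-1 accuracy from above: the nearest
# city is by construction one of the three nearest.
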