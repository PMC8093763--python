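"""Fit the adaptive ensemble on synthetic multi-city abundance data.

Generates the reference four-city scenario (40/20/20/8 training samples,
300 taxa, city signatures at log-fold 2), applies the downstream filters,
fits the ensemble, and evaluates on an independent draw of 25 samples per
city from the same city profiles — large enough that held-out kappa
resolves individual errors finely.
"""

import numpy as np

import microgeo as mg

TRAIN_SIZES = (40, 20, 20, 8)
cfg = mg.SyntheticConfig(samples_per_city=tuple(t + 25 for t in TRAIN_SIZES), seed=7)
table, truth = mg.generate_dataset(cfg)
rel = mg.filter_and_renormalize(table)  # prevalence >= 1%, >= 10 reads, renormalise
y = rel.label_array()
train, test = [], []
for c, city in enumerate(cfg.city_names):
    idx = np.flatnonzero(y == city)
    train.extend(idx[:TRAIN_SIZES[c]])
    test.extend(idx[TRAIN_SIZES[c]:])
train, test = np.array(train), np.array(test)

config = mg.EnsembleConfig(roster=mg.standard_roster(), n_bootstraps=20, seed=7)
model = mg.fit_ensemble(rel.subset_samples(train), config)
report = mg.evaluate_ensemble(model, rel.values[test], y[test])

print("winner counts over 20 bootstraps:", model.winner_counts)
print(f"held-out kappa {report.kappa:.3f}  G-mean {report.gmean:.3f} "
      f"MAUC {report.mauc:.3f}  accuracy {report.accuracy:.3f}")
print("per-city precision:", {c: None if v is None else round(v, 2)
                              for c, v in report.per_class_precision.items()})

top = mg.rf_feature_importance(model, top_k=10)
planted = {f"s__taxon{i:05d}" for i in truth.all_signature_indices()}
hits = sum(t in planted for t in top["taxon_id"])
print(f"\ntop-10 random-forest taxa ({hits}/10 are planted signatures):")
print(top[["taxon_id", "importance"]].to_string(index=False))

# kappa/MAUC near the best single candidate show the ensemble adapting to
# whichever classifier suits this data; high importance ranks for planted
# signature taxa show the forest recovering the city-discriminating taxa.
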