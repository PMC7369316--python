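# omapop

Population analysis of how cortical neurons encode **observed
manipulative actions (OMAs)** across changes in visual presentation
format.

When a monkey watches videos of seven hand actions (drag, drop, grasp,
push, roll, rotate, squeeze), each filmed in four visual formats (two
actor postures x two camera viewpoints), single units in parietal
cortex respond selectively to action identity — and many keep the
*same* exemplar preference order in every format while rescaling their
firing rate. This package reimplements the complete single-unit and
population pipeline behind that observation, exercised end-to-end on a
synthetic Poisson spike-train generator with known ground truth:

- **Unit classification** — per-format 3 x 7 mixed ANOVA (epoch
  within-trial x exemplar between-trial) labelling units task-unrelated
  / action-related / OMA-selective; a 2 x 9 control-experiment ANOVA
  and a Pearson motion/contrast screen over nine natural videos; the
  time course of the tuned-unit fraction.
- **Format x action mixing models** — split-half cross-validated
  comparison of an additive model `A_ij = k1 E_i + k2 F_j` and a
  multiplicative model `M = s1 u1 v1ᵀ` (leading rank-1 SVD of the
  training matrix, Eckart–Young optimal), scored by the squared Pearson
  correlation with the held-out 4 x 7 response matrix.
- **Pseudopopulation decoding** — a Poisson naive Bayes classifier
  (class score `Σ_u n_u log λ_uc − λ_uc`) on pseudo-simultaneous data
  points, leave-one-split-out cross-validation, temporal-generalization
  matrices, label-shuffling permutation nulls, and cross-format
  generalization (train in one format, test in another).
- **Rank stability index (RSI)** — per 500-ms bin,
  `RSIr = 1 + Σᵢ (1 − (1/7)(Rfᵢ − 1))` over the three test formats,
  normalized to [0, 1]; unconstrained and constrained shuffling nulls;
  the stable/unstable population split.
- **State-space clustering** — ridge-regularized Mahalanobis distances
  between condition clouds in N-dimensional firing space, UPGMA trees
  with optimal leaf order, Newick export.

## Worked example

```python
import pandas as pd
import omapop as op
from omapop import classify, mixing, rank_stability as rs, decoding as dec

pop = op.make_population(
    {"multiplicative_stable": 30, "mixed_unstable": 30, "untuned": 20}, seed=1
)
rec = op.generate_main_dataset(pop, seed=1)          # 336-trial session

labels = classify.classify_main(rec)
print(labels["main_label"].value_counts().to_string())

fits = mixing.fit_session(rec)                       # epoch-2 model fits
sel = (labels.main_label == "oma_selective").to_numpy()
res = mixing.compare_models_population(fits[sel])
print({k: round(v, 2) for k, v in res["medians"].items()})
t = res["tests"]["r2_multiplicative_vs_r2_additive"]
print("multiplicative vs additive: Z = %.2f, P = %.4f" % (t["Z"], t["p"]))

b = op.bin_rates(rec, 0.5, 0.02, (-0.5, 2.6))        # RSI binning
tcs = rs.format_exemplar_timecourses(b, rec.trials)
scores = pd.Series({u: rs.rsi_timecourse(tcs[i], b.bin_starts).total_score
                    for i, u in enumerate(rec.unit_ids)})
print(rs.stability_split(scores[sel]).stability_label.value_counts().to_string())

b2 = op.bin_rates(rec, 0.3, 0.3, (0.9, 1.5))         # late-video window
acc = dec.cross_format_decode(b2, rec.trials, "stand_lateral", "sit_frontal",
                              n_runs=5, seed=1)
print("cross-format OMA decoding accuracy: %.2f (chance 0.14)" % acc.diagonal.mean())
```

Output:

```
main_label
oma_selective     63
task_unrelated    17
{'r2_observed': 0.96, 'r2_multiplicative': 0.37, 'r2_additive': 0.35}
multiplicative vs additive: Z = 2.04, P = 0.0419
stability_label
unstable    32
stable      31
cross-format OMA decoding accuracy: 0.85 (chance 0.14)
```

Reading the numbers: 63 of the 80 units (the 60 tuned ones plus a
handful of false positives at the nominal 5% level) pass the
OMA-selectivity screen. On this half-stable/half-unstable population
the split-half reliability ceiling is high (observed R² 0.96) while
both models fit the mixed-selectivity half poorly, so the medians sit
near 0.35 with a modest multiplicative advantage. The RSI total-score
split recovers the 30/30 stable-vs-unstable composition (31/32 among
the 63 selective units), and pooled pseudopopulation decoding trained
in one format transfers to another far above the 1/7 chance level —
carried by the rank-stable half of the population.

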