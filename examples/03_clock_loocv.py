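"""Train an elastic-net epigenetic clock and evaluate it by LOOCV.

Every sample's DNAm age comes from a model trained without that sample
(penalty reselected per fold); accuracy is the Pearson correlation and the
median absolute error of the pooled predictions.
"""

import ovisclock as oc
from ovisclock.simulate import evaluation_config

dataset, _, truth = oc.simulate_dataset(evaluation_config(seed=1))
config = oc.ClockConfig(seed=1)

model = oc.train_clock(dataset, config)
pos, neg = model.positive_negative_counts()
selected = set(model.coefficients)
planted = set(truth.index[truth["role"] == "clock"])
print(f"clock: {model.n_probes} CpGs selected "
      f"({pos} positively, {neg} negatively weighted); "
      f"{len(selected & planted)} are planted age-responsive probes")

print("running LOOCV (150 folds, full retrain each) ...")
evaluation = oc.loocv(dataset, config)
print(f"LOOCV: cor = {evaluation.cor:.3f}, "
      f"MAE = {evaluation.mae:.3f} years (median absolute error)")
print()
print("cor near 1 and sub-half-year MAE mean the clock reads chronological")
print("age from methylation alone, out of sample.")
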