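"""Train the SNPsnp regressors and predict a strain's saturated SNP number.

Builds a synthetic 500-strain cohort with a known nonlinear target,
trains the linear and random-forest models (grid search + 5-fold CV) and
prints held-out RSE/RAE/R-squared, the forest's feature importances, and
one prediction against its generator ground truth.
"""

import numpy as np

from snpsat.predictor import FEATURES, predict_saturated_snps, train_models
from snpsat.synthetic import simulate_predictor_dataset

rows = simulate_predictor_dataset(500, "nonlinear", noise_sd=0.02, seed=42)
models = train_models(rows, seed=42)

print(f"linear:  RSE={models.linear_metrics.rse:.4f} RAE={models.linear_metrics.rae:.4f} R2={models.linear_metrics.r2:.4f}")
print(f"forest:  RSE={models.forest_metrics.rse:.4f} RAE={models.forest_metrics.rae:.4f} R2={models.forest_metrics.r2:.4f}")
print("forest importances:")
for name, imp in zip(FEATURES, models.feature_importances):
    print(f"  {name:14s} {imp:.4f}")
print("current SNP number and SNP density carry almost all the signal,")
print("matching their strong correlation with the saturated count")

row = rows.iloc[-1]
pred, flagged = predict_saturated_snps(models, row[list(FEATURES)].to_dict())
print(f"one strain: predicted {pred:.0f}, generator truth {row['target_truth']:.0f}"
      + (" [flagged: below current count]" if flagged else ""))
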