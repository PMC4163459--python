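"""Train and cross-validate the rotation forest on synthetic data.

Shows the ensemble's fit/predict surface and a repeated stratified 5-fold
cross-validation report with the full metric bundle.
"""

import numpy as np

import drivermut as dm

fm, labels, _ = dm.simulate_feature_table(
    n_samples=200, n_features=30, n_informative=6, effect_size=3.0, seed=9
)

model = dm.RotationForest(dm.RotationSpec(n_trees=10, subset_size=3, seed=0))
model.fit(fm.values, labels, feature_names=fm.feature_names)
proba = model.predict_proba(fm.values)
print(f"training accuracy: {(model.predict(fm.values) == labels).mean():.3f}")
print(f"first sample P(driver) = {proba[0, 0]:.3f}")

report = dm.cross_validate(
    fm, labels,
    lambda: dm.RotationForest(dm.RotationSpec(seed=4)),
    folds=5, repeats=5, seed=2,
)
print("\n5-fold CV, 5 repeats (mean / variance across repeats):")
for name in ("precision", "recall", "f_measure", "accuracy", "mcc", "roc_area"):
    print(f"  {name:10s} {report.metric_means[name]:.4f} / "
          f"{report.metric_variances[name]:.6f}")

# Each tree trains on all samples after a block rotation built from
# per-feature-group principal axes, so the ensemble is diverse yet every
# tree sees the full data — CV accuracy well above the 0.5 chance level
# reflects the planted 6-feature signal.
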