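"""Train on one synthetic cohort, evaluate on a disjoint hold-out cohort.

The sequence-feature reduction and the median imputer are fitted on the
training cohort only; the hold-out call verifies that no test sample was
seen during reducer fitting before reporting the confusion matrix.
"""

import warnings

import numpy as np

import drivermut as dm

cfg = dm.default_config()
train_ds, _ = dm.simulate_dataset(
    dm.SimConfig(n_driver=150, n_passenger=150, effect_size=2.5, seed=10)
)
test_ds, _ = dm.simulate_dataset(
    dm.SimConfig(n_driver=50, n_passenger=50, effect_size=2.5, seed=11)
)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    reducer = dm.fit_reducer(train_ds, cfg)          # training split only
    train_fm = dm.assemble_features(train_ds, cfg, reducer)
    test_fm = dm.assemble_features(test_ds, cfg, reducer)

imputer = dm.MedianImputer().fit(train_fm.values)
y_train = np.array([m.label for m in train_ds.mutations])
y_test = np.array([m.label for m in test_ds.mutations])

model = dm.RotationForest(dm.RotationSpec(seed=0))
model.fit(imputer.transform(train_fm.values), y_train,
          feature_names=train_fm.feature_names)

test_imputed = dm.FeatureMatrix(
    test_fm.sample_ids, test_fm.feature_names,
    imputer.transform(test_fm.values), test_fm.provenance,
)
cm, bundle = dm.evaluate_on_holdout(model, test_imputed, y_test, reducer=reducer)

print(dm.holdout_report(cm, dataset="synthetic-holdout"))
# Columns follow the conventional detail layout TP, FP, TN, FN, then the
# percentage metrics; MCC stays on its native [-1, 1] scale. Accuracy well
# above 50% on the disjoint cohort shows the planted substitution and
# annotation signal generalizes rather than being memorized.
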