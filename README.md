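# drivermut

Classify somatic missense mutations as cancer **drivers** (mutations under
positive selection in tumors) versus neutral **passengers**, from protein
sequence and mutation annotations. `drivermut` is a library + thin CLI
implementing a classical feature-engineering pipeline for this problem:
four feature families, two univariate/greedy feature-ranking methods with
incremental selection, a from-scratch rotation-forest classifier, and a
cross-validated evaluation suite. A built-in synthetic-data generator
plants class signal mechanistically, so every stage runs and is testable
with no external databases.

## The method

Each mutation (protein P, position i, wild residue W → mutant M) is encoded
as 126 features in four families:

* **AARC** (15): residue-change values `AARC_j(X) = AARC_j(W) − AARC_j(M)`
  for 15 physicochemical property scales;
* **SSM** (51): the (W, M) element of 51 substitution scoring matrices;
* **PSS** (31): 2-gram (dipeptide) counts of P over the 20-letter alphabet
  (400 components) and over a reduced 6-letter physicochemical alphabet
  ({D,E,N,Q}, {H,R,K}, {C}, {S,T,P,A,G}, {M,I,L,V}, {F,Y,W}; 36
  components). The 30 of these 436 components with the highest DX score on
  the training data are kept, plus the linear correlation coefficient
  (LCC) between the sample's 436-vector x and the training mean profile x̄:
  Pearson's r computed across components;
* **AF** (29): annotated features from the mutation table (14 binary
  flags + 15 numeric scores; missing binaries are absence-coded, missing
  numerics take the training median).

Features are ranked either by the **DX score**

    DX = (mean_pos − mean_neg)² / (var_pos + var_neg),

or by greedy **mRMR** (mutual information with the class minus mean mutual
information with already-selected features, on 3-bin discretized columns).
**Incremental feature selection (IFS)** evaluates every top-k prefix of a
ranking by repeated stratified 5-fold cross-validation and keeps the
smallest k attaining the best mean accuracy.

The classifier is a **rotation forest**: for each of 10 trees, features are
randomly partitioned into groups of 3; per group, principal axes are fitted
on a bootstrap of a random class subset (half the instances removed) and
assembled into a block rotation of the full feature space; an unpruned Gini
decision tree is grown on the rotated data and the trees' leaf class
distributions are averaged. Performance is summarized from pooled confusion
counts as precision, recall, accuracy, F-measure, MCC, and ROC area.

## Worked example

```python
import drivermut as dm

fm, labels, truth = dm.simulate_feature_table(
    n_samples=200, n_features=40, n_informative=5, effect_size=4.0, seed=3)
ranking = dm.rank_dx(fm, labels)
print(ranking.top(5))
curve = dm.ifs(fm, labels, ranking,
               lambda: dm.RotationForest(dm.RotationSpec(seed=0)),
               folds=5, repeats=3, seed=1, max_k=20)
print(curve.best_k, round(curve.best_accuracy, 3))
```

prints

```
['f014', 'f038', 'f034', 'f002', 'f035']
5 0.983
```

— the five planted informative features are exactly the DX top 5
(`truth["informative_features"]` lists the same names), and the IFS curve
peaks at k = 5 with 98.3% cross-validated accuracy: the selection machinery
recovers the planted dimensionality. `examples/` contains one short script
per capability (feature encoding, ranking + IFS, rotation-forest CV,
hold-out evaluation with the leakage guard, and the CLI pipeline).

The same flow from the shell:

```bash
drivermut simulate --out run/fixture --n-driver 60 --n-passenger 60 --seed 5
drivermut extract  --sequences run/fixture/sequences.fasta \
                   --mutations run/fixture/mutations.tsv --out run/features
drivermut rank     --features run/features/features.tsv \
                   --labels run/features/labels.tsv --method dx --out run/dx.tsv
drivermut ifs      --features run/features/features.tsv \
                   --labels run/features/labels.tsv --ranking run/dx.tsv \
                   --out run/curve.tsv
drivermut train    --features run/features/features.tsv \
                   --labels run/features/labels.tsv --ranking run/dx.tsv \
                   --top-k best --curve run/curve.best.json --out run/model.joblib
```

## Data formats

Sequences are FASTA; mutations are TSV with columns `protein_id, position
(1-based), wild, mutant`, optional `label` (driver/passenger), and any
further columns as annotated features (empty cell = missing). Property
scales and substitution matrices are residue-labelled TSVs (one file per
table, defaults bundled under `src/drivermut/data/`, fully swappable via
directories). Feature matrices, rankings, IFS curves and reports are
TSV/JSON.

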