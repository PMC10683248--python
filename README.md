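# mmis

Gene-panel variant annotation and missense pathogenicity prediction for
primary mitochondrial disease.

Primary mitochondrial diseases are Mendelian disorders caused by variants in
mtDNA or in the nuclear genes required for oxidative phosphorylation.
Genome-wide pathogenicity predictors are trained on the whole exome and
perform unevenly on this gene set, while exome triage leaves clinicians with
hundreds of rare candidate variants per patient. `mmis` implements a
disease-specific alternative in two halves:

* **Annotation** — filter a VCF down to a configurable panel of
  mitochondrial-disease genes (protein-coding mtDNA genes, nuclear disease
  genes, mitochondrially localized nuclear genes), pick one MANE
  representative transcript per gene, and join on a typed, multi-level
  annotation schema (variant / gene / transcript level; integer / boolean /
  continuous dtypes) with explicit missingness.
* **Prediction** — turn annotated variants into a feature matrix, impute
  missing values with k-nearest neighbours, min-max normalize, select a
  classifier by nested cross-validation over six algorithm families, and fit
  a logistic-regression scorer

  &nbsp;&nbsp;&nbsp;&nbsp;Pr(pathogenic | x) = σ(b + Σᵢ ωᵢ xᵢ),

  where |ωᵢ| doubles as feature importance. Evaluation covers a 12-metric
  panel (Missing, PPV, NPV, specificity, FPR, recall, FNR, accuracy, MCC,
  AUC, F1, average precision), ROC/PR sweeps with Youden-J optimal
  thresholds, an ACMG-style three-way stratification (pathogenic Pr > 0.75,
  benign Pr < 0.15, VUS between), and a simulated-exome benchmark that
  spikes one causative variant into ~400-variant background exomes and
  reports candidate-list size and causative-variant rank per predictor.

Synthetic fixture generators (`mmis.synth`) emulate every input — gene
registries, annotation sources with controlled missingness, labeled feature
matrices drawn from a known logistic model, background exomes — so the whole
pipeline runs and is tested without any external databases.

## Worked example

```python
from mmis import fit_final, predict, full_report, stratified_report, feature_importance
from mmis.synth import SyntheticTruth, gen_labeled_dataset

truth = SyntheticTruth(true_coefficients=(2.0, -1.0, 0.0), seed=11,
                       missingness_rate=0.05)
train = gen_labeled_dataset(2000, truth)
test = gen_labeled_dataset(500, SyntheticTruth((2.0, -1.0, 0.0), seed=12,
                                               missingness_rate=0.05))

model = fit_final(train)              # KNN impute -> min-max -> logistic fit
scores = predict(model, test)         # Pr(pathogenic) per variant
panel = full_report(scores, test.labels, threshold=0.5).rounded()
print("accuracy %:", panel["accuracy"], " AUC:", panel["auc"],
      " AP:", panel["average_precision"], " MCC:", panel["mcc"])

strat = stratified_report(scores, test.labels)
print("classified %:", round(strat.proportion_classified, 2),
      " accuracy of classified %:", round(strat.accuracy_of_recommended, 2))

for name, w in feature_importance(model)[:3]:
    print(f"{name}  |w| = {w:.2f}")
```

prints

```
accuracy %: 79.2  AUC: 0.887  AP: 0.886  MCC: 0.587
classified %: 34.4  accuracy of classified %: 94.19
f0  |w| = 9.66
f1  |w| = 4.78
f2  |w| = 0.06
```

Read: at the default 0.5 cutoff the scorer classifies the held-out variants
with 79% accuracy and 0.887 AUC; under the stricter clinical cutoffs it
commits to a call on 34% of variants and is right on 94% of those, leaving
the rest as VUS. The importance ranking recovers the generative structure —
the feature with true weight 2 dominates, the zero-weight feature is last
(coefficients are on the normalized scale, hence larger than the raw truth;
`denormalized_coefficients` maps them back).

The same steps are available from a shell:

```sh
mmis synth registry --counts 13,321,1127 --out genes.tsv
mmis synth vcf --n 1000 --registry genes.tsv --fraction-in-panel 0.5 --out in.vcf
mmis annotate --vcf in.vcf --registry genes.tsv --schema schema.yaml \
              --sources sources/ --missense-only --out annotated.tsv
mmis train --matrix train.tsv --out model.json
mmis score --model model.json --matrix X.tsv --out scores.tsv
mmis evaluate --scores scores.tsv --stratify --out report.tsv
mmis simulate --backgrounds bg.tsv --causatives hits.tsv \
              --thresholds thresholds.yaml --out bench/
```

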