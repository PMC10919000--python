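# targetfish

Ligand-based **target fishing**: given a query compound, predict and rank
the protein targets it is likely to modulate, using one classifier per
target trained on that target's known active and inactive ligands.

The package is aimed at cheminformaticians who work with ChEMBL-style
bioactivity tables (compound, SMILES, target, IC50, unit, assay) and want a
reproducible pipeline from raw assay rows to a consensus-ranked target
profile, with honest accounting of the predictions that *cannot* be
validated.

## What it does

1. **Curation** — four rules: keep IC50 endpoints only; convert all values
   to µM; aggregate replicate measurements of a (compound, target) pair by
   rejecting outliers with the modified z-score
   `|0.6745 (x − median)/MAD| > 3.5` and taking the median of the
   survivors; label a pair *active* iff IC50 ≤ 10 µM. Targets must have
   ≥ 10 actives and ≥ 10 inactives to be modelled (≥ 5 + 5 for external
   validation sets, which are built as release differences).
2. **Featurization** — three descriptor spaces per molecule: `FGP`
   (1024-bit Morgan fingerprint, radius 8), `DSC` (123 physicochemical /
   topological properties from a frozen manifest), and `FUS` (their
   concatenation, length 1147).
3. **Modeling** — per target, 15 target-centric models (TCM): {DT, RF,
   KNN, SVM, GM (Gaussian naive Bayes)} × {FGP, DSC, FUS}. The majority
   class of the 70 % training portion is undersampled with k-means
   (k = minority count, one member per cluster) to exact balance; a 30 %
   stratified holdout measures the f1-score. Every model carries a
   distance-based **applicability domain** (AD): threshold
   `mean + 3·SD` of training distances to the centroid — Hamming on the
   majority-vote bit centroid for FGP, Euclidean on standardized features
   for DSC, and both simultaneously for FUS.
4. **Evaluation** — a confusion matrix with an explicit *unknown* cell for
   predictions lacking experimental records, lacking a model, or outside
   the AD. Besides TPR/TNR/FPR/FNR/precision/f1, two coverage rates:
   `recovery = (TP+FP+TN+FN) / n_model_covered` and
   `unknown = (T − (TP+FP+TN+FN)) / T` over a T-target candidate universe.
5. **Consensus** — scores normalized to [0, 1]; model prediction profiles
   compared by Pearson similarity `(r+1)/2`, clustered (average linkage,
   cutoffs 0.72 / 0.75 / 0.8 as presets), the best-f1 model kept per
   cluster; consensus score = mean probability of the selected models
   (≥ 0.5 ⇒ active); ranked lists evaluated at top fractions 1 %, 5 %,
   10 %, …, 100 %.

A synthetic-panel generator (`targetfish.synth`) builds ChEMBL-style
interaction tables with known ground truth — scaffold-separated active and
inactive families, lognormal replicate IC50s, unit mixtures, outliers and
off-endpoint rows — so the whole pipeline runs and is tested without any
external download.

## Worked example

The coverage metrics on a single screened compound: a 126-target candidate
universe, database records for 12 targets, models for 9 of those, with the
compound outside the AD of 2 — the 7 evaluable predictions resolving to
TP=2, FP=2, TN=2, FN=1:

```python
>>> from targetfish import ConfusionWithUnknown, recovery_rate, unknown_rate
>>> cm = ConfusionWithUnknown(tp=2, fp=2, tn=2, fn=1, unknown=119, n_model_covered=9)
>>> round(recovery_rate(cm), 2)   # 7 evaluable of 9 model-covered targets
0.78
>>> round(unknown_rate(cm, T=126), 2)   # (126 - 7) / 126
0.94
```

End to end on the default synthetic panel (5 targets, 30 actives + 90
inactives each):

```bash
targetfish run-all --seed 1 --out artifacts/
```

With seed 1 this curates 2 430 assay rows into 600 labeled pairs (150
active / 450 inactive), trains 75 models (15 per target) with holdout
f1-scores between 0.86 and 1.00, selects 2 representative model types at
the 0.75 similarity cutoff, and writes a fraction sweep in which the top
20 % of the consensus ranking already contains every true interaction
(TPR = 1.0) while 80 % of the candidate universe remains unvalidated
(unknown rate 0.80) — the signature of a sparsely annotated target space.

Artifacts: `curated.csv`, `features_*.csv`, `models/` (+ JSON manifest),
`predictions.csv`, `evaluation_per_model.csv`, `consensus.csv`,
`fraction_sweep.csv`, `run_manifest.json`.

## Scope

The package is ligand-based only (no protein features, no 3D), does not
query ChEMBL or any web prediction service, and performs no feature
selection. See `docs/methods.md` for modeling choices, defaults and
limitations.
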