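# Methods

## Problem setting

Target fishing inverts the usual virtual-screening question: instead of
ranking compounds against one target, a query compound is ranked against a
panel of targets. We treat each target as an independent binary
classification problem over its known ligands (target-centric models,
TCM). Because bioactivity databases annotate only a small corner of the
compound × target space, the evaluation layer keeps an explicit *unknown*
category rather than silently restricting itself to the annotated corner.

## Curation model

Raw assay rows are reduced to one labeled (compound, target) pair each:

- Only IC50 endpoints are used; other endpoints (Ki, EC50, …) are distinct
  physical quantities and are dropped, not converted.
- Units are converted to µM from a declared table (pM…M). An unknown unit
  is an error, not a guess; non-positive values are dropped with a warning.
  Qualified values (">", "<") are not representable in the input schema by
  design — censored measurements cannot feed a median.
- Replicates are aggregated on the linear µM scale: modified z-score
  `0.6745 (x − median)/MAD`, cutoff 3.5 (both configurable); survivors'
  median is the pair's IC50. With MAD = 0 (≥ half the replicates
  identical) nothing is flagged and the median is returned — a dominant
  repeated value is trustworthy, and the alternative is a division by
  zero. The consistency constant 0.6745 makes the score comparable to a
  z-score under normality.
- Label: active iff IC50 ≤ 10 µM, boundary inclusive. 10 µM is the
  conventional single-dose activity cutoff in ligand-based target
  prediction. Pairs that look active in one replicate and inactive in
  another are resolved solely by the aggregated median — no conflict veto.
- Gate: ≥ 10 actives and ≥ 10 inactives per target for training (≥ 5 per
  class for external validation). The gate is applied to curated
  (deduplicated) data, before any balancing.

## Descriptor spaces

- `FGP`: 1024-bit folded Morgan fingerprint, radius 8. Radius 8 is far
  larger than the common 2–3; environments then cover most of a drug-sized
  molecule and bits become nearly molecule-specific, which is tolerable
  for scaffold-level discrimination but increases folding collisions. Both
  radius and width are configurable.
- `DSC`: 123 two-dimensional physicochemical and topological properties,
  computed with RDKit in the fixed order of `data/descriptors_123.txt`.
  The manifest is the package's pinned property list (RDKit's standard 2D
  descriptors minus the fragment-count family, minus Ipc, whose raw form
  overflows on large molecules, and ExactMolWt, redundant with MolWt);
  its length is enforced at load. Zero-variance columns are never dropped.
- `FUS`: concatenation, FGP block first, length 1147.

SMILES standardization keeps the largest fragment (desalting) and leaves
stereochemistry as given; canonicalization is RDKit's.

## Per-target models

Fifteen models per target: {DT, RF, KNN, SVM, GM} × {FGP, DSC, FUS}, all
with library-default hyperparameters (RF: 100 trees; KNN: k = 5; SVM: RBF
kernel) and no feature selection. SVM probabilities come from a Platt
sigmoid calibrated on the training folds (`CalibratedClassifierCV`,
`ensemble=False`); KNN probabilities are neighbor class fractions; the
others are native.

Scaling: tree models and naive Bayes see raw features. Distance-based
learners (KNN, SVM) see standardized *continuous* features only — the DSC
matrix, or the DSC block of FUS via a column transformer. Fingerprint bits
already share a scale; standardizing them would give rare bits enormous
weight and distort the geometry (observed as a large KNN accuracy drop on
otherwise separable scaffolds).

**Splitting.** 30 % stratified holdout per target, test size
`floor(0.3 n)` (minimum one per class), drawn once per target so every
descriptor space sees the same compounds.

**Balancing.** After the split, the training majority class is undersampled
to the minority count with k-means, k = minority count, one member sampled
per cluster. This guarantees the exact count while spreading the retained
subset across the majority's chemical space. Balancing is seeded per
(target, descriptor kind) since the clustering lives in each descriptor
space separately. The holdout keeps the natural class ratio.

**Applicability domain.** Distance-to-centroid with threshold
`mean + k·SD` (k = 3 default) of training distances. FGP: Hamming distance
to the majority-vote bit centroid (ties → 0 — a Hamming centroid must be
binary and the sparse convention is the natural one). DSC: Euclidean
distance after standardizing with the training mean/SD (zero SD columns
get scale 1). FUS: a point is in-domain iff inside both sub-regions.
Centroid distance (not nearest-neighbor) was chosen because the AD is
summarized per target by its centroid; the k multiplier is configurable.
Out-of-AD predictions are flagged, never suppressed — the evaluation layer
decides what to do with them.

## Evaluation

For one compound against a T-target universe, a prediction is evaluable
iff the pair has a truth record, a model exists, and the compound is
inside that model's AD; `p_active ≥ 0.5` predicts active (boundary
inclusive, mirroring the IC50 convention). Everything else is *unknown*,
so `TP+FP+TN+FN+unknown = T` always.

- `recovery = (TP+FP+TN+FN) / n_model_covered`, where the denominator
  counts targets with both a truth record and a model. (The looser reading
  — all truth-annotated targets — disagrees with the worked arithmetic of
  the coverage example, 7/9; the stricter denominator is used.)
- `unknown = (T − (TP+FP+TN+FN)) / T`.

Zero-denominator rates are NaN markers, excluded from aggregation rather
than zeroed (zeroing would bias averages downward); aggregate summaries
report the contributing count alongside mean ± SD (population SD).

## Consensus

- Normalization: min–max to [0, 1] (constant lists map to 0.5 — no order
  information, so the midpoint) or linear rank mapping (best rank → 1,
  ties share their mean position).
- Model similarity: Pearson r of p_active over rows where both models
  predict, mapped to `(r+1)/2`. Pearson was chosen for scale-freeness; a
  pair with fewer than two common rows is an error. Constant profiles
  compare by near-equality (1 if equal, else 0).
- Selection: average-linkage hierarchical clustering on `1 − similarity`,
  cut so models cluster together only when merged at similarity strictly
  above the cutoff (presets 0.72 / 0.75 / 0.8); the highest-f1 model
  represents each cluster, ties broken lexicographically.
- Fusion: plain mean of the selected models' probabilities per
  (compound, target); entries missing because a compound sits outside one
  model's AD are excluded from the mean, not imputed as 0 (imputation
  would systematically deflate scores). Pairs with no contributor are
  omitted.
- Sweep: ranking by score (descending) with target-id tie-break; at
  fraction f the top `ceil(f·N)` entries are evaluated. The grid is
  {1 %} ∪ {5 %, 10 %, …, 100 %}. The unknown-rate universe is the full
  entry list, so shallow cuts report high unknown rates by construction.

## Synthetic panels

The generator emulates a curated bioactivity database at desk scale, with
two independently tunable separations:

- **chemistry**: each target's actives come from one aromatic scaffold
  family, its inactives from a disjoint aliphatic family (substituent
  enumeration on distinct cores; all SMILES verified to parse, families
  verified disjoint);
- **potency**: replicate IC50s are lognormal around 1 µM (actives) and
  50 µM (inactives) with log-scale SD 0.3, straddling the 10 µM cutoff by
  ≫ 4 SD on the log scale, so curation recovers the ground-truth labels.

Defaults: 5 targets, 30 actives + 90 inactives each (a 3:1 imbalance for
the balancing stage to fix), 3–5 replicates per pair, 5 % outlier
probability (× 100 corruption), units alternating nM/µM, plus two Ki rows
per target for the endpoint filter to discard. Replicate counts start at 3
because MAD-based rejection is inert below that; outliers are additionally
capped below each pair's replicate majority (`cap_outliers=True`) so the
aggregated median — and hence the ground-truth label — survives curation
by construction. Hard cases (label noise, overlapping potency
distributions) are created by raising `noise_sd`, moving the medians, or
disabling the cap; they are deliberately not the default, which is the
parameter-recovery condition.

Truth is a complete cross-table: a compound is active only against its
origin target (families are target-specific), giving every (compound,
target) pair a label and making coverage metrics exactly computable.

What the panel does **not** emulate: real assay heterogeneity (mixed
protocols, inter-lab variance), promiscuous compounds hitting several
targets, congeneric-series bias inside a family, censored measurements,
and target spaces that overlap chemically — so passing tests demonstrate
machinery correctness and parameter recovery under clean conditions, not
expected performance on ChEMBL-scale data.

## Problem sizes and determinism

The test suite and examples run the default 5-target panel (600 compounds,
~2 400 assay rows, 75 models), which completes in well under a minute on a
single CPU; unit tests use a 2-target panel. One global seed fans out to
per-stage seeds via a fixed CRC-based derivation (`derive_seed`), so any
stage can be reproduced in isolation; identical seeds reproduce every
report byte-for-byte.

## Known limitations

- Radius-8 folded fingerprints make Gaussian naive Bayes brittle under
  label noise: a single mislabeled training compound can collapse its
  holdout recall on that target, because near-molecule-specific bits give
  the contaminated class spurious likelihood mass.
- The 123-property manifest is a pinned stand-in list; swapping it changes
  DSC models and is intentionally version-gated.
- The AD is a single centroid ball per descriptor space; multi-modal
  training sets (several scaffold families per target) would be better
  served by a nearest-neighbor distance, which is not implemented —
  `ADRegion` isolates the distance logic so the variant can be added
  without touching the models.
- Consensus weighting is a plain mean; no per-model weighting is applied.
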