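# nucleograde

Computational grading of breast tumors from the spatial architecture of their
nuclei. `nucleograde` is aimed at computational-pathology researchers who want
a tested, reusable implementation of a centroid-based grading pipeline: given
the malignant-nucleus centroids of core-needle-biopsy (CNB) sections and a
patient's routine clinical markers (age, ER%, PR%, HER2), it classifies
Nottingham grade as high (G3) versus low/intermediate (G1,2) and fuses the two
information channels into an ensemble probability.

## What it computes

**52 spatial features per CNB section**, from nuclear centroids alone:

- 24 *nuclear-graph* features: Voronoi-cell area, perimeter and maximum vertex
  distance; Delaunay edge lengths and triangle areas; minimum-spanning-tree
  branch lengths — each summarized by mean, population standard deviation,
  min/max ratio, and the disorder statistic σ/(μ+σ) ∈ [0, 1);
- 27 *nuclear-density* features: neighbor counts within four radii, distances
  to the k-th nearest neighbor for two k, and min/median/max of the k-NN
  density estimate ρ(i) = k/(π r_k(i)²);
- the nuclear count.

**A leakage-audited ML protocol**: Pearson-r² collinearity pruning with
point-biserial tie-breaking, patient-level stratified 70/30 split (per-class
ceil rule), Z-score standardization with retained training parameters, SMOTE /
borderline-SMOTE minority oversampling, sequential forward feature selection
repeated over reshuffled 10-fold CV with modal-subset voting (≤ 10 features),
randomized hyperparameter search, and a 15-quantity diagnostic metric panel
(AUC, Sn/Sp, predictive values, likelihood ratios, DOR, F1).

**Probability fusion**: section probabilities are averaged per patient with
tumor-bed-ratio (TBR) weights, then fused with the clinical probability as
p = (1−w)·p_clin + w·p_spat, with w scanned over {0, 0.01, …, 1} by training
cross-validation.

**Instance-segmentation metrics** (Aggregated Jaccard Index, unscored AP/mAP
over IoU 0.50–0.95, precision/recall/F1 at IoU 0.5 and 0.7) for evaluating
nucleus segmentation masks, plus a seeded synthetic-cohort generator so the
whole pipeline is testable without any slide data.

## Worked example

```python
from nucleograde import (CohortSpec, GradeClassificationModel,
                         PipelineConfig, generate_cohort)

cohort = generate_cohort(CohortSpec(n_patients=60, seed=7,
                                    sections_per_patient=(1, 2)))
cfg = PipelineConfig(clinical_models=("logistic",),
                     spatial_models=("logistic",),
                     sffs_iterations=4, sffs_folds=4,
                     rgs_iterations=5, rgs_folds=4, fusion_folds=5, seed=7)
res = GradeClassificationModel.from_cohort(cohort, config=cfg).fit()
print(res.summary())
```

prints (abridged):

```
Grade classification pipeline (G3 vs G1,2)
==========================================================
patients: 41 train / 19 test
selected ensemble: clinical=logistic + spatial=logistic
fusion weight w* = 0.63 (clinical 37% / spatial 63%)
...
                    AUC    ACC      Sn      Sp     PPV  ...
clinical:logistic 0.795 73.684  72.727  75.000  80.000
spatial:logistic  1.000 94.737 100.000  87.500  91.667
ensemble          1.000 94.737  90.909 100.000 100.000

leakage audit: clean
```

Here the synthetic G3 group is denser and more clustered than G1,2 by
construction, so the spatial channel separates the test patients almost
perfectly; the fusion scan accordingly puts most of the weight (w* = 0.63) on
the spatial channel. The metric columns are the standard diagnostic panel on
the held-out patients; "leakage audit: clean" certifies that test patients
were touched exactly once, at final evaluation.

The same stages are scriptable from a shell:

```bash
nucleograde simulate --seed 17 --out cohort/
nucleograde extract --centroids cohort/centroids.csv --out features.csv
nucleograde train --features features.csv --clinical cohort/clinical.csv \
    --sections cohort/sections.csv --seed 17 --out run1/
```

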