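# Methods

## Problem and model

The package classifies breast-tumor Nottingham grade as a binary task — high
grade (G3) versus low/intermediate grade (G1,2) — at the patient level, from
two channels: (i) clinical markers routinely reported on diagnostic biopsies
(age in years, ER and PR percentages, HER2 status), and (ii) the spatial
architecture of malignant-nucleus centroids in each core-needle-biopsy (CNB)
section, summarized by 52 features. Nucleus detection itself (a segmentation
network in the original workflow) is out of scope; centroids are an input, and
the synthetic generator stands in for them.

## Spatial features

All features are computed from 2-D centroids in pixel units (no
pixel-to-micron calibration is applied; none is assumed).

Population statistics. Every per-object distribution (cell areas, edge
lengths, …) is summarized by four statistics: mean; population standard
deviation (divide by n — configurable but the default, and the convention
used throughout); min/max ratio (defined as 1 when all values are equal,
including all-zero); disorder σ/(μ+σ), an algebraic rewriting of the
cell-graph disorder statistic 1 − 1/(1+σ/μ) that avoids 0/0 at μ = 0 and is
defined as 0 when σ = 0. Disorder lies in [0, 1), min/max ratio in [0, 1].

Graph block (24). Voronoi tessellation: per bounded cell, polygon area,
perimeter and maximum pairwise vertex distance (12 values). Unbounded cells
are excluded rather than clipped — clipping would impose arbitrary boundary
geometry; the statistics therefore describe interior packing. Delaunay
triangulation: unique edge lengths ("sides", each shared edge counted once)
and per-triangle areas (8 values). MST: the n−1 Euclidean minimum-spanning-
tree branch lengths (4 values), computed on the Delaunay edge graph (the
Euclidean MST is a Delaunay subgraph), with a complete-graph fallback for
degenerate (e.g. collinear) inputs.

Density block (27). With the default configuration: neighbor counts within
radii (25, 50, 75, 100) px → 4 × 4 statistics; distance to the k-th nearest
neighbor for k ∈ {3, 5} → 2 × 4 statistics; and min/median/max of the k-NN
density ρ(i) = k/(π·r_k(i)²) with k = 5 → 3 values. A point is never its own
neighbor. The 16 + 8 + 3 decomposition is the package's reading of a
"27 density features" design: it is the unique small decomposition consistent
with four distance bands, two neighbor counts and three ρ summaries. The
radii and k values are plausible for nuclei at 40× magnification but are
package defaults, not measured constants; they are configurable, and the
default configuration is what the 52/24/27 structural tests pin down.

House-keeping. Exact-duplicate centroids are merged before tessellation
(count logged). Sections with fewer than 10 nuclei are excluded with an
explicit exception/log entry — 10 is the smallest count at which all four
geometric constructions are comfortably well-posed — never silently dropped.

Univariate comparison uses the two-sided Mann–Whitney U test per feature
(rank-based, no normality assumption); constant features are reported with
p = 1 and a tie flag rather than dropped.

## ML protocol

- Collinearity pruning: pairs of continuous features with Pearson r² ≥ 0.7
  are resolved by dropping the member with the lower |point-biserial|
  correlation (Pearson against the 0/1 label), visiting pairs in descending
  r²; constant features are flagged, not dropped.
- Split: patient-level, label-stratified, test count per class =
  ceil(0.30 × class size). For a 138-patient cohort with 80 G3 / 58 G1,2 this
  yields 24 + 18 = 42 test patients (G3 prevalence 57.14%).
- Standardization: Z-scores with training means/SDs retained and re-applied
  verbatim to the test set; zero-variance features are flagged.
- Oversampling: plain SMOTE for the clinical channel, borderline SMOTE for
  the spatial channel (danger points = minority samples whose k-nearest
  overall neighborhood is at least half, but not entirely, majority). Both
  are implemented in-package and applied inside training folds only; a
  borderline call with no danger points falls back to plain SMOTE with a
  warning.
- SFFS: plain sequential forward selection (a floating add/remove mode is
  available behind a flag), repeated for independent iterations with fresh
  fold shuffles; the criterion is mean CV AUC; growth stops at 10 features
  or when the best addition improves the criterion by less than tol = 1e-3
  (an explicit stop rule; "no improvement" is otherwise numerically
  ill-defined). The reported set is the modal (most frequent exact) subset,
  ties broken by higher mean CV AUC then lexicographic order.
- Randomized search draws parameter settings from per-model spaces shipped as
  a versioned default dict (conventional ranges; not claimed to match any
  external appendix) and maximizes mean CV AUC.
- Spatial models train on section rows labeled with their patient's grade;
  CV folds are grouped by patient so sections of one patient never straddle
  folds — a deliberately leakage-safe choice, possibly stricter than
  strictly necessary. Gaussian Naive Bayes is refused for the clinical
  channel (HER2 is ordinal, violating its continuous-Gaussian assumption).
- The metric panel is computed from confusion counts at a fixed probability
  threshold of 0.5 (an unexceptional default; all panel identities hold at
  any fixed threshold) plus rank-based AUC.

## Aggregation and fusion

A section's tumor-bed ratio is its tumor-bed pixel area divided by the summed
areas of its patient's sections; patient spatial probability = TBR-weighted
average (uniform weights, logged, when areas are missing). Fusion is the
convex combination (1−w)·p_clin + w·p_spat on a 101-point grid w ∈ {0, 0.01,
…, 1}; w is chosen by mean 10-fold CV AUC on training patients with ties
resolved toward smaller w (prefer the clinical-only model). The same fold
assignment is reused across the grid, so the endpoints reproduce each
single channel's CV AUC exactly. Training-side probabilities entering the
scan are out-of-fold cross-validated predictions (precomputed at the patient
level; the scan does not refit models per weight). When several clinical and
spatial models are available, every pairing is scanned and the pair is
selected by training-CV AUC — never by test performance.

## Segmentation metrics

AJI pairs each ground-truth instance (ascending id; ties by larger
intersection) with the available prediction of maximal IoU and reports
aggregated intersection over aggregated union plus unmatched-prediction
pixels. Matching at a threshold is greedy one-to-one in descending IoU.
AP uses the unscored convention AP(t) = TP/(TP+FP+FN) averaged over IoU
thresholds 0.50–0.95 (step 0.05): the masks carry no confidence scores, so
score-ranked COCO AP is not applicable — a documented divergence.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
tissue appearance. Per group: age ~ Normal (51.6 ± 10.8 vs 50.3 ± 9.2 y,
clipped to [25, 90]); ER and PR are zero-inflated — a point mass at 0
(receptor-negative) plus a scaled-Beta component on (0, 100] — because the
low-grade group is strongly ER-positive (median ≈ 90) while the high-grade
group's ER median is 0, which no plain normal can reproduce; HER2 ~
Bernoulli (≈ 0.45/0.49). Spatially, G3 sections default to a Thomas cluster
process (expected 450 nuclei, ~40 parents, σ = 25 px) and G1,2 to hard-core
sequential inhibition (expected 250 nuclei, 12 px minimum spacing) on a
750 × 750 px extent, encoding the higher count and stronger clustering of
high-grade sections without claiming any specific process generated the real
data; the per-section intensities are realism choices, fixed once. Tumor-bed
areas are uniform fractions (0.2–0.8) of the section area. Determinism: one
root seed, per-patient substreams keyed by counter, so enlarging a cohort
never reshuffles existing patients; identical (spec, seed) gives
byte-identical CSV output.

Instance masks stamp disks of a given radius at the centroids (overlap pixels
go to the nearest center, with a warning); the paired "prediction" applies
controlled perturbations (instance dropping, exact-magnitude center shifts,
radius dilation/erosion) so the expected metric regimes are known — e.g. a
shift by exactly one radius gives per-instance IoU ≈ 0.243 by the circle-lens
closed form.

What passing tests do not show: the generator produces no staining artifacts,
no segmentation errors correlated with tissue context, no inter-section
correlation within a patient beyond shared group parameters, and marginals
only as faithful as the distributions above — so green tests certify the
pipeline's mechanics and its statistical contracts, not clinical performance
on real slides.

## Pre-processing

Tissue masking is Otsu thresholding on grayscale (tissue = below threshold)
followed by binary closing and small-object removal. Tiling is a
non-overlapping grid anchored at (0, 0) (stride/offset being a free choice),
size 750 px, discarding tiles with more than 10% background while keeping
exhaustive grid accounting. Stain normalization is Macenko-style: SVD of
optical densities above β = 0.15, stain vectors at the 1st/99th angle
percentiles, concentrations normalized to a standard H&E reference basis at
the 99th percentile; near-white tiles take a flagged no-stain path and are
returned unchanged. A Reinhard-style alternative was considered and dropped
to keep one well-tested path; the reference basis ships as configuration.

## Problem sizes and numerical choices

Library defaults follow the full protocol (SFFS and randomized search: 100
iterations × 10-fold CV). The shipped tests and the acceptance script run the
pipeline at desk scale — 200-patient cohorts, 1–2 sections per patient, SFFS
15 iterations × 5 folds, randomized search 10 iterations, logistic models for
both channels — sizes chosen as the package's own single-CPU reproduction
setting; all protocol constants remain available at their full defaults. The
null-cohort chance-level check averages the ensemble test AUC over three
seeds, since a single ~60-patient test split has a null-AUC standard
deviation near 0.09 and a one-seed check would mostly measure sampling noise.
Oracle-equivalence tests (Prim MST, brute-force k-NN and radius counts) are
exact to 1e-9; rasterized Voronoi areas match polygon areas within 2% at the
chosen raster pitch.

## Known limitations

- The 52-feature set is centroid-only: no nuclear morphology, texture or
  CNN-derived features.
- Real-cohort performance figures are not reproducible here (private slides,
  GPU-trained networks); the pipeline's claims are structural and
  property-based.
- The density-feature radii/k defaults are conventions, not fitted values.
- Borderline-SMOTE's danger definition uses the common "at least half
  majority neighbors" rule; other variants exist.
- Whole-slide pyramid formats are unsupported; pre-processing operates on
  desk-scale RGB arrays.

Note on parameter recovery: when a planted signal carrier is involved in a
pruning merge (r² above the threshold against a near-duplicate), the carrier
surviving into the model is the merge representative, and recovery checks
follow the pruning report's kept/dropped chain rather than the raw column
name — the pruned-away duplicate and its representative are the same signal
by the pruning rule's own definition.
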