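# Methods

## Problem and model

`cordfa` implements a slice-level analysis of cervical spinal-cord
diffusion-tensor imaging (DTI) for distinguishing injured from healthy
cord. The unit of observation is one axial slice with a binary region of
interest (ROI) marking the cord cross-section. The quantity of interest
is fractional anisotropy (FA),

    FA = sqrt(3/2) * sqrt(sum_i (lambda_i - lbar)^2) / sqrt(sum_i lambda_i^2),
    lbar = (lambda_1 + lambda_2 + lambda_3) / 3,

computed from the eigenvalues of the per-voxel diffusion tensor. FA is
unitless in [0, 1]: 0 for isotropic diffusion, 1 in the single-direction
limit, and invariant to eigenvalue scaling and permutation. A healthy
cord has coherently oriented white-matter tracts and high FA; injury
disrupts tract integrity and lowers it.

The analysis proceeds in stages:

1. **FA map** — eigenvalues via `numpy.linalg.eigvalsh`, FA per voxel on
   the ROI, zero outside.
2. **Quadrant partition** — the ROI is split into posterior (P), anterior
   (A), left (L) and right (R) subregions by the two 45-degree diagonals
   through a center point; the four mean FA values form one record.
3. **Feature expansion** — the 4 base features are expanded to all
   2^4 − 1 = 15 non-empty subset averages, in a fixed canonical order
   (singletons, pairs, triples, full set). Composites are unweighted
   row-wise means, so composite class means equal the means of component
   class means exactly.
4. **Screening and selection** — per-feature pooled two-sample t-tests
   (patient vs normal slices); R-value/RFS ranking with ReliefF as an
   independent comparator.
5. **Classification** — Euclidean k-nearest-neighbor, evaluated by
   leave-one-out cross-validation (subject level, k=1) and stratified
   three-fold cross-validation (slice level, k=5), reported as confusion
   counts with accuracy, sensitivity (injured detection rate, positive
   class = injured) and specificity.

## Synthetic cohort calibration

No public spinal-cord DTI cohort with quadrant annotations exists, so the
generator emulates the clinical study conditions: 9 patient and 5 control
subjects, 12 axial slices per subject (the reported per-subject counts,
14–15 retained slices, do not divide the 164-slice total evenly, so the
per-subject count is a parameter rather than a guess; 12 slices give
108/60 slices per class, close to the reported 106/58).

Per-slice base features (P, A, L, R) are drawn from class-conditional
multivariate Gaussians. The class means are the published per-region FA
averages (patient / normal):

| region | patient | normal |
|--------|---------|--------|
| P      | 0.427   | 0.535  |
| A      | 0.451   | 0.684  |
| L      | 0.475   | 0.645  |
| R      | 0.419   | 0.610  |

The within-class dispersions are not published; the only dispersion
information available is the per-region t-test p-values. `cordfa`
recovers a pooled SD per region by inverting the pooled two-sample
t-test at group sizes 106/58 (df = 162): given two-tailed p, solve
`p = 2 P(T_162 >= |t|)` for t, then `s = diff / (t * sqrt(1/106 + 1/58))`.
The recovered SDs are approximately 0.108 (P), 0.099 (A), 0.098 (L),
0.091 (R) FA units — plausible magnitudes for per-slice quadrant means.
The round-trip (SD back to p) reproduces the p-value to 1e-9 and is the
defining property test.

Adjacent cord quadrants share tissue, so base regions carry a common
pairwise correlation, default 0.3; tests also exercise 0 and high values.
Only the 4 base regions are sampled; all 15 features are computed
downstream, guaranteeing internal consistency of the composites. Samples
are clamped to [0, 1] (FA is bounded by definition); at the calibrated
SDs clamping touches well under 1% of values.

What the generator does **not** emulate: acquisition physics (echo-planar
distortion, b-values, gradient tables), partial-volume contamination at
the cord/CSF boundary, spatially varying noise, inter-subject mean
shifts (slices within a subject are i.i.d. around the class mean), and
any within-subject slice ordering. Passing tests therefore demonstrate
the pipeline's correctness and its behavior under the assumed Gaussian
feature model — not clinical performance on real data.

Image phantoms are elliptical ROIs with per-quadrant FA constants plus
Gaussian noise, either directly as FA maps or as prolate tensor fields
whose eigenvalue triple `(1+2d, 1-d, 1-d)` is solved in closed form to
attain the target FA (`d = f / sqrt(3 - 2 f^2)`).

## Numerical and design choices

* **Center point.** The ROI center defaults to the marginal-median
  convention: the coordinate at which the cumulative mask sum along each
  axis first reaches half the total. Center of mass is a config
  alternative; the two agree on symmetric ROIs.
* **Diagonal tie-break.** Pixels exactly on a partition diagonal go to
  the sector counter-clockwise of the boundary (image-up = +90 degrees);
  the center pixel, whose angle is undefined, lands in the right sector.
  Any fixed rule suffices; this one is tested against exhaustive
  enumeration. No further per-voxel rebalancing about the center is
  performed.
* **Orientation.** Image-direction to anatomy mapping (default
  up=anterior, down=posterior, left=left, right=right) is configuration;
  acquisition rotations/flips belong there, not in the partition code.
* **t-tests.** Pooled (Student) two-sample, two-tailed by default, df =
  N − 2 — the same pooled form the SD recovery inverts; Welch available
  as a flag. Zero variance in both groups with equal means reports
  t = 0, p = 1 rather than NaN.
* **R-value.** The overlap-count definition — a record is congested when
  more than `threshold` of its `k_neighbors` nearest records (Euclidean,
  ties by record index) belong to the other class; score =
  count / N, always an integer multiple of 1/N. Defaults k=7,
  threshold=3 (majority); the parameters used in the original clinical
  analysis are not published, so both are exposed rather than
  hard-coded. Feature indices in rankings follow the canonical expansion
  order throughout.
* **ReliefF.** Standard hit/miss formulation with per-feature diffs
  scaled to the observed range; `n_iterations=None` visits every record
  once in index order, making the weights fully deterministic and
  directly checkable against a naive trace.
* **KNN determinism.** Unweighted Euclidean majority vote; vote ties go
  to the class of the single nearest neighbor, distance ties to the
  lower record index. Three-fold CV is stratified by class with fold
  assignment a deterministic function of the seed; single repetition by
  default.
* **Negative eigenvalues** (tensor-fit noise) pass through to the FA
  formula unmodified but are counted in a QC field, so data problems
  surface instead of being clamped away. The all-zero tensor maps to
  FA = 0 by convention.
* **FSDD and CBFS** selectors are not implemented: no formula is
  available, only one-line descriptions. The ranking interface
  (`FeatureRanking`) is method-tagged so they can be added from their
  original sources. SVM is likewise out of the core surface; the
  scikit-learn implementation can serve as an external comparator.

## Problem sizes

Defaults used by the test suite and the acceptance script: cohorts of
14 subjects × 12 slices (168 slice records), 50 cohort replicates for
the stochastic checks, 10,000 random triples for FA property sweeps,
100-instance brute-force oracle comparisons and 1,000 random masks for
the partition invariant. The calibration check uses 10,000 slices per
class so sample means resolve to within three standard errors.

## Known limitations

* The published R-value scores and slice-level accuracies of the
  clinical cohort cannot be reproduced without the (undeposited)
  clinical data; the package reproduces every number computable from
  printed inputs and the stochastic behavior of the calibrated model.
* The marginal-median center and the diagonal tie-break are one
  defensible reading of a loosely specified procedure; both are
  configurable or documented where they are fixed.
* Subject-level aggregation assumes every slice of a subject shares one
  label; cords with mixed injured/normal slices per subject are rejected
  rather than silently averaged across labels.
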