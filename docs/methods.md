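# Methods

`footshape` implements a geometric-morphometrics pipeline for healthy adult
3D foot shape: synthetic (or scanned) surface cohorts are brought into
dense anatomical correspondence, superimposed by Generalized Procrustes
Analysis (GPA), summarized by a PCA point-distribution model, and related
to subject factors by multivariate linear regression with BIC forward
selection, post-hoc power analysis, and per-vertex asymmetry/loading
measures.  This note records the model, its assumptions, the numerical
choices, and what the synthetic cohorts do and do not establish.

## Shape correspondence

Every scan is re-expressed on the vertex ordering of one reference mesh by
non-rigid registration: `X_target ≈ Ψ(T(X_reference), β)` with `T` an
affine transform and `Ψ` an elastic deformation whose looseness grows with
the elasticity parameter β.  The solver alternates, per stage of an
increasing β schedule:

1. **Affine step** — closed-form least-squares affine fit to the current
   nearest-point matches.
2. **Elastic step** — per-vertex displacements `d` minimizing
   `Σ w_i ‖x_i + d_i − y_i‖² + (1/β) Σ_{(i,j)∈E} ‖d_i − d_j‖²`,
   where `E` are template edges (combinatorial graph Laplacian) and
   `w_i ∈ {0,1}` flags accepted matches.  Larger β therefore admits more
   deformation.  The linear systems (one per coordinate) are sparse SPD
   and solved exactly.

Matches are nearest target vertices refined by projection onto their
incident triangles, rejected beyond a distance cap (default 15 mm) or a
normal-incompatibility cap (default 60°); the target's open boundary ring
(an artifact of the ankle crop, not anatomy) is excluded.  Unmatched
template vertices carry no data term and follow the smoothness
interpolation.  Two choices matter for accuracy and reproducibility:

* **Pose-covariant initialization.**  The affine ICP starts from a
  principal-axes alignment (best of the four proper sign combinations by
  nearest-neighbour distance).  This makes registration equivariant under
  rigid motion of the target and robust to arbitrary scan pose.
* **Final vertex-matching stage.**  Point-to-surface matching leaves the
  tangential position unconstrained on featureless regions (the sole), so
  the last β stage matches target vertices instead of surface points.  On
  deformation-only targets this cuts the mean ground-truth error from
  ~1.2 mm to ~0.3 mm; on isotropically remeshed targets it stays ~1 mm,
  well under the 2%-of-foot-length working tolerance.

Defaults: β schedule `0.05 … 5.0` in six geometric steps (stiff → loose,
two orders of magnitude), ≤ 20 inner iterations per stage, convergence
when no vertex moves more than 0.01 mm.  All are exposed in
`RegistrationParams`.

## Procrustes alignment

Classic three-step GPA: translate each corresponded shape's centroid to
the origin, scale to unit centroid size (root summed squared vertex
distance to the centroid), rotate to the evolving mean by the Kabsch
solution with reflections excluded (left feet are mirrored upstream).  The
mean is recomputed and re-normalized until no coordinate moves by more
than 1e-12 in a pass, so the result is a fixed point of the align-to-mean
map; the whole pass is repeated (default three times) with the converged
mean as the refreshed reference.  Pre-normalization centroid sizes are
stored so reporting can be restored to millimetres.  The final
configuration is rotated into a canonical data-derived frame (principal
axes of the mean, signs fixed by third moments, handedness enforced),
which removes the arbitrary global-rotation gauge and makes outputs
reproducible across runs and input orderings.

## PCA shape model

Shapes are modelled as `X = M + Σ P_i w_i` with orthonormal components
`P_i` from an SVD of the centered `N × 3V` matrix (never the `3V × 3V`
covariance).  Score variances use the `N − 1` denominator.  Sign
convention: the largest-magnitude coordinate of each component is
positive.  Explained-variance fractions are `σ_i² / Σ σ²`.

A point to note when validating against planted deformation modes:
superimposition removes the similarity-transform content of any
deformation, so the recoverable ground truth is the eigenstructure of the
planted mode covariance *projected into the similarity tangent space* at
the template (`planted_tangent_model`).  This matters: the global-width
mode has cosine ≈ 0.4 with the pure scaling direction, and comparing
against unprojected modes would understate recovery by construction.

## Factor regression

Following the regression orientation `F = W B + E` (factors as responses,
selected PC scores as predictors, `E ~ N(0, σ²I)` independent across
factor columns), the package provides:

* **BIC forward selection** of PCs: greedy, adds the PC that most
  decreases the total BIC (sum of per-factor univariate Gaussian BICs,
  parameter count `m(k+1) + m`), stops at the first non-improving step,
  ties break to the lower PC index.
* **Per-factor inference**: OLS fit, R², the overall-regression F-test
  p-value, and post-hoc power from the noncentral-F distribution with
  Cohen's `f² = R²/(1−R²)` and noncentrality `λ = f² n` at degrees of
  freedom `(k, n−k−1)`.  The analytic power matches a 50,000-replicate
  Monte-Carlo simulation to < 0.01 across a grid of (R², n, k).
* **PC–factor correlations**: Pearson by default (the analysis is linear
  throughout), Spearman by flag; raw two-sided p-values with a 0.05
  significance flag and no multiplicity correction, matching standard
  reporting for this table.
* **Asymmetry / loading measures**: per-vertex Euclidean distances
  between corresponded, aligned right-vs-left (or half-vs-full-loaded)
  shapes; the distance vectors get their own PCA + selection + regression.
* **Shape prediction** (`predict_shape`): the fitted linear map is
  inverted by least squares; because the coefficient matrix maps scores to
  factors, prediction uses its pseudo-inverse, truncating singular values
  below 0.1% of the leading one so that factors with (near-)zero fitted
  effect leave the predicted shape at the conditional mean instead of
  exploding through an ill-conditioned inverse.  Factor ranges follow the
  requested rule: 5th–95th percentile of the training distribution
  (default), mean ± 2 SD, or min–max.

**Pooling versus subject-level inference.**  The pipeline's default
factor table treats all scans as rows (n = subjects × 4), replicating the
common published treatment; with four scans per subject this
pseudo-replication makes per-factor p-values anti-conservative.  For the
recovery validation the package uses a two-level design: PCs are selected
on the pooled scans (high power), while the per-factor F-tests run on
subject-averaged scores (independent rows, valid type-I control).  With
62 subjects this recovers three planted active factors in 20/20 replicate
cohorts with zero false flags on the inactive ones.  Pure subject-level
selection is *not* recommended: with ~250 candidate PCs and 62 rows,
greedy BIC selection overfits (max-selection bias) and simultaneously
lacks power for ρ ≈ 0.5 effects.

## Synthetic cohorts

The generator (`synthetic_cohort`) is first-class, tested code that
defines the study conditions:

* **Template** — a procedural foot-like closed surface (metaball implicit
  surface polygonized by marching cubes): elongated body, heel bulge, five
  toe lobes, medial arch concavity, flat-capped ankle stub; ~250 mm
  plantar length, ~95 mm breadth, plantar surface at z = 0 in the
  canonical frame (x mediolateral, y posteroanterior, z plantodorsal).
  A vertex-count target (default 2,500) is met within ±10% by iterating
  the grid pitch; construction is deterministic.
* **Six deformation modes** — smooth unit-norm fields, orthogonalized in
  order: (1) arch height (positive = flatter), (2) ball width + toe
  spread, (3) global width, (4) hallux medio-lateral rotation, (5) hallux
  vs second-toe length, (6) midfoot width.  Default weight SDs
  (60, 45, 35, 25, 18, 12) are strictly decreasing so PC order is
  identifiable; with 0.3 mm vertex noise the variance budget puts ~91% of
  total variance in the first six shape-space directions, consistent with
  what dense-correspondence foot studies report for six PCs.
* **Factors** — 31 female / 31 male by default; age, height, sport hours
  truncated-normal within published adult ranges; shoe size sex-specific
  (male ≈ +4 EU), BMI correlated with age (ρ ≈ 0.35), weight derived from
  BMI and height.  Mode weights are `B_trueᵀ z + residual` with z-scored
  factors.  Residual weights are (i) decorrelated from the factor columns,
  so a zero entry of the effect matrix means exactly zero sample
  association, and (ii) whitened so the realized weight covariance equals
  `diag(mode_sds²)` exactly (moment-matched sampling — standard in
  simulation design, and it removes the ~18% sampling noise a 62-subject
  draw would put on per-mode variances).
* **Scan effects** — bilateral asymmetry (a distinct smooth field,
  orthogonal to the modes, with per-subject amplitude) applied to right
  feet; loading applied as arch flattening (the mode-1 direction) on
  half-loaded scans; i.i.d. per-vertex Gaussian noise at the 0.3 mm
  scanner accuracy; random similarity pose per scan (±10°, ±20 mm,
  ±3% scale); optional isotropic remeshing (subdivision + vertex
  clustering on a randomly shifted 3 mm grid) plus vertex shuffling, with
  the ground-truth template-vertex positions retained per scan.

**What the synthetic cohorts do not establish.**  Real scans have
structured (not i.i.d.) scanner noise, soft-tissue deformation between
loadings far richer than one arch mode, partial occlusions, and shape
variation beyond six smooth modes.  Passing tests show the pipeline
recovers what it is designed to recover under controlled conditions; they
do not certify accuracy on arbitrary real scan data.

## Problem sizes and numerical choices

Validation runs use a 2,500-vertex template, 62 subjects × 4 scans for
model/factor recovery, 20 remeshed targets for registration accuracy,
50,000-replicate Monte-Carlo for power calibration and 10,000 null pairs
for correlation calibration — sizes chosen to exercise every contract at
full statistical scale while staying desk-runnable.  Degenerate inputs
fail loudly: empty geometry, out-of-range face indices, zero-size shapes,
rank-deficient regression designs (collinear columns are named), constant
correlation columns, all-zero deviation fields.  Nearest-neighbour ties
break to the lowest vertex index; PCA signs follow the largest-entry
convention; all randomness flows from explicit seeds (the pipeline fans a
single study seed out to per-stage seeds via `numpy.random.SeedSequence`),
and a fixed configuration reproduces every CSV output bitwise.

## Known limitations

* Correspondence quality is bounded by the nearest-point matching model:
  strongly non-isometric targets (e.g. pathological deformity) may slide
  along featureless regions despite the final vertex-matching stage.
* The regression is linear with no interactions, by design.
* The 90% range rule is univariate (5th/95th percentiles of the varied
  factor); a joint-density contour is not implemented.
* PLY/OBJ/STL cover the interchange needs here; no mesh repair beyond
  validity checks is attempted.
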