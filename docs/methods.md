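# Methods

## Problem setting

Deep-learning auto-segmentation (DLAS) tools contour organs at risk on
head-and-neck planning CTs. Their accuracy degrades for patients whose
setup deviates from typical positioning, and sagittal neck tilt —
flexion or extension of the upper cervical spine — is a quantifiable
proxy for such deviation. `tiltqa` implements a QA analysis that (1)
measures neck tilt from cervical-cord and vertebra segmentations, (2)
splits a cohort into normal/abnormal tilt by percentile cutoffs, (3)
scores auto-contours against gold-standard contours geometrically and
dosimetrically, and (4) tests whether contour quality differs between
the tilt groups. Because real planning CTs and commercial DLAS outputs
cannot be redistributed, the package ships a phantom-cohort generator
that reproduces the statistical structure the analysis assumes, with
full ground truth.

## Coordinate conventions

All physical coordinates are LPS (x right→left, y anterior→posterior,
z inferior→superior), axis-aligned, with voxel-center semantics: voxel
(i, j, k) sits at `origin + (i·sx, j·sy, k·sz)` mm. NIfTI volumes whose
affine is a signed axis permutation are normalized to this convention
on read; oblique affines are rejected rather than resampled, because
resampling binary masks would change the very surfaces being scored.
Masks and dose grids for one patient need not share a grid; only the
two masks of a compared pair (and the five spine masks) must.

## Neck-tilt measurement

The cord mask is restricted to the longitudinal extent of C1–C4, taken
as the set of z-slices in which the union of the four vertebra masks
has any foreground ("longitudinal extent" is a slice-range notion, so
z-slice overlap is used rather than 3D intersection). PCA runs on the
3D physical coordinates of the remaining cord voxels; the leading
eigenvector of the coordinate covariance, oriented so v_z ≥ 0, is
projected onto the sagittal plane and

    tilt = atan2(−v_y, v_z)   (degrees)

so that flexion (superior cord leaning anterior, −y) is positive and
extension negative. PCA is deliberately 3D with PC1 projected to
(y, z) — not 2D PCA on (y, z) — since the two differ when lateral
spread dominates. A minimum of 20 cord voxels is required; below that
the covariance is unreliable on 2 mm slices. Eigenvalue ties are broken
deterministically (eigenvalue order, then lexicographic on absolute
components) and flagged.

As a per-patient cross-check, a least-squares line `y = a·z + b` is fit
through the four vertebra (y, z) centroids and `atan(−a)` compared with
the PCA angle; agreement within 2° is flagged per patient. We regress y
on z (not z on y) because z is the nearly error-free ordinate along the
spine. On phantom cohorts the two estimators agree to ≲0.5° with
Pearson r > 0.999.

**Stratification.** Thresholds are nearest-rank percentiles: the value
at rank `ceil(p/100·n)` of the sorted tilts, at the 12th and 88th
percentiles by default. A patient is abnormal iff their tilt is
strictly below the lower or strictly above the upper threshold; both
thresholds are inclusive-normal. This is the unique simple convention
that labels exactly 8 of 35 distinct tilts abnormal (4 below, 4 above),
the group size the cutoffs were designed to produce.

## Contour metrics

* **DSC** — Sørensen volumetric Dice by voxel counts, `2|A∩B|/(|A|+|B|)`.
* **Surface representation** — the exact set of voxel faces separating
  foreground from background (with implicit background padding outside
  the array). Each face carries its center and physical area. This
  representation was chosen over marching-cubes meshes because it makes
  an exact brute-force oracle feasible: all distances are Euclidean
  distances between face centers, with no subvoxel interpolation.
* **sDSC(τ)** — area fraction of both surfaces lying within τ of the
  other surface, τ = 2 mm by default; symmetric by construction.
* **MDA** — symmetric, area-weighted mean of nearest-surface distances.
  (Directed and element-count variants exist in the literature; the
  symmetric area-weighted form is implemented and stated in outputs.)

Nearest distances use a k-d tree, which is exact for Euclidean metrics;
tests verify exact agreement of tolerance membership with an O(n²)
all-pairs oracle and MDA agreement to 1e-9 mm. Comparisons where either
mask is empty yield a missing record (not 0 or ∞) and the pair is
dropped from cohort statistics, with a log entry.

## Dose analysis

Mean dose over a structure is the average of the dose field sampled
with trilinear interpolation at the mask's foreground voxel centers.
Sampling at voxel centers (rather than resampling dose onto the mask
grid) is exact for linear fields and introduces no resampling
artifacts; mask voxels outside the dose grid's physical extent raise an
error rather than being clamped. The signed difference is defined as
`test − gold` (negative: the auto-contour sits in lower-dose tissue);
the convention is stated in output headers since either order is
defensible. Structures whose gold contour receives < 5 Gy mean dose are
flagged `excluded` and omitted from cohort statistics — dose agreement
in near-zero-dose regions is not planning-relevant.

## Cohort statistics

Each (structure, source, metric) combination is compared between the
normal and abnormal groups with a two-tailed Wilcoxon rank-sum
(Mann–Whitney U) test: exact p by full enumeration when the combined
sample size is ≤ 20 with no ties, otherwise the normal approximation
with tie-corrected variance and continuity correction (the method used
is recorded per test; with groups of ~27 vs 8 the asymptotic branch is
the norm). If every pooled observation is tied the test is degenerate
and p = 1 is reported. Median differences are reported as
abnormal − normal, so degradation appears as negative DSC/sDSC deltas
and positive MDA deltas. No multiple-testing correction is applied —
each organ/source pair is a separate QA question at raw p < 0.05, with
tiers `*` (p < 0.05) and `**` (p < 0.01); readers scanning many rows
should keep the inflated family-wise error in mind. Box-plot summaries
use the 1.5×IQR whisker convention.

## Phantom cohort generator

Each patient is built from a true tilt θ drawn from Normal(12°, 15°)
truncated to [−25°, 70°] — median near 12–15°, normal range roughly
−5°…25°, extremes comparable to severe clinical flexion:

* **cord**: solid cylinder, radius 5 mm, length 60 mm, along
  `(0, −sin θ, cos θ)`;
* **C1–C4**: four 15 mm boxes (20 × 20 mm cross-section) stacked along
  the cord axis over its superior 60 mm, C1 most superior;
* **organs**: two parotid-like ellipsoids (semi-axes 12, 18, 22 mm)
  offset ±35 mm laterally from the superior cord end, and a midline
  brainstem-like control ellipsoid (10, 10, 20 mm) superior to it;
* **auto-contours**: per simulated vendor, the gold ellipsoid translated
  by a Gaussian vector with per-axis sd
  `σ(θ) = σ0 + k·max(0, |θ − median θ| − Δ)` (σ0 = 1 mm,
  k = 0.15 mm/deg, Δ = 15°), then dilated or eroded by a random 0- or
  1-voxel radius. The control organ always uses σ0, making it
  tilt-insensitive. The deadband makes normal-range patients
  statistically indistinguishable, mirroring the flat scatter expected
  for typical setups; translation + light morphology is the simplest
  error model that produces the tilt-dependent degradation signal;
* **dose**: `D(p) = 70·exp(−‖p−c‖²/(2·30²))` Gy with c at the superior
  cord end jittered by Normal(0, 10 mm) per axis — a head-and-neck-like
  bath giving parotid mean doses around 25–45 Gy, so the 5 Gy exclusion
  rule is exercised only occasionally.

Masks use CT spacing 1.27 × 1.27 × 2 mm; dose grids use 3 mm isotropic
spacing (the dose model has a 30 mm length scale, so trilinear error is
negligible). Each structure is rasterized on a tight bounding grid,
which keeps a 35-patient cohort generation plus full analysis near one
second and makes repeated-seed studies cheap. The whole cohort is a
bit-for-bit pure function of (config, seed).

**What the phantom does not emulate:** CT intensities (no HU image is
generated — no stage needs one), elastic or anatomy-dependent contour
errors, inter-observer variability in the gold standard, correlated
errors across vendors, and realistic treatment-plan dose falloff.
Passing phantom tests therefore demonstrates correctness of the
measurement and statistics machinery under a known generative model,
not clinical performance of any DLAS product.

## Problem sizes and observed behavior

Module tests use masks up to 12³ voxels against brute-force oracles
(100 random pairs for the oracle-equivalence check). Cohort-level
properties use the default 35-patient, one-vendor phantom; the
end-to-end detection-rate study repeats the full pipeline over 100
seeded cohorts, and `scripts/acceptance.py` uses a 25-seed ensemble.
At these settings, tilt recovery RMSE is ≈ 0.12°, and the pooled
parotid-like contrast is detected (p < 0.05) in ≈ 0.9 of seeds for the
geometric metrics (sDSC ≈ 0.93, MDA ≈ 0.91, DSC ≈ 0.89), but only
≈ 0.5–0.6 of seeds for the absolute mean-dose difference; per-parotid
(unpooled) detection rates are ≈ 0.65. With 8 abnormal patients whose
tilt deviations mostly sit just past the 15° deadband, and a ±1-voxel
morphology noise floor on every auto-contour, the dose contrast is
simply underpowered at these generator settings — the corresponding
end-to-end test documents this as a known failure rather than papering
over it. The control organ stays non-significant in ≥ 0.9 of seeds for
all metrics.

## Known limitations

* Geometric metrics require the gold and test mask of a pair to share a
  grid; cross-grid comparison would need a resampling policy, which is
  out of scope.
* Oblique NIfTI affines are rejected, not resampled.
* MDA is the symmetric area-weighted variant only.
* The rank-sum exact/asymptotic switch at combined n ≤ 20 mirrors
  common practice but is not configurable per test.
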