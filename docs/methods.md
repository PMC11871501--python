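# Methods

## Model and procedure

A 4D study is ten respiratory-phase bins (0 %–90 %), each carrying a binary
GTV mask on a shared mm voxel grid and one centroid position per implanted
fiducial marker. The 30 % phase is the reference (planning) frame; it is
configurable, and a study lacking the configured label fails loudly rather
than falling back.

For every marker subset of size ≥ 2 the analysis aligns each phase on the
subset's marker centroid and measures the residual motion of the GTV
centroid (see README for the formulas). Two equivalent evaluation routes
are implemented:

* **centroid mode** (default): the residual is computed algebraically from
  centroids, `(G_p − M_p) − (G_ref − M_ref)`. Translating a rigid structure
  translates its centroid by exactly the shift vector, so this is lossless
  and fast.
* **mask-shift mode**: each phase mask is literally shifted (voxel-snapped)
  and its centroid recomputed. This exists to validate the shortcut
  end-to-end; it differs from centroid mode only by the sub-voxel snap
  remainder, bounded by half a voxel per axis.

Pooling: per marker-count group (k = 2…5, plus "all") the per-combination
RMSE values of all cases are pooled per direction; the group reports min,
max, SD and the 95th percentile (the TLE). Conventions, both exposed as
arguments because the field does not standardize them:

* percentile — linear interpolation between closest order statistics
  (zero-based rank 0.95·(n−1)); values 1…20 give exactly 19.05;
* SD — population SD (divisor n).

The dependent variable of the correlation analysis is the per-combination
RMSE. The TLE itself is a single pooled number per group, so "correlation
of TLE with a covariate" is only well-defined at combination level; this
reading is deliberate and worth knowing when comparing against analyses
that phrase it loosely. Covariates per combination: per-axis marker–GTV
distance in the reference phase, and per-axis respiratory marker motion
(max displacement of the subset centroid from its reference position;
peak-to-peak available by argument). Pearson r and its two-sided p come
from `scipy.stats.pearsonr`; no multiplicity correction is applied by
default.

## Target construction and comparison

`gtv_union_shift` is the union of the per-phase GTV masks after each phase
is shifted by s_p (reference unshifted). `gtv_tle_ref` expands the
reference GTV by the per-axis TLE margins; `ptv_tle_ref` adds an isotropic
5 mm. Margin expansion is morphological dilation with an ellipsoidal
structuring element of semi-axes (lr, ap, si) mm built in physical
coordinates, so anisotropic spacing is handled correctly; a zero margin on
an axis forbids growth along it.

Mask shifts are snapped to whole voxels (round half away from zero per
axis) to avoid interpolation pseudo-volume on binary masks; the remainder
is returned by `snap_shift` for auditing. Grids are padded automatically
wherever a shift or expansion would otherwise clip (`pad=True` defaults),
and masks from different constructions are embedded on a common bounding
grid before set operations.

Comparison metrics: rV = |gtv_tle_ref| / |gtv_union_shift|; 3-D Euclidean
distance between the two centroids; and the geometric coverage fraction
|union ∩ PTV| / |union|. Coverage proxies dosimetric V100 % under the
assumption that the prescription isodose covers the PTV — a deliberate
simplification: no beam model, dose falloff, or interplay is represented,
so coverage numbers should be read as a lower-level geometric statement,
not a plan metric.

## Synthetic phantom

Each object (tumor, markers) follows
`baseline + amplitude·w(t_p + lag) + drift·p + noise`, t_p = p/10, with
`w = sin(2πt)` by default (an asymmetric `cos⁴(πt)` option dwells at exhale
for more realistic demos; the sinusoid is default because it admits exact
closed-form residuals). The tumor is rasterized as a sphere: a voxel is
occupied iff its center lies within the radius. Markers are mathematical
points; marker size is metadata only.

Default study conditions (chosen once as plausible for fiducial-tracked
lung SBRT, since no quantitative asynchrony distribution is available to
fit):

| parameter | default | rationale |
|---|---|---|
| phases / reference | 10 / 30 % | standard 4D-CT binning |
| tumor amplitude (LR, AP, SI) | U(0.5–3), U(1–5), U(6–15) mm | SI-dominant lung motion, >10 mm possible |
| tumor radius | U(5–15) mm | early-stage lung tumor sizes |
| marker lag | U(−0.1, 0.1) cycles | sub-cycle asynchrony |
| marker amplitude | tumor × U(0.75, 1.25) per axis | nearby but imperfect surrogates |
| marker offset from tumor | U(−25, 25) mm per axis | peritumoral implantation |
| positional noise SD | 0.2 mm | localization jitter |
| voxel spacing | 2 mm (cohort), 1 mm (oracle tests) | CT-like; finer where tolerance matters |
| cohort census | 2/3/4/5 markers × 1/2/4/4 cases (TLE), 2/3/4 × 2/5/3 (validation) | realistic marker-count mix; yields 157 combinations |

What the phantom does **not** emulate: deformable anatomy, hysteresis
beyond phase lag, intra-phase motion blur, CT reconstruction artifacts
(including marker elongation), delineation variability, and marker
migration. Passing tests therefore demonstrate correctness of the
*computation* under rigid, well-localized conditions — not robustness to
the artifact-driven errors that dominate some clinical cases.

The closed-form oracle `analytic_residual_rmse` evaluates the residual
directly from the continuous trajectories (no rasterization, noise
required to be zero) and anchors the parameter-recovery tests: mask-based
RMSE must agree within half a voxel diagonal (in practice agreement is
~0.1–0.2 mm at 2 mm spacing, since a digitized sphere's centroid error
averages out over thousands of voxels).

## Numerical choices and degenerate inputs

* All randomness flows from one seed; per-study and per-object generators
  are derived from (seed, index) and (seed, crc32(object id)), so outputs
  are order-independent and bit-reproducible.
* Deterministic combination order: by subset size, then lexicographic ids.
* Empty masks have no centroid (error); empty groups are omitted from
  pooling; correlations skip groups of n < 3 and zero-variance covariates.
* Sphere-exits-grid, off-grid shift without padding, missing
  (marker, phase) pairs, non-numeric coordinates, and axis-mapping typos
  all fail with targeted messages before any computation runs.
* Problem sizes in the test and acceptance runs (50 oracle phantoms, a
  3×3 amplitude/lag recovery grid, 200 noise seeds for the
  marker-averaging trend, 11 + 10 cohort studies at 2 mm spacing) keep the
  full suite at a few seconds while leaving every tolerance comfortably
  non-binding.

## Known limitations

* Alignment is pure translation of marker centroids; rotational or
  deformable registration and distance-weighted marker pooling are out of
  scope.
* DICOM-RT structure sets are not read; the interchange formats are raster
  masks (NRRD/NIfTI with axis-aligned orientation) plus CSV tracks, with
  the file-to-patient axis mapping declared in the study manifest.
* Margin application uses the cohort-level pooled TLE by default; explicit
  per-axis margins can be supplied instead (`margins_mode="explicit"`).
* Dose calculation and treatment planning are not modeled at all; see the
  coverage-proxy caveat above.
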