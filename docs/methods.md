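# Methods

Model, parameter rationale, numerical choices, and limitations for the
strokemap pipeline. Units: millimetres for lengths, mm³ for volumes; grids are
index-ordered (x, y, z) with the left→right axis first.

## 1. Statistical model

### Voxel lesion-symptom mapping (VLSM)

At each brain voxel *v*, subjects split into lesion-present and lesion-absent
groups according to their binary lesion masks. Behavioural scores are compared
with an unequal-variance (Welch) two-tailed t-test; Welch is used because
lesioned and unlesioned animals have no reason to share a variance. A voxel is
*testable* only when both sides have at least `min_group_size` subjects
(default 5); untested voxels carry NaN statistics and are reported separately
from non-significant voxels, since "no evidence" and "cannot be assessed"
are different statements.

Inference permutes the behaviour scores across subjects (`n_permutations`,
default 1000), holding the lesion masks fixed — this preserves the spatial
covariance of the lesion pattern while breaking the anatomy–behaviour
coupling. The per-voxel two-sided p-value uses the add-one estimator
p = (1 + #{|t*| ≥ |t|}) / (1 + P), which can never return 0 and is valid for
any P. Voxelwise p-values are corrected with the Benjamini–Hochberg (BH)
step-up FDR procedure at q = 0.05.

### Tensor-based morphometry (TBM)

Deformation is summarised per voxel by the Jacobian determinant
J = det(I + ∇u) of the displacement field u; analyses run on log J so
expansion and compression are symmetric and group effects are multiplicative.
Group maps use Welch t between label groups; behaviour maps use Spearman ρ
(rank Pearson), which is invariant to monotone transformations of the scores.
Voxels where any subject's J is non-positive (a folded deformation) are
excluded from testing, not clamped.

Resolving a BH rank-1 threshold q/m with per-voxel permutation p-values needs
at least m/q permutations — 840 000 for 42 000 voxels at q = 0.05
(`required_permutations`). Two escapes are provided:

- **Pooled null** (default): under the global null, permutation t-values are
  identically distributed across voxels, so the null samples are pooled into
  one distribution of size P × V. With ~11 600 in-brain voxels, 200
  permutations give a pooled null of 2.3 million values — p-resolution
  ~4 × 10⁻⁷, below the rank-1 threshold. The trade-off is the exchangeability-
  across-voxels assumption (marginals, not joint structure, must match).
- **Exhaustive enumeration**: when C(n, n₁) is at most the requested
  permutation count, all label assignments are enumerated and the null is
  exact.

### Threshold-free cluster enhancement (TFCE)

TFCE(v) = Σ_h e(h, v)^E · h^H · dh over thresholds 0 < h ≤ stat(v), where
e(h, v) is the extent of the connected component containing *v* at threshold
h. Defaults H = 2, E = 0.5 (the standard recommendation), 6-connectivity, and
a midpoint rule with dh = max|stat| / 100. The integrand's extent term is a
step function of h, so the quadrature converges first-order in dh; the test
suite pins the closed forms S³/3 (isolated voxel) and √N · S³/3 (uniform
N-voxel component) at 2 % accuracy with dh = S/200. Two-sided maps are
enhanced lobe-by-lobe (the negative lobe on the negated map). Family-wise
error correction uses the permutation distribution of the maximum in-mask
|TFCE|; one shared dh is used across the observed and all null maps so the
transform is identical within the family — the max-statistic argument is then
valid for any fixed dh and step count.

### Power calculations

Two-sample designs are sized with the noncentral-t distribution using
Welch–Satterthwaite degrees of freedom; the minimum detectable group mean is
found by bracketing and Brent root refinement on the power gap. A normal
approximation is *not* used: at the 30 v 10 morphometry design it misses the
third decimal of the minimum detectable mean J, whereas the noncentral-t
solution gives 1.055 (SDs 0.05/0.05) and 1.115 (SDs 0.05/0.20). When the
reference mean is 1.0 (a null Jacobian), log(mean) is reported alongside.

The minimum detectable correlation uses Fisher's z with the small-sample mean
correction E[z(r)] ≈ z(ρ) + ρ/(2(n−1)), which tracks the exact t-test of r
closely at moderate n (0.486 at n = 30, vs 0.492 for plain Fisher z; a
Monte-Carlo mode simulating the exact test is available for verification and
agrees within 0.005).

## 2. Synthetic phantom generator

### What it emulates

- **Geometry**: a 32³ grid at 0.234 × 0.234 × 0.5 mm (typical rodent T2
  acquisition), an ellipsoidal brain, an off-centre ellipsoidal ventricle.
- **Groups**: sham (no lesion), striatal, and striatal + cortical, the last
  adding a second more superficial sphere; lesion centres jitter by 1 voxel SD
  across subjects, radii by ~10 %.
- **Appearance**: lesions are hyperintense at a configurable contrast
  (default 3 reference SDs) on a noisy background, matching the segmentation
  rule *voxel > mean + 1 SD of the homologous contralateral ROI*.
- **Deformation**: the lesion and ventricle act as volume sources. A
  Gaussian-mollified point-source kernel u(r) = M(r)/(4πr²) · r̂ (whose
  divergence is the mollified source density) is convolved with the source
  map by FFT; by construction ∫(J − 1) dV over the brain approximates the
  prescribed volume change (tested at 10 %). Each subject adds a smooth random
  field (0.05 voxel SD) for registration-like noise. Magnitudes that would
  fold the grid are scaled down with a warning; generated fields are checked
  diffeomorphic (J > 0).
- **Behaviour**: four scores — left/right foot faults (%, clamped to
  [0, 100]) and grip strengths (g, floored at 0) — linear in total lesion
  volume plus Gaussian noise. Defaults: ffl = 20 + 1.5·V ± 10,
  gsl = 1000 − 15·V ± 100, with the ipsilateral pair uncoupled. At the mean
  striatal lesion volume (~7.5 mm³) the ffl shift is ~1.1 pooled SD, the
  effect scale the designs were sized for.
- **Reproducibility**: per-subject `SeedSequence(seed, spawn_key=(i,))`
  streams make each subject's data independent of cohort composition;
  ground truth (templates, volumes, slopes) is returned with the cohort.

### What it does not emulate

Registration error structure (noise is a smooth random field, not a
registration residual), partial-volume and bias-field artefacts, lesion shape
complexity (spheres only), longitudinal change, inter-site variation, or any
real behaviour distribution beyond a linear volume coupling. It is a
*calibration* instrument: faithful in the statistical properties the pipeline
relies on, deliberately simple everywhere else.

## 3. Numerical choices

- Jacobians use `np.gradient`-style central differences (one-sided at edges)
  and a hand-coded 3×3 cofactor determinant; exact for affine fields and
  matched to a brute-force oracle at 1e−12.
- Permutation engines are BLAS matrix products over sufficient statistics
  (group-sum matrices against score/value matrices), so thousands of
  permutations over ~10⁴ voxels run in milliseconds. Zero-variance
  permutation columns are set to +∞ (conservative).
- The FFT convolution uses `scipy.fft.rfftn` at size `next_fast_len(2s−1)`;
  the extracted "same" region is alias-free (overlap–save argument), keeping
  the kernel cacheable and the per-subject cost ~30 ms.
- BH is implemented directly (step-up on sorted p, NaNs excluded from m) and
  tested against `statsmodels.stats.multitest.multipletests` as an oracle.

## 4. Open design decisions

- Correlation-power method: bias-corrected Fisher z chosen as default; the
  plain Fisher z and Monte-Carlo exact modes remain available. The exact
  small-sample distribution of r has no closed form, so ±0.01 is the
  documented method tolerance.
- TBM pooled inference assumes across-voxel exchangeability of null t values;
  a per-voxel mode (`pool_across_voxels=False`) is provided when that is in
  doubt, at the cost of many more permutations.
- The smoothing scale of the deformation kernel maps from the two smoothness
  knobs as σ_mm = max(0.25, 0.5·μ + 0.25·λ); small σ keeps source mass inside
  the brain for boundary-near lesions (the volume-integral property), large σ
  gives smoother, more realistic fields.

## 5. Limitations

- VLSM per-voxel splits are confounded by lesion volume: behaviour couples to
  total volume, so voxels lesioned in only part of the lesioned group show
  diluted effects. This is a property of VLSM itself, visible in the phantom
  recovery tests (sensitivity is quoted at voxels with a clean group split).
- FDR control is asserted in expectation under the global null; dependent
  voxels make BH conservative but not invalid here.
- TFCE p-values are family-wise corrected only at the map maximum level;
  voxelwise TFCE p-values inherit the usual weak-FWE caveats away from the
  maximum.
- The phantom generator's noise model is Gaussian and stationary; calibration
  results transfer to real data only to the extent those assumptions hold.
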