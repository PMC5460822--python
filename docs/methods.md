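# Methods

## Problem

Second-order texture features — grey-level co-occurrence matrix (GLCM) and
run-length matrix (GLRLM) statistics — are widely used as imaging
biomarkers of tumor heterogeneity. Their values, however, depend on
acquisition and preprocessing choices that vary between scanners and
studies: the in-plane matrix size, the slice thickness, and the number of
grey levels the ROI intensities are discretized into (the dynamic range).
`tumortex` quantifies that dependence: it computes 16 classical 3D texture
features over a tumor region of interest under a grid of
resolution/dynamic-range configurations and summarizes per-feature
stability with the coefficient of variation (CV).

## Texture matrices

Both matrices are built on a quantized volume: integer grey levels
1..N on masked voxels, 0 outside the mask.

**Co-occurrence matrix.** `CM(i, j)` counts ordered pairs of masked voxels
at unit Chebyshev distance (all 26 neighbors in 3D) with levels `(i, j)`.
Both orders of each pair are counted, so the matrix is symmetric. Features
are evaluated on the matrix normalized to unit sum; this is the convention
under which `-sum p ln p` is a conventional non-negative Shannon entropy
(a raw-count entropy would be negative for counts > 1). Natural logarithms
throughout. The five CM features are Entropy, Homogeneity
(`sum p/(1+(i-j)^2)`), Contrast (`sum p (i-j)^2`), Dissimilarity
(`sum p |i-j|`) and Uniformity (`sum p^2`).

**Run-length matrix.** `RLM(i, j)` counts maximal collinear runs of `j`
consecutive masked voxels at level `i`, accumulated over the 13 direction
vectors of the 26-neighborhood (one per antipodal pair). Runs terminate at
level changes, at unmasked voxels and at the grid edge, so each masked
voxel belongs to exactly one run per direction and
`sum_ij RLM(i,j) * j = 13 * |mask|` — an identity asserted in the tests on
every input. The 13 directional matrices are **summed** into one matrix.
Averaging instead would leave the `1/nr`-normalized features unchanged but
rescale GLNU, RLNU and RPC; summation was chosen and is fixed here. The 11
RLM features are SRE/LRE, LGRE/HGRE, the four mixed moments (SRLGE, SRHGE,
LRLGE, LRHGE), GLNU, RLNU and RPC. RPC is defined as
`nr / sum_ij RLM(i,j) * j`, i.e. runs per voxel-direction incidence, which
confines it to (0, 1].

Degenerate masks are rejected loudly: the CM requires at least one
26-adjacent masked pair, the RLM a nonempty mask, rather than returning
silent zeros.

## Preprocessing grid

Each subject is evaluated under every combination of

* **in-plane matrix size** — native, and a coarser standard size obtained
  by bilinear interpolation at voxel centers with the physical extent
  preserved (output index `k` samples source index `(k+0.5)*n/t - 0.5`);
  only downsampling is allowed;
* **slice thickness** — native, and doubled by averaging disjoint pairs of
  consecutive slices (an unpaired trailing slice is dropped with a
  warning);
* **dynamic range** — N in {16, 32, 64} grey levels.

The default grid is 2 x 2 x 3 = 12 datasets per subject. Masks are
resampled with the same linear kernel and re-binarized at 0.5 (a
majority-like rule; the convention is a free choice and is fixed here).

Quantization is uniform min–max binning **within the ROI**: the masked
minimum maps to level 1 and the masked maximum to level N, equal-width
half-open bins with the top bin closed; a constant ROI maps entirely to
level 1. Two consequences are used as test invariants: levels 1 and N are
always attained on a non-degenerate ROI, and bins for N and 2N levels are
nested, so collapsing consecutive level pairs of the 2N quantization
reproduces the N quantization exactly. Nesting in turn forces CM Entropy
to be non-decreasing and Uniformity non-increasing in N. The intensity
range is recomputed per configuration, after resampling; whether the
original study inherited the raw-image range instead is not knowable from
its description, and recomputation is the package's fixed choice. This
fixed-bin-number convention is common in radiomics but not universal;
feature values are not comparable across quantization conventions.

## Robustness protocol

The CV of a series is `100 * SD / |mean|`, with the sample (n-1) SD by
default (`ddof` is configurable since the series have only 3 or 4 values,
where the flavor matters; all 16 features are positive so the absolute
value in the denominator is a formality). Series with fewer than two
values or a numerically zero mean are rejected, each with its own error.

* **Experiment 1** (dynamic-range robustness): for each feature, subject
  and spatial configuration, the CV over the three dynamic ranges; then
  mean and SD over subjects. Output: 16 features x 4 spatial
  configurations.
* **Experiment 2** (spatial robustness): for each feature, subject and
  dynamic range, the CV over the four spatial configurations; then mean
  and SD over subjects. Output: 16 features x 3 dynamic ranges.

A cell is *robust* when its across-subject mean CV is strictly below the
threshold (default 10%); a feature is robust overall when all its cells
are. Missing grid cells fail loudly; there is no imputation.

## Synthetic cohort

No image data ships with the package; a phantom generator stands in for a
patient cohort. Each phantom is an ellipsoidal tumor in a uniform
background, with three intensity layers (bright enhancing rim over the
outer `rim_fraction` of the normalized radius, darker core, dark
background — the enhancing-rim phenotype of contrast-enhanced
T1-weighted glioblastoma imaging), plus a spatially correlated intensity
field (seeded white noise smoothed with an isotropic Gaussian of width
`texture_correlation_length`, rescaled to SD `texture_amplitude` inside
the mask) and independent additive Gaussian noise, clipped at zero to
mimic magnitude MRI (a Rician magnitude model is available behind a
flag). The mask is the ellipsoid inequality evaluated at voxel centers
(center-in convention), which makes a brute-force voxel enumeration an
exact oracle. Nothing is published about intra-tumor intensity statistics
at this level of description; the correlated-field construction is the
package's own choice of the simplest controllable spatial texture.

Cohorts jitter geometry and heterogeneity per subject (radii +-15%,
intensity levels +-5%, texture amplitude and correlation length +-20%,
sub-voxel center shifts) from named substreams of a single seed, so
identical (spec, seed) reproduce the cohort bit-exactly.

Default parameters (arbitrary units; grid in voxels, lengths in mm):

| parameter | test scale | full scale | why |
|---|---|---|---|
| grid / spacing | 64x64x16 @ 1x1x1 | 432x432x120 @ 0.5x0.5x1 | full scale mirrors the emulated acquisition matrix; the test scale keeps a cohort run in seconds |
| tumor radii | 12, 10, 6 | 24, 20, 18 | ~3000 (test) masked voxels, enough for stable second-order statistics after 4x downsampling |
| background / core / rim | 20 / 100 / 180 | same | strong rim contrast, clearly above the noise floor |
| texture amplitude / correlation length | 15 / 2.5 | same | visible intra-tumor heterogeneity at a few-voxel scale |
| noise sigma | 5 | same | ~5% of core intensity, a plausible SNR for 3T CE-T1 |

The analysis drivers and tests pair the 64-voxel grid with matrix sizes
{64, 38}, preserving the 256/432 ratio of the full-scale protocol, and
slice thicknesses {1, 2} mm.

**What the phantoms do and do not show.** They exercise every pipeline
stage under realistic geometry and give the qualitative dependence
structure: pair-distribution entropy grows roughly logarithmically with
N, so no feature — entropy included — is robust under dynamic-range
changes, while entropy is stable under spatial resampling. They do not
reproduce patient-level CV magnitudes: real glioblastomas have richer
spatial structure (necrosis, infiltration, vasculature) and scanner
noise, so cohort-level CV values here are illustrative, not clinical
estimates. On these smooth phantoms SRE and RPC also clear the 10%
spatial-robustness bound, which real tumors need not replicate.

## Numerical choices

* Quantization uses `floor((v - min)/(max - min) * N) + 1` clipped to N;
  exact ties at internal bin edges go to the upper bin (half-open bins).
* The RLM builder recovers grid lines by lexicographic sorting on (line
  base point, step along direction); it is checked against a naive
  line-walking oracle on randomized volumes.
* CV rejects means with |mean| <= 1e-12 as undefined rather than
  returning huge values.
* The robustness threshold comparison is strict (`mean CV < 10`), so a
  mean CV of exactly 10.0% is *not* robust.
* Feature tables are validated for grid completeness before aggregation;
  any missing (subject, spatial, grey) cell is an error listing the cells.

## Problem sizes

Tests and the acceptance script use the test-scale cohort (20 subjects,
64x64x16 grid, 12 configurations each — 240 extractions, 3840 feature
values), which completes in seconds; oracle cross-checks run on ~100
random volumes up to 6^3 voxels with <= 4 levels, where the O(V^2)
brute-force enumerations are exact and fast. The full-scale grid is
available through `default_spec(scale="full")` and the CLI.

## Known limitations

* No scanner physics: no bias field, no multi-coil noise correlation, no
  gadolinium kinetics, single sequence only.
* No intensity normalization across subjects, no bias-field correction,
  no registration; segmentation is an input, never computed.
* Interpolation is fixed to bilinear in-plane + pairwise slice averaging;
  other kernels (cubic, anti-aliased) would change feature values in
  detail.
* First-order histogram features and spectral/wavelet textures are out of
  scope.
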