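# tumortex

Robustness analysis of 3D texture features for tumor MRI under changes of
spatial resolution and grey-level dynamic range.

Radiomic texture features — grey-level co-occurrence matrix (GLCM) and
run-length matrix (GLRLM) statistics computed over a segmented tumor —
are candidate imaging biomarkers of tumor heterogeneity, but they are
only usable across scanners and studies if they are stable under the
protocol parameters that routinely differ: the in-plane matrix size, the
slice thickness, and the number of grey levels N the ROI is discretized
into. `tumortex` implements the full pipeline for measuring that
stability on 3D volumes:

* **16 features** from two second-order structures, both fully 3D:
  a symmetric 26-neighbor, unit-Chebyshev-distance co-occurrence matrix
  (Entropy, Homogeneity, Contrast, Dissimilarity, Uniformity — computed
  on the unit-sum normalized matrix, natural log), and a run-length
  matrix summed over the 13 antipodal direction pairs (SRE, LRE,
  LGRE, HGRE, SRLGE, SRHGE, LRLGE, LRHGE, GLNU, RLNU, RPC).
* **A 12-configuration preprocessing grid** per subject: {native,
  downsampled} in-plane matrix x {native, doubled} slice thickness x
  N in {16, 32, 64}, with ROI min–max quantization recomputed per
  configuration.
* **The coefficient-of-variation protocol**: CV = 100·SD/|mean| of a
  feature across one axis of the grid, per subject, then mean (SD) over
  subjects. Experiment 1 varies dynamic range at fixed resolution;
  Experiment 2 varies resolution at fixed dynamic range. A feature is
  *robust* when its mean CV stays strictly below 10%.
* **A synthetic cohort generator**: seeded, heterogeneous ellipsoidal
  tumor phantoms (enhancing rim, darker core, correlated intra-tumor
  texture, additive noise) so the whole pipeline runs and is testable
  without patient data. NIfTI-1 and DICOM-series input are supported for
  real data.

See `docs/methods.md` for the exact matrix conventions, formulas and
design choices.

## Worked example

```python
import tumortex as tt

# one synthetic subject: 64x64x16 grid, ellipsoidal rim+core tumor
phantom = tt.generate_phantom(tt.default_spec(scale="test", seed=7))
print(phantom.mask.n_voxels)            # 3048 tumor voxels

# the 12-configuration grid and the 16 features of one dataset
grid = tt.build_configuration_grid(
    phantom,
    tt.default_spatial_configs((64, 38), (1.0, 2.0)),
    tt.default_grey_configs((16, 32, 64)),
)
print(len(grid), grid[0].label)         # 12 m64_st1mm_dr16
f = tt.extract_features(grid[0])
print(round(f["Entropy"], 3), round(f["SRE"], 3))   # 4.272 0.771
```

`Entropy` is the Shannon entropy (nats) of the grey-level pair
distribution — higher means a more heterogeneous ROI; `SRE` is 1 when
every run of equal grey level has length 1, and values below 1 reflect
the longer runs that a coarse 16-level quantization produces.

The cohort-level analysis is a sequence of thin drivers:

```sh
python analysis/01_simulate_cohort.py        # 20 phantoms -> scratch/cohort/
python analysis/02_extract_features.py       # 240 rows x 16 features -> results/features.csv
python analysis/03_robustness_experiments.py # CV tables -> results/experiment{1,2}.csv
python analysis/04_feature_profiles.py       # per-subject normalized profiles
```

On the default seed-0 cohort, `03_robustness_experiments.py` prints (excerpt):

```
experiment1: mean CV (SD), % — robust overall: none
                 64x64; 1 mm    64x64; 2 mm    38x38; 1 mm    38x38; 2 mm
Entropy         23.83 (0.50)   21.33 (0.39)   21.16 (0.42)   19.74 (0.51)
Contrast       113.12 (0.09)  113.29 (0.10)  113.21 (0.11)  113.25 (0.15)

experiment2: mean CV (SD), % — robust overall: ['Entropy', 'RPC', 'SRE']
                  16 levels      32 levels      64 levels
Entropy         7.50 (1.23)    5.90 (0.99)    4.18 (0.80)
Homogeneity    25.31 (2.82)   29.44 (3.33)   31.34 (3.59)
```

Reading: each cell is the across-subject mean (and SD) of the CV, in
percent. Varying the dynamic range (Experiment 1) moves every feature by
20–110% — none is robust, entropy included, because pair-distribution
entropy grows roughly logarithmically with N. Varying only the spatial
resolution at fixed N (Experiment 2) leaves entropy within ~4–8% CV,
i.e. robust at the strict 10% bound. These synthetic-cohort numbers show
the qualitative dependence structure; patient-data CV magnitudes depend
on real tumor heterogeneity that phantoms do not reproduce.

A `tumortex` CLI wraps the same stages (`simulate`, `extract`,
`robustness`, `run`) for NIfTI/DICOM inputs; `tumortex run --help` shows
the pipeline options.

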