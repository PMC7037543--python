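# lcmap

Semi-automated mapping of the locus coeruleus (LC) from neuromelanin-sensitive
magnetization-transfer (MT) 7T MRI, with synthetic phantoms and cohort-level
statistics for validating the full pipeline end to end.

The LC is a small noradrenergic brainstem nucleus whose neuromelanin content
shortens T1 and produces hyperintensity on MT-prepared images. `lcmap`
implements a complete measurement chain:

1. **Enhancement mapping** — voxelwise fractional enhancement
   `E = S_MT / S_noMT` between an MT-weighted and a non-MT reference volume
   acquired on the same grid.
2. **Three-class Gaussian mixture** — a univariate mixture with K = 3
   components is fitted to the enhancement values by
   expectation–maximization. The components are ordered by mean and assigned
   roles: lowest = white matter, **middle = neuromelanin (LC)**,
   highest = CSF/fluid.
3. **Anatomically constrained extraction** — neuromelanin-class voxels are
   kept only within a millimetre-exact dilation (default 4 mm, computed with
   an anisotropic Euclidean distance transform) of a fourth-ventricle mask;
   connected components smaller than 5 voxels are discarded, and the result
   is split into left and right LC at the ventricle's sagittal plane.
4. **Measurement** — LC volume (voxel count × voxel volume), volume
   normalized by brainstem (and optionally whole-brain) volume, rostrocaudal
   length, mean enhancement inside/outside the LC, enhancement contrast
   (Welch t), and line profiles through the segmentation.
5. **Cohort statistics** — group comparisons (pooled or Welch t with
   Cohen's d), 2×2 chi-square, partial Spearman correlations between
   normalized LC volume and affect questionnaires (MASQ, ATQ) controlling for
   age or sex, with Benjamini–Hochberg FDR correction across the six scales.
6. **Phantoms and simulation** — a synthetic brainstem phantom with known LC
   geometry (bilateral 2 × 2 × 14.5 mm tubes, 116 mm³ total) for validating
   the segmentation chain, and a rank-correlation-calibrated cohort simulator
   for validating the statistics.

## Core model

With enhancement values `x_i`, the mixture density is

    p(x) = Σ_k  w_k · N(x; μ_k, σ_k²),   k = 1..3

fitted by EM with a log-sum-exp E-step, a relative log-likelihood
convergence tolerance of 1e-6, and a variance floor of 1e-10 × Var(x).
Initialization uses deterministic smoothed-histogram modes by default (see
`docs/methods.md` for why, and for a percentile-based alternative). Voxels
are classified by maximum posterior; the component with the **median** mean
is the neuromelanin class.

## Worked example

Build the default phantom and run the full pipeline:

```python
from lcmap import PhantomSpec, build_phantom
from lcmap.pipeline import segment_subject

bundle = build_phantom(PhantomSpec(), seed=7)
result = segment_subject(bundle.mt, bundle.nomt,
                         bundle.truth_ventricle, bundle.truth_brainstem)

print("GMM means:", [round(x, 4) for x in sorted(result.model.means_)])
print(result.measurement.to_row("phantom07"))
```

Output:

```
GMM means: [0.6001, 0.8004, 1.0001]
{'subject_id': 'phantom07',
 'lc_vol_mm3': 111.36000000000003,
 'lc_vol_left_mm3': 55.680000000000014,
 'lc_vol_right_mm3': 55.680000000000014,
 'lc_norm_brainstem': 0.006088599622086921,
 'lc_norm_wholebrain': None,
 'lc_length_mm': 14.5,
 'enh_lc_mean': 0.8005284525092847,
 'enh_nonlc_mean': 0.6005508512225002}
```

The fitted class means recover the generating values (1.00 fluid, 0.80
neuromelanin, 0.60 white matter). Against the analytic ground-truth volume of
116 mm³ the recovered 111.36 mm³ is a −4.0 % error (Dice overlap 0.980), the
rostrocaudal length matches the generating 14.5 mm tubes exactly, and the
off-midline distractor blob is excluded by the ventricle-distance constraint.

The same pipeline is available from the command line:

```
lcmap simulate-phantom --out-dir phantom --seed 7
lcmap segment --mt phantom/mt.nii.gz --nomt phantom/nomt.nii.gz \
      --ventricle phantom/ventricle.nii.gz --brainstem phantom/brainstem.nii.gz \
      --out-dir seg
lcmap simulate-cohort --out-dir cohort --seed 4
lcmap cohort-stats --cohort cohort/cohort.csv --out-dir stats
lcmap verify-table1
```

`segment` writes the enhancement map, label map, LC mask, mixture parameters,
a one-row `measurements.csv`, and a `provenance.json` with SHA-256 input
hashes and the full configuration. `cohort-stats` writes a JSON/text report
with the group test and FDR-corrected partial correlations. `verify-table1`
recomputes a set of reference demographic-table statistics from their
published counts and summary moments (e.g. the male/female comparison gives
p = 0.095).

## Layout

- `src/lcmap/volumes.py` — NIfTI I/O, grid compatibility checks, masks
- `src/lcmap/enhancement.py` — MT/non-MT ratio maps
- `src/lcmap/gmm.py` — `ScalarGMM` estimator (scikit-learn API), role assignment
- `src/lcmap/lc_extract.py` — mm dilation, extraction, measurement, profiles
- `src/lcmap/cohort_stats.py` — t/chi-square/partial-Spearman/FDR, cohort report
- `src/lcmap/phantom.py` — phantom builder and cohort simulator
- `src/lcmap/pipeline.py` — single-subject segmentation pipeline
- `src/lcmap/demographics.py`, `cli.py` — reference table checks, CLI
- `docs/methods.md` — modelling and numerical choices in detail
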