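# Methods

This note documents the model, the default parameters, and the numerical
choices behind `lcmap`, together with the scope and limitations of its
synthetic validation data. It makes no empirical claims beyond what the
test suite and `scripts/acceptance.py` compute.

## Enhancement mapping

Fractional MT enhancement is the voxelwise ratio `E = S_MT / S_noMT`.
Voxels are valid where both inputs are finite and the non-MT signal exceeds
a denominator floor, by default 5 % of the 99th percentile of the non-MT
volume; this excludes background and near-zero-signal voxels where the
ratio is numerically meaningless. Off-mask voxels are NaN. Inputs must share
the grid exactly (same shape; affines equal elementwise to 1e-4).

## Three-class mixture

Valid enhancement values are modelled as a univariate K = 3 Gaussian
mixture fitted by EM (`ScalarGMM`, scikit-learn estimator API):

- E-step in log space with log-sum-exp for numerical stability.
- Variance floor of `1e-10 · Var(x)` to prevent component collapse.
- Convergence when the relative log-likelihood change is below 1e-6;
  `max_iter = 500`. The log-likelihood trace is retained and is
  non-decreasing up to floating-point slack.
- At least 10 000 values are required; zero-variance input is rejected.

**Initialization.** The default is deterministic smoothed-histogram modes:
a 512-bin histogram over the 0.1–99.9 percentile range is smoothed with a
Gaussian kernel (σ = 3 bins), and the top three interior local maxima at
least 16 bins apart seed the means (falling back to percentiles if fewer
modes exist). A 10/50/90-percentile initialization is available
(`init="percentile"`) but is a poor default here: the neuromelanin class
occupies well under 1 % of brainstem voxels, so all low percentiles fall in
the dominant white-matter mode and EM converges to a split of that mode
instead of the three tissue classes. On the default phantom the mode
initialization recovers means (0.600, 0.800, 1.000) and Dice 0.98, whereas
the percentile initialization yields (0.591, 0.603, 0.933) and Dice 0.0.

**Role assignment.** Components are sorted by mean: lowest = white matter,
middle = neuromelanin, highest = fluid. The middle class is the LC class
because neuromelanin enhancement sits between white matter and CSF on these
ratio maps. Classification is maximum posterior (argmax of the log joint),
ties resolved to the lowest component index; label 0 marks invalid voxels.

## Anatomically constrained extraction

- **Dilation in millimetres.** The ventricle mask is dilated by a Euclidean
  distance transform with anisotropic `sampling = voxel_size`, keeping
  voxels with distance ≤ radius + 1e-9 (the epsilon absorbs floating-point
  boundary error; the tests check exact agreement with an integer-lattice
  enumeration oracle). Default radius 4 mm.
- Neuromelanin-class voxels inside the dilated region are grouped by
  26-connectivity (6/18 available); components below 5 voxels are dropped.
  An empty result warns rather than raises.
- Left/right split at the sagittal plane through the ventricle centroid in
  world coordinates (RAS+).
- Volume is voxel count × voxel volume; normalized volume divides by
  brainstem (and optionally whole-brain) volume. Rostrocaudal length is the
  world-z extent of the mask plus one slice thickness (a mask confined to a
  single slice still has one slice of physical extent).
- Enhancement contrast between two disjoint masks uses Welch's t.

## Statistics

All p-value producers are cross-checked in the tests against SciPy and
against hand-coded textbook formulas to 1e-10.

- **Two-sample t**: pooled (df = n₁+n₂−2) or Welch–Satterthwaite. Cohen's d
  always uses the pooled SD. Zero pooled variance with equal means returns
  t = 0, p = 1, d = 0. Summary-statistic and binary-count variants exist;
  the binary variant expands counts to 0/1 indicators and applies the
  pooled t, which is how categorical rows of demographic tables are often
  tested in practice.
- **Chi-square** on 2×2 tables: Pearson, no continuity correction; a zero
  margin is rejected as degenerate.
- **Partial Spearman**: complete-case observations are ranked (average
  ties), both variables are residualized on the covariate ranks (least
  squares with intercept), and Pearson correlation of the residuals is
  tested with the t approximation on df = n − 2 − k.
- **FDR**: Benjamini–Hochberg step-up, hand-coded as
  `min over j ≥ rank(i) of p_(j)·m/j`, clipped at 1, via a reversed
  cumulative minimum. The `p·m/j` form matches the brute-force definition
  bit-for-bit (tests assert exact equality against an O(m²) oracle and
  agreement with statsmodels to 1e-12). Note `p·m/m` can round one ulp
  below `p`.
- **Cohort report**: Welch t for patient-vs-control normalized LC volume,
  then six partial Spearman correlations (MASQ ×3, ATQ ×3) per covariate
  set (age; sex), FDR-corrected within each set of six.

## Synthetic phantom

Grid 96 × 96 × 64 at 0.4 × 0.4 × 0.5 mm, affine centred on the origin so
the field of view is symmetric. Structures, all defined in millimetres and
voxelized half-open so volumes are lattice-exact:

- Brainstem: ellipsoid with semi-axes (16, 18.5, 15) mm.
- Fourth ventricle: cylinder, radius 2 mm, length 24 mm, on the z-axis.
- LC: bilateral 2 × 2 mm tubes of length 14.5 mm, centred 3 mm lateral to
  the ventricle wall; exactly 725 voxels per side, 116.0 mm³ total.
- Distractor: a neuromelanin-intensity sphere (radius 2 mm) 13 mm from the
  ventricle wall, emulating other pigmented nuclei that the
  ventricle-distance constraint must exclude.

Class mean ratios are 1.00 (fluid), 0.80 (neuromelanin), 0.60 (white
matter) — ordered so that the neuromelanin class is the middle component,
consistent with the role-assignment rule. Gaussian noise (SD 1.25 on a
non-MT level of 100, i.e. ≈0.02 SD on the ratio) separates the classes by
roughly 10 σ; a Rician noise model is available. Everything is driven by a
single integer seed.

**What the phantom does not emulate:** partial-volume fractions, bias
fields, spatially varying noise, motion, anatomy-shaped (curved, tapering)
LC, or inter-subject geometric variability. It validates the numerical
chain — ratio → mixture → constraint → measurement — not biological
realism. Recovery numbers on it (e.g. −4 % volume, Dice 0.98) reflect pure
voxelization/classification error, a lower bound on real-data error.

## Cohort simulator

Subjects carry a latent standard-normal LC score with a group shift of
`true_d` (default 1.08) for patients. Questionnaire scales are coupled to
the standardized score through a Gaussian copula: target Spearman ρₛ is
converted to Pearson r = 2·sin(πρₛ/6), scales are conditionally independent
given the latent score (which keeps any target vector positive-definite),
and marginals are affine (hence rank-preserving). Defaults: n = 12 controls
+ 15 patients, ages uniform 24–57, normalized LC volume mean 0.005 (SD
0.002). The simulator is calibrated, not fitted: tests verify that sample
Spearman correlations recover the set-points within 0.1 at n = 200, that
the mean recovered Cohen's d over 500 cohorts is within ±0.15 of the true
value, and that the FDR-corrected family false-positive rate over 1000 null
cohorts stays at the nominal level.

## Limitations

- The mixture is univariate and spatially blind; no Markov-random-field or
  atlas prior. Real data with strong bias fields should be corrected first.
- The middle-mean rule assumes exactly three classes with neuromelanin
  between white matter and fluid; acquisitions where this ordering fails
  need a different role map.
- The dilation constraint requires a ventricle mask; its quality bounds the
  extraction.
- The partial Spearman p-value uses the t approximation, adequate at the
  cohort sizes here but approximate for very small n with many ties.
- Binary-count group comparisons via the pooled indicator t are reported
  for comparability with common practice; the chi-square variant is also
  provided and preferred for pure independence testing.
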