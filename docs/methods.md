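# Methods

## Model and procedure

The pipeline analyses longitudinal scalar brain maps (CBF, FA, MD) from a
concussed cohort against a once-imaged control cohort.  Its chain is:
normative difference scoring → condition-summary construction → uncentered
task PLS → repeated-measures bootstrap with low-rank imputation →
voxel + cluster-extent thresholding → ROI effect statistics, plus an
independent clinical nonparametric battery.

### Normative scoring

Controls are matched to each athlete on sex, history of concussion (HOC)
and age within an inclusive ±2-year caliper (ages may be fractional; the
caliper is applied to the raw difference).  The voxelwise subgroup
reference is the Huber location M-estimate with tuning k = 1.35: the
minimizer of Σρ_k((x−μ)/σ̂) with σ̂ = 1.4826·MAD held fixed — the standard
auxiliary-scale companion, consistent at the normal.  It is solved by
IRLS from a median start; the objective is convex in μ, so the iteration
converges globally.  Columns with zero MAD fall back to the median.  One
reference map per athlete is computed and reused across that athlete's
sessions, keeping the longitudinal baseline fixed.  QC-excluded scans
are removed before matching.

### Summary matrices and uncentered PLS

Per modality, two 3 (sessions) × V (voxels) matrices are built from the
athletes' Δ maps: session means (MEAN), and session-wise point-biserial
correlations of Δ with sex (SEXCORR; zero-variance voxels get r = 0 and
are counted).  Missing sessions are simply omitted cell-wise.  Each
matrix is decomposed by an SVD with *no* row or column centering — the
task-PLS convention for condition summaries; grand-mean removal is
deliberately not applied, so a shared offset across sessions loads on
component 1.  MEAN and SEXCORR are two separate decompositions (not one
stacked six-row problem) because their covariance shares are reported
separately.  Components are sign-fixed by making the largest-magnitude
session-salience element positive.  Only component 1 is reported;
components 2–3 are computed and available on the estimator.

### Bootstrap inference

The resampling unit is an athlete with their full ACU/RTP/1YR triplet
(sessions are never mixed across athletes).  Each of the n_boot = 1,000
default replicates resamples athletes with replacement, completes the
resampled athlete × (session·voxel) matrix with SOFT-IMPUTE at the fixed
CV-chosen λ (fresh completion per replicate), rebuilds the summary,
refits the PLS, and sign-aligns the candidate to the reference component
by the sign of the voxel-salience inner product (zero → +1).  Replicates
with a single distinct athlete — or, for SEXCORR, fewer than two
athletes of either sex — are redrawn and counted.

The accumulated bootstrap statistic is the *data-scale* first-component
pattern s₁·v₁ (voxel side) and s₁·u₁ (session side), not the unit-norm
salience: the unit constraint couples all voxels and makes the ratio
scale-degenerate, whereas the covariance-scale pattern behaves like a
z-score wherever the component is stable.  BSR = bootstrap mean /
bootstrap SE (ddof = 1), p = 2(1−Φ(|BSR|)).  A statistic with zero
bootstrap SE is reported as signed infinity with p = 0 and counted in
`n_degenerate`.  The % covariance gets a 2.5/97.5 percentile interval.

Within bootstrap replicates the SOFT-IMPUTE sweeps are warm-started from
the full-data completion and capped (default 100 sweeps; the calibration
experiments showed the cap does not change BSR exceedance rates, it only
saves time).  A resample can leave an entire session block unobserved
for every drawn athlete; such columns carry no information in that
replicate and are filled from the full-data completion.

### SOFT-IMPUTE

Z ← SVT_λ(P_obs(X) + P_miss(Z)) until the relative Frobenius change
falls below 1e-5 (default), where SVT soft-thresholds singular values by
λ.  The objective ½‖P_obs(X−Z)‖² + λ‖Z‖⁎ is tracked every sweep and
asserted non-increasing.  Observed entries always pass through
unchanged.  The SVD is routed through the n×n Gram matrix when the
matrix is wide (p ≥ 4n), which is exact and an order of magnitude
faster for athlete-by-voxel matrices.

λ is chosen by repeated random holdout: 200 repeats (default), each
hiding 5% of observed entries (redrawn if a row or column would lose its
last observation), scoring squared error on the hidden entries over a
λ grid (default 15 log-spaced values from s_max down two decades,
imputed largest-first with warm starts).

Two different matrices are completed in the pipeline.  The PLS bootstrap
completes the athletes × (session-concatenated voxels) matrix, where
voxel-level values are needed to rebuild saliences.  The ROI statistics
first average Δ over the cluster voxels and then complete the small
athletes × sessions matrix of ROI values, with λ cross-validated on that
matrix itself: there, a held-out entry *is* a missing-session cell, so
the selection is matched to the actual prediction task.  On the
concatenated matrix, by contrast, entrywise holdout rewards
interpolation from spatial neighbours and selects very small λ; the
resulting minimum-nuclear-norm-style completion recovers only a
fraction of a session-level effect in wholly missing blocks (a caveat
listed under limitations, and the reason ROI statistics do not reuse
the voxel-level completion).

### Cluster-extent correction

Smoothness is estimated from athlete-level residual maps (Δ minus the
session mean) by the classical first-neighbour variance-ratio estimator
FWHM = Δx·√(−2 ln 2 / ln(1 − s²_diff/(2 s²))) per axis, averaged over
maps, summarized by the geometric mean.  Fields at least as rough as
white noise give FWHM 0 with a warning.  The minimum cluster extent is
the (⌈(1−α)·n_sim⌉-th order statistic + 1) of the largest suprathreshold
cluster over n_sim = 2,000 (default) simulated smooth unit-variance
Gaussian null fields, thresholded two-sided at |z| > Φ⁻¹(1−p/2) with
p = .005.  Cluster extraction uses the same two-sided rule with
faces-only (6-neighbour) connectivity by default — the NN level and
sidedness are configurable since practice varies — and reports
|BSR|-weighted centers of mass in template mm, extents in mm³, and peak
signed BSR, sorted by size.

### ROI statistics and clinical battery

ROI statistics average Δ over a significant-cluster mask: per group
(all, male, female) and session, with bootstrapped CIs, BSR and p from
an athlete-level bootstrap (imputing the athletes × sessions ROI matrix
within each replicate), and BH-FDR flags across the three sessions of
each group block.  CIs are recentred percentile intervals: the
percentile spread of the bootstrap distribution anchored at the
omission-based point estimate.  The recentring matters because the
soft-thresholded completion shrinks imputed cells toward zero, shifting
the whole replicate distribution below the (unbiased) point estimate;
anchoring removes that systematic offset while keeping the resampling
spread.  The sex
contrast is the female−male difference pooled over the sex-analysis'
FDR-significant sessions (all three when none reach significance, so the
quantity is always defined).  Symptom scoring uses the 22 SCAT items
partitioned 9 somatic / 6 cognitive / 3 sleep / 4 mood; Wilcoxon tests
report the tie-corrected normal z, with p-values from the exact null
distribution for small untied samples (≤25) and the normal approximation
otherwise; elevation tests versus baseline are one-sided by default.
FDR control is Benjamini–Hochberg throughout.  The attrition screen
correlates session retention with demographics by Spearman rho under one
BH pass; constant covariates are reported as missing.

## Synthetic cohorts

The generator emulates the study conditions: 167 controls, 61 concussed,
session retention 53/51/32 of 61 (MCAR Bernoulli dropout — the study
found attrition unrelated to demographics), sex ~ Bernoulli(0.5), HOC ~
Bernoulli(0.5), integer ages from a truncated normal (mean 20.3, SD 2.0)
on 17–28 for controls and 18–24 for concussed athletes — the narrower
concussed range keeps every athlete's matched subgroup viable under the
±2-year caliper and reproduces the study's matched-subgroup median
(~29 of 167 controls; the generator yields ≈28–29).

Maps live on a 24×28×24 grid of 3-mm voxels with an ellipsoidal analysis
mask of ≈1,900 voxels — a miniature of a template-space mask chosen so
study-scale cohorts run in seconds.  Each map is baseline + sex/age/HOC
offsets + a subject-level random intercept + planted effects + smooth
Gaussian noise (FWHM 6 mm, matching the preprocessing smoothing scale;
fields are variance-renormalized after smoothing so `noise_sd` is the
marginal SD).  Per-modality baselines (CBF 55 ± 5 ml/100 g/min; FA
0.45 ± 0.025, clipped to [0,1]; MD 0.80 ± 0.02 on the 10⁻³ mm²/s scale)
and demographic offsets are plausible field values; the per-voxel noise
SD is a free parameter since the study reports none.  Subject random
intercepts are deliberately kept below the voxel noise SD
(CBF 4 ml/100 g/min): a large shared intercept acts as a global common
mode that the uncentered first component locks onto, and real analyses
mitigate this with the matched-control referencing the generator
emulates.  Effects are spheres with per-session amplitudes in noise-SD
units: the main effect is added to all concussed maps, the sex effect as
±amplitude/2 for female/male athletes, so the amplitude *is* the planted
female−male contrast.  Symptom tables are low-rate baseline items with
elevated ACU ratings.

What the generator does *not* emulate: biophysical forward models,
scanner artifacts, spatially varying noise, registration error, and —
importantly — inter-subject global variability as large as real
perfusion data show.  Passing calibration tests therefore demonstrates
the statistical machinery is sound under its stated noise model, not
that real-data BSR maps are exactly standard normal.

## Numerical choices

- float32 on disk (NIfTI), float64 in memory.
- Huber IRLS: tol 1e-8 on the location update, max 100 iterations.
- SOFT-IMPUTE: tol 1e-5 (1e-4 inside CV), max 500 sweeps (capped at 100
  warm-started sweeps inside bootstrap replicates).
- Cluster simulation uses periodic-boundary Gaussian smoothing with
  exact variance renormalization, making the null fields stationary.
- All stochastic stages draw child seeds (< 2³¹) deterministically from
  the master seed; reruns are byte-identical.
- Test problem sizes: calibration suites use 20–50 simulated cohorts,
  reduced grids (≈800–2,000 mask voxels), 100–300 bootstrap replicates
  and 400 cluster-null fields — sizes chosen so the whole suite runs on
  one CPU while keeping the statistical bounds meaningful.

## Known limitations

- The control-subgroup reference error (the estimation error of each
  matched subgroup's robust mean) is a smooth map shared across
  athletes, and the repeated-measures bootstrap — whose resampling units
  are athletes, as in the original design — never resamples controls.
  Consequences measured by the calibration suite: voxel-level null BSR
  exceedance stays near nominal when pooled, but the familywise rate of
  spurious *clusters* on null cohorts runs above the nominal 5%
  (≈ 0.15 at study-scale settings), and ROI-contrast CIs are narrower
  than the true cross-cohort variability, with coverage ≈ 0.73 rather
  than 0.95.  These are properties of the procedure itself; widening
  inference to control-resampling would change the method.
- Deterministic SOFT-IMPUTE completion understates imputation
  uncertainty relative to proper multiple imputation; at the study's
  ~47% 1YR attrition this contributes anticonservative null cohorts and
  narrow ROI intervals.
- Entrywise holdout CV on the concatenated voxel matrix chooses
  interpolation-scale λ and recovers only part of a session-level effect
  in wholly missing blocks (see above); the ROI path avoids this, the
  voxel-level PLS bootstrap retains it.
- Salience BSRs are only approximately standard normal: under a pure
  global null the first component is unstable and BSRs are strongly
  conservative; in the presence of any stable common mode they can be
  anticonservative.  The cluster-extent stage assumes N(0,1) voxel
  statistics and inherits these deviations.
- The multivariate QC screen (PCA to 90% control variance +
  median/MAD-standardized robust distances against a Bonferroni-adjusted
  chi-square tail) is this package's own specification of a standard
  voxel-map screen; the flag method is configurable.
- Manual mask edits (ventricle/brain-stem exclusions) are represented
  only as an optional user-supplied exclusion mask; no registration or
  segmentation is performed.
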