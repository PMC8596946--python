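# deltapls

Normative difference-map scoring and uncentered task-PLS bootstrap
inference for longitudinal brain parameter maps, with SOFT-IMPUTE
missing-session completion, Monte-Carlo cluster-extent correction, and a
nonparametric clinical test battery — the statistical core of a
sport-concussion neuroimaging study, reimplemented as a tested, reusable
pipeline that runs end to end on synthetic cohorts with known ground
truth.

## The problem

Concussed athletes are imaged at acute injury (ACU), medical clearance to
return to play (RTP), and one year post-RTP (1YR); a large control cohort
is imaged once.  Raw parameter maps — cerebral blood flow (CBF, ml/100
g/min), fractional anisotropy (FA) and mean diffusivity (MD) — mix
injury effects with baseline demographic differences.  The pipeline
therefore:

1. **Normative scoring.**  For each athlete *s*, finds all controls
   matching on sex, history of concussion, and age (±2 years), computes
   the voxelwise robust control mean *m_s* with a Huber location
   M-estimator (k = 1.35, scale fixed at 1.4826·MAD), and forms
   difference maps Δx_s = x_s − m_s.  The same subgroup is reused for all
   of the athlete's sessions.
2. **Task PLS.**  Builds two 3×V condition summaries per modality — the
   per-session mean Δ maps (main effect) and the per-session correlations
   of Δ with sex (sex effect) — and decomposes each by an *uncentered*
   SVD.  The first component's voxel and session saliences and its share
   of squared singular value (% covariance) are reported.
3. **Repeated-measures bootstrap.**  Athletes (with their full session
   triplets) are resampled 1,000 times; missing sessions are completed by
   SOFT-IMPUTE at a soft threshold λ chosen by repeated random-holdout
   cross-validation (200 repeats, 5% holdout).  Bootstrap ratios
   (BSR = bootstrap mean / SE) are referred to the standard normal.
4. **Cluster-extent correction.**  Map smoothness (FWHM) is estimated
   from residual maps; smooth Gaussian null fields are simulated to find
   the minimum cluster size controlling familywise error at α = .05 after
   voxelwise thresholding at p = .005.
5. **ROI and clinical statistics.**  Cluster-averaged Δ with bootstrapped
   95% CIs per session and group (all/male/female), a female−male
   contrast, BH-FDR control, SCAT symptom scoring (22 items, four
   domains), Wilcoxon tests (exact for small untied samples), and a
   Spearman attrition screen.

A first-class synthetic-data module generates cohorts (167 controls, 61
concussed with the study's session attrition of 53/51/32) with planted
session-varying main and sex×session effects, so every stage is testable
against known truth.

## Worked example

```python
from deltapls import (PipelineConfig, SimulationConfig, default_effects,
                      run_pipeline)
from deltapls.normative import MatchCriteria

sim = default_effects(SimulationConfig(n_control=80, n_concussed=30,
                                       modalities=("CBF",), seed=1))
cfg = PipelineConfig(simulation=sim, n_boot=100, n_sim=300, cv_repeats=10,
                     criteria=MatchCriteria(max_age_gap=10), seed=1)
res = run_pipeline(cfg)
mod = res["modalities"]["CBF"]
for analysis, entry in mod["analyses"].items():
    b = entry["bootstrap"]
    print(analysis, round(b.pct_cov_point, 1),
          entry["clusters"].n_clusters)
print(mod["analyses"]["SEXCORR"]["roi"].contrast)
```

prints (seed 1):

```
MEAN 77.2 1
SEXCORR 62.7 5
{'mean': 4.51, 'ci_low': 3.64, 'ci_high': 5.5, 'bsr': 8.04, 'p': 0.0, ...}
```

The main-effect component explains 77.2% of the summary-matrix
covariance and yields one significant cluster at the planted injury
region; the sex-effect component (62.7%) finds clusters at the planted
sex×session region, and the ROI female−male contrast over the
FDR-significant sessions is 4.51 ml/100 g/min with 95% CI [3.64, 5.50],
against planted per-session contrasts of 2.5/4.0/2.5 ml/100 g/min
(0.5/0.8/0.5 × the 5 ml/100 g/min noise SD) peaking at RTP.

The same pipeline is scriptable from the shell:

```bash
deltapls run-all --seed 1 --out results/demo
deltapls simulate --seed 1 --out data/cohort
```

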