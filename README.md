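# neurocovar

Group-level metabolic covariance and multimodal volumetrics for
dissecting dementia variants.

Behavioral-variant Alzheimer's disease (bvAD) presents with prominent
behavioral change yet, on structural MRI, with the temporoparietal
atrophy of typical amnestic AD (tAD) rather than the frontal atrophy of
behavioral-variant frontotemporal dementia (bvFTD). Resolving that
clinico-anatomical dissociation takes markers beyond atrophy: FDG-PET
hypometabolism, metabolic network connectivity, subcortical volumes and
white-matter-hyperintensity (WMH) burden. `neurocovar` packages that
analysis as a tested, reusable pipeline for researchers comparing
diagnostic groups on co-registered brain volumes and derived tables:

- **SUVr preparation** — reference-region (pons) normalization,
  12-mm Gaussian smoothing, gray-matter-masked ROI extraction.
- **Voxelwise contrasts** — mass-univariate OLS with covariates
  (age, sex, and field strength + intracranial volume for gray-matter
  maps), t-maps per pairwise group contrast, max-statistic permutation
  FWE (Freedman–Lane) or uncorrected thresholds, cluster extent k,
  bit-coded overlay maps.
- **Metabolic connectivity** — seed-based interregional covariance
  (IRCA): across subjects of a group,
  `voxel ~ 1 + seed + age + sex` at every gray-matter voxel, with 4-mm
  seed spheres at PCC (−8,−56,26), amPFC (6,52,−2), right frontoinsula
  (36,18,4) and right DLPFC (44,36,20); goodness of fit against network
  templates, GOF = T̄_inside − T̄_outside; and a two-group per-group-slope
  interaction test of connectivity differences.
- **Features & discrimination** — within/outside-network SUVr and
  gray-matter ratios, signature-ROI means, amygdala volume, lobar WMH
  burdens; pairwise ROC with Mann–Whitney AUC, DeLong 95% CI and
  p-values, and top-k discriminator ranking.
- **Volumetric statistics** — subcortical-volume GLM with explicit
  Bonferroni family, control-normalized WMH volumes, and gamma GLM
  (log link) group contrasts.
- **Synthetic cohorts** — a download-free generator producing the exact
  statistical structure the stages assume (group hypometabolism
  patterns, rank-1 latent network covariance, covariate effects,
  gamma-distributed WMH), used by the tests and the reproduction
  script.

See `docs/methods.md` for models, assumptions, defaults and limitations.

## Worked example

Run the full pipeline on a synthetic cohort (119 subjects on a 4-mm
MNI-like grid, ~14 s on one CPU):

```python
from neurocovar.pipeline import RunConfig, run_pipeline

run_pipeline(RunConfig(output_dir="run", rng_seed=42, n_perm=200))
```

or equivalently `neurocovar run-all --out run --seed 42`. The GOF table
(`run/gof_profile.csv`, pivoted) reads:

```
network    ECN     SN   aDMN   pDMN
group
CN       23.72  41.39  43.10  44.70
bvAD     21.70  26.74  34.31  42.14
bvFTD    22.62  38.89  44.96  37.24
tAD      25.44  17.82  30.84  53.25
```

Each entry is the mean covariance-map t inside a network template minus
the mean outside it, for that group's seed map — larger means the
group's metabolic covariance pattern matches the network better. On this
cohort the anterior-DMN GOF is higher in bvAD (34.3) than tAD (30.8),
with bvFTD highest (45.0), while tAD leads in the posterior DMN (53.3) —
the anterior/posterior dissociation the generator plants. (Magnitudes
are larger than in typical cohort studies because the synthetic noise
model is clean; only comparisons across groups are meaningful.)

Top discriminators for bvAD vs tAD (`run/roc_bvAD_vs_tAD.csv`):

```
          feature   auc  ci_low  ci_high direction  p_value
     amygdala_cm3 0.855   0.760    0.949  bvAD>tAD    0.000
     fdg_SN_ratio 0.217   0.099    0.335  bvAD<tAD    0.000
fdg_FTD_signature 0.275   0.142    0.407  bvAD<tAD    0.001
   fdg_aDMN_ratio 0.358   0.214    0.503  bvAD<tAD    0.055
    wmh_occipital 0.388   0.239    0.537  bvAD<tAD    0.139
```

AUC is fixed to the "bvAD scores higher" orientation (values below 0.5
mean tAD scores higher; ranking uses max(AUC, 1−AUC)). Amygdala volume
discriminates best (AUC 0.86, bvAD larger), with salience-network and
frontoinsular FDG measures next — bvAD metabolism is subtly lower there.

Voxelwise CN > bvAD clusters at permutation-FWE p < 0.05, k = 50
(`run/clusters_CN_gt_bvAD.csv`):

```
 cluster_id  n_voxels  peak_t  x_mm  y_mm  z_mm
          1      1469    9.14 -42.0 -54.0   6.0
          2       285    4.63 -34.0  30.0   6.0
```

a large temporoparietal cluster and a smaller frontoinsular one — the
planted bvAD hypometabolism pattern.

## Command line

`neurocovar simulate | suvr | discriminate | volumetrics | run-all`;
each subcommand is a thin wrapper over the library (`--help` for
options). `run-all` accepts a YAML file of `RunConfig` fields and writes
a JSON run report with per-stage status, elapsed time and an inputs
hash.

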