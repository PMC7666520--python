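# Methods

`neurocovar` implements a group-level multimodal neuroimaging analysis for
dissecting dementia variants — behavioral-variant Alzheimer's disease
(bvAD), typical amnestic AD (tAD), behavioral-variant frontotemporal
dementia (bvFTD), and cognitively normal controls (CN) — from FDG-PET and
structural-MRI derivatives. This note describes each model, its
assumptions, the tunable parameters, the synthetic data the package is
calibrated on, and the numerical choices made where the design was open.

## Spatial data model

Volumes live on a `VolumeGrid`: a voxel lattice with a 4×4 affine mapping
indices to world millimetres (RAS; the MNI convention). Two grids compare
equal when shapes match and affines agree within 1e-6 mm. Every analysis
requires its inputs to share a grid exactly; `resample_to_grid` exists but
is never applied implicitly, so misregistration cannot pass silently.

Numerical choices:

- **Sphere seeds** (default radius 4 mm) include a voxel iff its *center*
  lies within the radius — the behaviour of common sphere-ROI toolkits;
  no partial-volume weighting.
- **Template binarization** uses a strict `value > threshold` cut
  (default r = 0.2 for correlation-style network maps), making the
  boundary reproducible.
- **Gaussian smoothing** (default FWHM 12 mm for SUVr maps) uses
  σ = FWHM/√(8 ln 2) per axis in voxel units and a symmetric *reflect*
  boundary, which preserves the volume mean to machine precision.

## SUVr normalization

FDG uptake is divided by the mean uptake in a reference-region mask (the
pons, relatively metabolically preserved in AD), so the reference mean of
the output is exactly 1 and any per-subject global scanner scale cancels.
Seed and ROI means are taken over the ROI ∩ gray-matter mask; a single
cohort-level GM mask is used (per-subject GM masks are out of scope).
Intracranial volume is the plain sum of GM, WM and CSF volumes.

## Voxelwise group contrasts

`MassUnivariateOLS` fits the same ordinary-least-squares design
independently at every in-mask voxel of a (subjects × voxels) matrix.
The design uses cell-means group coding plus mean-centered covariates
(age, sex for PET; plus scanner field strength and ICV for gray-matter
analyses), so pairwise group contrasts are ±1 vectors and t statistics
are unaffected by the centering. Contrast t-maps carry df = n − rank(X).

Thresholding:

- *Uncorrected*: voxel p from Student-t(df), default α = 0.001 for
  patient-vs-patient contrasts. Patient-vs-control contrasts are
  one-sided in the hypometabolism/atrophy direction; patient-vs-patient
  contrasts are run two-sided (or in both directions).
- *Family-wise error*: max-statistic permutation with Freedman–Lane
  shuffling — the nuisance columns (zero contrast weight) are fitted,
  their residuals row-permuted and the nuisance fit added back before
  the full-model contrast is recomputed; the per-permutation maximum
  over voxels forms the null. The observed statistic must exceed the
  (1−α) null quantile. At least ⌈1/α⌉ permutations are required
  (default 500 at α = 0.05). Permutation FWE was chosen over
  random-field theory because it is exactly specifiable and
  distribution-free; thresholds can differ slightly from parametric FWE.
- *Extent filter*: connected components (18-neighbourhood, faces+edges)
  smaller than k voxels (default 50) are removed afterwards.

Overlay maps code each input significance mask as one bit, so a voxel's
integer value identifies exactly which contrasts include it.

## Metabolic covariance (IRCA) and goodness-of-fit

Across the subjects of one group, the mean SUVr in a 4-mm seed sphere
(∩ GM mask) is regressed against SUVr at every GM voxel, adjusting for
age and sex: `voxel ~ 1 + seed + age + sex`. The stored map is the
seed-slope t per voxel; one map per (group, seed). Canonical seeds:
PCC (−8, −56, 26) for the posterior DMN, amPFC (6, 52, −2) for the
anterior DMN, right frontoinsula (36, 18, 4) for the salience network,
right DLPFC (44, 36, 20) for the executive control network. (One source
labels the amPFC seed "left" while printing x = +6; the coordinate is
used as printed.)

Goodness of fit against a network template is
GOF = mean t inside the template − mean t outside it, both restricted to
the analysis mask. GOF is computed on the *unthresholded* t-map (a
thresholded variant is available for display-style sensitivity checks);
"outside" means analysis mask minus template, since counting out-of-brain
zeros would dilute the outside mean arbitrarily. GOF is exactly invariant
to adding a constant to the map and linear in the map. No inferential
statistics are attached to GOF: it is a group-level descriptive score.

The interaction analysis pools two groups and fits per-voxel
`voxel ~ 1[g=A] + 1[g=B] + seed·1[g=A] + seed·1[g=B] + age + sex`
(covariate effects shared across groups — the model with per-group
covariate slopes is not identifiable at these sample sizes), testing
slope_A = slope_B with a Wald t. Relabeling the groups negates the map
exactly. Results are reported at p < 0.001 and p < 0.05 uncorrected
without an extent threshold.

## Subject-level features and ROC discrimination

- *Network ratio*: mean signal inside a template ∩ mask divided by the
  mean over mask \ template; scale-invariant and > 1 iff the inside mean
  exceeds the outside mean. Applied identically to SUVr and gray-matter
  maps.
- *Signature-ROI means*: plain ROI averages over AD-signature
  (temporoparietal, parietal) and FTD-signature masks, supplied as
  inputs.
- *Amygdala volume*: left+right sum (no laterality difference is
  modelled).
- *Lobar WMH burden*: sum over sides and the four concentric layers per
  lobe, with an optional per-layer weight vector (default uniform — the
  appropriate weighting is not established, so none is imposed).

AUC uses the Mann–Whitney formulation with midrank ties: the probability
that a random subject of the positive group scores above a random
negative (ties count ½). The 95% CI and the two-sided p-value against
AUC = 0.5 come from the DeLong structural-components variance estimator
(deterministic; a seeded bootstrap would be the alternative). AUC is
reported in the fixed pos>neg orientation and may fall below 0.5; ranking
uses the orientation-free score max(AUC, 1−AUC), ties broken by feature
name. No multiplicity correction is applied across features. A constant
pooled sample degenerates to AUC 0.5 with a warning.

## Volumetric statistics

Subcortical volumes (7 bilateral structures, cm³) are compared with OLS
per structure on group indicators plus age, sex, field strength and ICV
(mean-centered). All pairwise group contrasts are Wald t-tests,
Bonferroni-corrected over the explicit family m = structures × pairs
(m is printed in every result row). Jointly rescaling all volumes and
ICV leaves the contrast t-values unchanged.

Regional WMH volumes (4 lobes × 2 sides × 4 layers, periventricular→
juxtacortical, plus a basal-ganglia/infratentorial pool) are strictly
positive and right-skewed, so group effects are multiplicative: a gamma
GLM with log link and the same covariates, dispersion by Pearson χ²/df
(the statsmodels default for the gamma family). Exact zeros are shifted
by half the smallest positive value in that region before fitting
(gamma support excludes zero); the offset is configurable. Pairwise
Wald contrasts are reported *uncorrected*, because the regional outcomes
are strongly correlated and a Bonferroni family would be ill-defined.
Normalizing regions to the control-group mean (the multiplicative-factor
convention) rescales each region by a constant and therefore leaves the
log-link group p-values unchanged — asserted in the tests.

## Synthetic cohort generator

The generator produces cohorts with exactly the structure the analyses
assume, on a small MNI-like grid (default 32×38×32 at 4 mm, ≈39k voxels,
chosen so a full run with hundreds of permutations completes in minutes;
configurable up to 2-mm MNI dimensions). Geometry is schematic:
axis-aligned world-space boxes stand in for the four networks (each
containing its canonical seed sphere, pairwise disjoint), the three
signature ROIs, the brain/GM masks and the pons.

Per subject, inside the brain mask:

    uptake = scale · (1 − depth_g(pattern)
                      + Σ_k λ_{g,k} z_{ik} 1[network k]
                      + Σ_r u_{ir} 1[pattern region r]
                      + g_i 1[brain∖pons]
                      + β_age (age−mean) + β_sex sex + ε)

with latent network loadings z ~ N(0,1) (the rank-1 covariance structure
seed-based analysis assumes), regional random effects u ~ N(0, 0.06²),
a whole-brain level g ~ N(0, 0.03²) that the pons does not share (so
SUVr normalization cannot absorb it), voxel noise ε ~ N(0, 0.05²), and a
lognormal global scanner scale (σ = 0.2) that SUVr normalization removes.

Defaults are the study conditions the package is calibrated under:
group sizes 29/28/28/34 with reference-cohort age, sex, and scanner
field-strength compositions; hypometabolism depth 0.15 SUVr units in the
primary pattern (temporoparietal for both AD groups, frontoinsular for
bvFTD), a *subtle* 0.05 frontoinsular deficit in bvAD, and network
couplings λ between 0.02 and 0.08 giving bvAD a stronger anterior-DMN
covariance signature than tAD. Subcortical volumes are
Normal(group mean, 10% of the CN mean) truncated positive with a mild
ICV-coupled component; the amygdala is 15% smaller in tAD than in bvAD
(where it matches CN). WMH volumes are Gamma(shape 2) with group
multiplicative factors confined to the basal-ganglia/infratentorial
pool (1.8/1.5/1.8 for bvAD/tAD/bvFTD) and a small age effect on the log
scale. Everything is a pure function of the configuration including its
seed.

What the generator does *not* emulate: PET physics and partial-volume
effects, anatomically shaped networks, spatially correlated noise,
registration error, and site/scanner batch structure beyond a global
scale. Passing tests therefore demonstrate that the statistical
machinery is correct and calibrated under the assumed data-generating
model — not that the pipeline is robust to the artifacts of real imaging
data.

## Degenerate inputs and tie-breaks

Empty ROIs/intersections, templates that cover (or miss) the whole
analysis mask, non-positive reference means, rank-deficient designs
(reported with the collinear column names), too-small groups, and
too-few permutations all raise typed errors rather than propagating NaN.
Zero residual variance yields t = 0 rather than ±∞. Cluster peaks take
the maximum statistic voxel; ranking ties break alphabetically.

## Problem sizes used in tests and the acceptance script

Oracle checks run on single voxels and lists of length ≤ 6. Calibration
uses 200 null simulations of a 10³-voxel, 20-subject dataset with 100
permutations each; type-I rates for the tabular GLMs use 40 null cohorts
of 15 subjects per group. Recovery uses 20–40 synthetic cohorts per
claim at the default grid or small matrix designs; the end-to-end
discrimination check uses 25 full default-size cohorts. These sizes give
binomial standard errors comfortably inside the asserted tolerances
while keeping a full run in the minutes range on one CPU.

## Known limitations

- Permutation FWE differs by construction from parametric random-field
  FWE; thresholds agree only approximately.
- GOF values depend on the analysis-mask definition of "outside"; other
  conventions (whole image, thresholded maps) give different magnitudes.
- The DeLong CI is asymptotic and can clip at [0, 1] near perfect
  separation.
- The gamma-GLM zero-offset is a pragmatic device; cohorts with many
  exact zeros would be better served by a hurdle model.
- The CLI's `run-all` drives the synthetic source end to end; applying
  the full orchestration to user-supplied imaging requires calling the
  stage functions directly (all stages accept in-memory objects).
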