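"""Synthetic multimodal cohort generator.

Every analysis stage in this package assumes a particular statistical
structure in its inputs: group-specific regional hypometabolism/atrophy,
across-subject covariance driven by latent network loadings, additive
age/sex effects, Gaussian voxel noise, and gamma-distributed regional WMH
volumes with multiplicative group factors. This module generates cohorts
with exactly that structure, download-free, on a small MNI-like grid, so
the whole pipeline can be exercised and calibrated end to end.

The default configuration mirrors the reference cohort the package was
designed around: four diagnostic groups (bvAD n=29, tAD n=28, bvFTD n=28,
CN n=34) with matched age distributions, majority-male samples, mixed
1.5 T / 3 T scanners, temporoparietal-predominant hypometabolism in both
AD groups, additional frontoinsular involvement in bvAD, frontal-
predominant hypometabolism in bvFTD, and network couplings that give bvAD
a stronger anterior-DMN covariance signature than tAD.

Geometry is deliberately schematic: networks and signature regions are
axis-aligned world-space boxes placed so that each canonical seed sphere
falls inside its paired network. Nothing anatomical should be read into
the shapes; only the statistical structure matters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .connectivity import CANONICAL_SEEDS, SEED_TEMPLATE_PAIRING, NetworkTemplate
from .errors import ConfigurationError, GeometryError
from .features import SignatureROI
from .suvr import GROUPS
from .volume import BinaryMask, ScalarVolume, VolumeGrid, make_sphere_mask
from .volumetrics import SUBCORTICAL_STRUCTURES, WMH_REGIONS

__all__ = [
    "SimulationConfig",
    "default_grid",
    "make_box_mask",
    "generate_network_templates",
    "generate_masks",
    "generate_signature_rois",
    "simulate_cohort_table",
    "simulate_fdg_cohort",
    "simulate_volume_tables",
]

# ---------------------------------------------------------------------------
# Reference-cohort demographics (counts, so percentages are recomputable)

GROUP_SIZES = {"bvAD": 29, "tAD": 28, "bvFTD": 28, "CN": 34}
AGE_MEAN = {"bvAD": 64.4, "tAD": 63.0, "bvFTD": 64.6, "CN": 64.9}
AGE_SD = {"bvAD": 9.4, "tAD": 9.3, "bvFTD": 4.4, "CN": 9.9}
MALE_COUNT = {"bvAD": 17, "tAD": 16, "bvFTD": 21, "CN": 22}
LOW_FIELD_COUNT = {"bvAD": 17, "tAD": 22, "bvFTD": 14, "CN": 22}  # 1.5 T scanners
APOE4_POSITIVE = {"bvAD": (11, 18), "tAD": (10, 14), "bvFTD": (3, 27), "CN": (6, 34)}
# overlap between behavioral and dysexecutive presentations in the
# reference cohort's parent sample (count, total)
DYSEXECUTIVE_OVERLAP = (9, 75)


def percent_of(count: int, total: int) -> int:
    """Whole-number percentage of a count, as reported in cohort tables."""
    if total <= 0:
        raise ConfigurationError("total must be positive")
    return int(round(100.0 * count / total))

# World-space boxes (center mm, half-widths mm). Placed so the four
# network boxes are pairwise disjoint and each contains its seed sphere.
TEMPLATE_BOXES = {
    "pDMN": ((-8.0, -56.0, 26.0), (16.0, 16.0, 12.0)),
    "aDMN": ((6.0, 52.0, -2.0), (16.0, 12.0, 12.0)),
    "SN": ((36.0, 18.0, 4.0), (12.0, 8.0, 10.0)),
    "ECN": ((44.0, 36.0, 20.0), (12.0, 8.0, 10.0)),
}

SIGNATURE_BOXES = {
    "AD_temporoparietal": ((-42.0, -52.0, 8.0), (12.0, 12.0, 12.0)),
    "AD_parietal": ((28.0, -60.0, 34.0), (12.0, 10.0, 8.0)),
    "FTD_signature": ((-34.0, 30.0, 2.0), (12.0, 12.0, 12.0)),
}

BRAIN_BOX = ((0.0, 0.0, 0.0), (58.0, 72.0, 50.0))
CENTRAL_NONGM_BOX = ((0.0, 0.0, 0.0), (10.0, 10.0, 10.0))  # ventricle/WM stand-in
PONS_BOX = ((0.0, -28.0, -44.0), (10.0, 10.0, 6.0))

# Hypometabolism pattern regions: unions of the boxes above.
PATTERN_REGIONS = {
    "temporoparietal": ("pDMN", "AD_temporoparietal", "AD_parietal"),
    "frontoinsular": ("SN", "FTD_signature"),
    "anterior_medial": ("aDMN",),
}


def _default_depths() -> dict:
    return {
        "bvAD": {"temporoparietal": 0.15, "frontoinsular": 0.05, "anterior_medial": 0.05},
        "tAD": {"temporoparietal": 0.15, "anterior_medial": 0.02},
        "bvFTD": {"frontoinsular": 0.15, "anterior_medial": 0.10},
        "CN": {},
    }


def _default_couplings() -> dict:
    return {
        "CN": {"pDMN": 0.06, "aDMN": 0.05, "SN": 0.05, "ECN": 0.05},
        "bvAD": {"pDMN": 0.07, "aDMN": 0.08, "SN": 0.03, "ECN": 0.04},
        "tAD": {"pDMN": 0.08, "aDMN": 0.04, "SN": 0.02, "ECN": 0.05},
        "bvFTD": {"pDMN": 0.03, "aDMN": 0.08, "SN": 0.08, "ECN": 0.05},
    }


# Subcortical means (cm³, bilateral sums) and per-group multipliers.
SUBCORTICAL_CN_MEAN = {
    "amygdala": 3.0,
    "nucleus_accumbens": 1.0,
    "caudate": 7.0,
    "putamen": 10.0,
    "globus_pallidus": 3.5,
    "hippocampus": 7.5,
    "thalamus": 16.0,
}


def _default_subcortical_factors() -> dict:
    return {
        "CN": {s: 1.0 for s in SUBCORTICAL_STRUCTURES},
        "bvAD": {
            "amygdala": 1.0,
            "nucleus_accumbens": 0.95,
            "caudate": 0.90,
            "putamen": 0.90,
            "globus_pallidus": 0.97,
            "hippocampus": 0.85,
            "thalamus": 0.90,
        },
        "tAD": {
            "amygdala": 0.85,
            "nucleus_accumbens": 0.88,
            "caudate": 0.97,
            "putamen": 0.97,
            "globus_pallidus": 1.0,
            "hippocampus": 0.85,
            "thalamus": 0.90,
        },
        "bvFTD": {
            "amygdala": 0.85,
            "nucleus_accumbens": 0.80,
            "caudate": 0.85,
            "putamen": 0.85,
            "globus_pallidus": 0.80,
            "hippocampus": 0.85,
            "thalamus": 0.85,
        },
    }


def _default_wmh_factors() -> dict:
    # multiplicative group factors; deviations confined to the
    # basal-ganglia/infratentorial pool, which is elevated in patients
    base = {r: 1.0 for r in WMH_REGIONS}
    out = {g: dict(base) for g in GROUPS}
    out["bvAD"]["bgit"] = 1.8
    out["bvFTD"]["bgit"] = 1.8
    out["tAD"]["bgit"] = 1.5
    return out


def _wmh_base_means() -> dict:
    # cm³ per region in controls; periventricular (layer 1) carries most load
    layer_mean = {1: 0.40, 2: 0.25, 3: 0.15, 4: 0.10}
    means = {}
    for r in WMH_REGIONS:
        if r == "bgit":
            means[r] = 0.30
        else:
            means[r] = layer_mean[int(r[-1])]
    return means


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort; outputs are pure functions of it.

    Defaults are the study conditions the pipeline is calibrated under:
    4 mm isotropic 32x38x32 grid, reference-cohort group sizes and
    demographics, hypometabolism depth 0.15 in the primary pattern,
    latent network couplings 0.03-0.08 SUVr units, voxel noise 0.05,
    age slope -0.002/yr, sex offset -0.01, gamma shape 2.
    """

    shape: tuple[int, int, int] = (32, 38, 32)
    spacing_mm: float = 4.0
    group_sizes: dict = field(default_factory=lambda: dict(GROUP_SIZES))
    depths: dict = field(default_factory=_default_depths)
    couplings: dict = field(default_factory=_default_couplings)
    noise_sigma: float = 0.05
    regional_sigma: float = 0.06  # per-subject random effect per pattern region
    global_gm_sigma: float = 0.03  # per-subject whole-brain metabolic level
    age_slope: float = -0.002
    sex_offset: float = -0.01
    global_scale_sd: float = 0.2  # lognormal sd of per-subject uptake scale
    subcortical_factors: dict = field(default_factory=_default_subcortical_factors)
    subcortical_sigma_frac: float = 0.10
    subcortical_icv_coupling: float = 0.25
    wmh_shape: float = 2.0
    wmh_factors: dict = field(default_factory=_default_wmh_factors)
    wmh_age_slope: float = 0.03  # per decade, on the log scale
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 4 for n in self.group_sizes.values()):
            raise ConfigurationError("group sizes must be >= 4")
        if self.noise_sigma <= 0:
            raise ConfigurationError("noise sigma must be > 0")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, rng_seed=seed)


# ---------------------------------------------------------------------------
# Geometry


def default_grid(shape=(32, 38, 32), spacing_mm: float = 4.0) -> VolumeGrid:
    """A centered MNI-like grid: RAS axes, origin at the grid center."""
    shape = tuple(int(s) for s in shape)
    affine = np.diag([spacing_mm, spacing_mm, spacing_mm, 1.0])
    affine[:3, 3] = -(np.array(shape) - 1) / 2.0 * spacing_mm
    return VolumeGrid(shape, affine)


def make_box_mask(grid: VolumeGrid, center, half_widths) -> BinaryMask:
    """Axis-aligned world-space box: member iff |coord - center| <= half."""
    coords = grid.coordinate_image()
    inside = np.all(
        np.abs(coords - np.asarray(center, float)) <= np.asarray(half_widths, float),
        axis=-1,
    )
    return BinaryMask(grid, inside)


def generate_network_templates(grid: VolumeGrid) -> dict[str, NetworkTemplate]:
    """Four pairwise-disjoint geometric network stand-ins (synthetic),
    each containing its canonical seed sphere."""
    templates = {}
    for name, (center, half) in TEMPLATE_BOXES.items():
        mask = make_box_mask(grid, center, half)
        if mask.n_true == 0:
            raise GeometryError(f"grid too small: template {name!r} is empty")
        sphere = make_sphere_mask(grid, CANONICAL_SEEDS[SEED_TEMPLATE_PAIRING[name]])
        if (sphere.membership & ~mask.membership).any():
            raise GeometryError(
                f"grid too small: seed sphere for {name!r} is not contained"
            )
        templates[name] = NetworkTemplate(name, mask, source_label="synthetic box")
    names = list(templates)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if (templates[a].mask.membership & templates[b].mask.membership).any():
                raise GeometryError(f"templates {a!r} and {b!r} overlap on this grid")
    return templates


def generate_masks(grid: VolumeGrid) -> dict[str, BinaryMask]:
    """Brain, gray-matter and pons-reference masks (synthetic geometry)."""
    brain = make_box_mask(grid, *BRAIN_BOX)
    pons = make_box_mask(grid, *PONS_BOX).require_nonempty("pons mask")
    central = make_box_mask(grid, *CENTRAL_NONGM_BOX)
    gm = brain.minus(central).minus(pons).require_nonempty("gray-matter mask")
    return {"brain": brain.require_nonempty("brain mask"), "gm": gm, "pons": pons}


def generate_signature_rois(grid: VolumeGrid) -> dict[str, SignatureROI]:
    return {
        name: SignatureROI(name, make_box_mask(grid, center, half))
        for name, (center, half) in SIGNATURE_BOXES.items()
    }


def _pattern_masks(grid: VolumeGrid) -> dict[str, np.ndarray]:
    boxes = {**TEMPLATE_BOXES, **SIGNATURE_BOXES}
    out = {}
    for region, members in PATTERN_REGIONS.items():
        acc = np.zeros(grid.shape, dtype=bool)
        for m in members:
            acc |= make_box_mask(grid, *boxes[m]).membership
        out[region] = acc
    return out


# ---------------------------------------------------------------------------
# Cohort table


def simulate_cohort_table(config: SimulationConfig, rng=None) -> pd.DataFrame:
    """Subject table with ages, sexes, field strengths and ICV drawn to
    match the reference-cohort moments; deterministic given the seed."""
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    rows = []
    for group, n in config.group_sizes.items():
        ages = rng.normal(AGE_MEAN.get(group, 65.0), AGE_SD.get(group, 9.0), n)
        ages = np.clip(ages, 40.0, 95.0)
        # scale the reference counts when a non-default group size is asked for
        ref_n = GROUP_SIZES.get(group, n)
        n_male = int(round(n * MALE_COUNT.get(group, ref_n // 2) / ref_n))
        n_male = min(max(n_male, 1), n - 1) if n >= 2 else n_male
        n_low = int(round(n * LOW_FIELD_COUNT.get(group, ref_n // 2) / ref_n))
        sex = np.zeros(n, dtype=int)
        sex[:n_male] = 1
        rng.shuffle(sex)
        fs = np.full(n, 3.0)
        low = np.zeros(n, dtype=bool)
        low[:n_low] = True
        rng.shuffle(low)
        fs[low] = 1.5
        icv = rng.normal(1450.0, 120.0, n) + 130.0 * sex
        for i in range(n):
            rows.append(
                {
                    "subject_id": f"{group}_{i:03d}",
                    "group": group,
                    "age": float(ages[i]),
                    "sex": int(sex[i]),
                    "field_strength_t": float(fs[i]),
                    "icv_cm3": float(icv[i]),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# FDG volumes


def simulate_fdg_cohort(config: SimulationConfig):
    """Generate the full imaging cohort.

    Returns (cohort, scans, masks, templates, rois, latents) where scans
    maps subject_id to a raw uptake :class:`ScalarVolume` (pons-mean near
    the subject's global scale, so SUVr normalization is exercised), and
    latents maps subject_id to its network loading vector z (exposed for
    calibration tests).

    Per subject i in group g, inside the brain mask::

        uptake = scale_i * ( 1 - depth_g(pattern)
                             + sum_k lambda_{g,k} * z_{ik} * 1[network_k]
                             + sum_r u_{ir} * 1[pattern region r]
                             + g_i * 1[brain \\ pons]
                             + beta_age * (age_i - mean age)
                             + beta_sex * sex_i
                             + eps ),   eps ~ N(0, sigma^2) iid

    with z_{ik} ~ N(0,1) latent loadings shared by all voxels of network
    k — the rank-1 structure seed-based covariance analysis assumes —
    and subject random effects u_{ir} ~ N(0, regional_sigma^2) per broad
    pattern region and g_i ~ N(0, global_gm_sigma^2) across the brain
    (pons excluded so SUVr normalization does not absorb it). The random
    effects give ROI-level features a realistic between-subject spread,
    keeping group separations on the images subtle rather than
    deterministic.
    """
    rng = np.random.default_rng(config.rng_seed)
    grid = default_grid(config.shape, config.spacing_mm)
    masks = generate_masks(grid)
    templates = generate_network_templates(grid)
    rois = generate_signature_rois(grid)
    patterns = _pattern_masks(grid)
    cohort = simulate_cohort_table(config, rng=rng)
    age_centered = cohort["age"] - cohort["age"].mean()
    brain = masks["brain"].membership
    net_names = list(templates)
    scans: dict[str, ScalarVolume] = {}
    latents: dict[str, np.ndarray] = {}
    for idx, rec in enumerate(cohort.itertuples()):
        base = np.zeros(grid.shape)
        base[brain] = 1.0
        for region, depth in config.depths.get(rec.group, {}).items():
            base[patterns[region] & brain] -= depth
        z = rng.standard_normal(len(net_names))
        for k, name in enumerate(net_names):
            lam = config.couplings.get(rec.group, {}).get(name, 0.0)
            base[templates[name].mask.membership & brain] += lam * z[k]
        for region in PATTERN_REGIONS:
            u = rng.normal(0.0, config.regional_sigma) if config.regional_sigma else 0.0
            base[patterns[region] & brain] += u
        g_i = rng.normal(0.0, config.global_gm_sigma) if config.global_gm_sigma else 0.0
        base[brain & ~masks["pons"].membership] += g_i
        base[brain] += config.age_slope * float(age_centered.iloc[idx])
        base[brain] += config.sex_offset * rec.sex
        base[brain] += rng.normal(0.0, config.noise_sigma, int(brain.sum()))
        scale = float(np.exp(rng.normal(0.0, config.global_scale_sd)))
        scans[rec.subject_id] = ScalarVolume(grid, base * scale)
        latents[rec.subject_id] = z
    return cohort, scans, masks, templates, rois, latents


# ---------------------------------------------------------------------------
# Volumetric tables


def simulate_volume_tables(config: SimulationConfig, cohort: pd.DataFrame | None = None):
    """Subcortical-volume and regional-WMH tables for the cohort.

    Subcortical: Normal(group mean, sigma) truncated positive, with an
    ICV-correlated component. WMH: Gamma(shape, scale) with per-group
    multiplicative regional factors and a mild age effect on the log
    scale. Deterministic given config.rng_seed.
    """
    # offset the stream so the tables do not recycle the imaging draws
    rng = np.random.default_rng((int(config.rng_seed) + 101) % 2**31)
    if cohort is None:
        cohort = simulate_cohort_table(config, rng=np.random.default_rng(config.rng_seed))
    icv = cohort["icv_cm3"].to_numpy()
    icv_rel = (icv - icv.mean()) / icv.mean()
    sub_rows = {"subject_id": cohort["subject_id"].to_numpy()}
    for s in SUBCORTICAL_STRUCTURES:
        cn_mean = SUBCORTICAL_CN_MEAN[s]
        means = np.array(
            [
                cn_mean * config.subcortical_factors[g][s]
                for g in cohort["group"]
            ]
        )
        vol = means * (1.0 + config.subcortical_icv_coupling * icv_rel)
        vol = vol + rng.normal(0.0, config.subcortical_sigma_frac * cn_mean, len(cohort))
        sub_rows[f"{s}_cm3"] = np.maximum(vol, 0.05 * cn_mean)
    subcortical = pd.DataFrame(sub_rows)

    base_means = _wmh_base_means()
    age = cohort["age"].to_numpy()
    wmh_rows = {"subject_id": cohort["subject_id"].to_numpy()}
    for r in WMH_REGIONS:
        factors = np.array([config.wmh_factors[g][r] for g in cohort["group"]])
        mean = (
            base_means[r]
            * factors
            * np.exp(config.wmh_age_slope * (age - age.mean()) / 10.0)
        )
        scale = mean / config.wmh_shape
        wmh_rows[r] = rng.gamma(config.wmh_shape, scale)
    wmh = pd.DataFrame(wmh_rows)
    return subcortical, wmh
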