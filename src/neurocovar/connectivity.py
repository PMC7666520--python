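"""Seed-based interregional metabolic covariance (IRCA) and goodness-of-fit.

Across subjects of one diagnostic group, the mean SUVr inside a small seed
sphere is regressed against SUVr at every gray-matter voxel (adjusting for
age and sex); the seed-slope t statistic per voxel forms the group's
covariance map. Agreement of a covariance map with a canonical functional
network is scored as GOF = mean t inside the network template minus mean t
outside it (both within the analysis mask). A two-group interaction model
with per-group seed slopes tests whether metabolic connectivity differs
between diagnostic groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import (
    ConfigurationError,
    DesignError,
    EmptyROIError,
    PartitionError,
    SampleSizeError,
)
from .glm import MassUnivariateOLS, TMap, ThresholdSpec, threshold_tmap
from .suvr import extract_roi_mean
from .volume import BinaryMask, ScalarVolume, SphereSeed, make_sphere_mask

__all__ = [
    "CANONICAL_SEEDS",
    "SEED_TEMPLATE_PAIRING",
    "NetworkTemplate",
    "CovarianceMap",
    "GOFScore",
    "InteractionResult",
    "SeedSlopeModel",
    "SlopeInteractionModel",
    "extract_seed_values",
    "irca_covariance_map",
    "goodness_of_fit",
    "gof_profile",
    "interaction_analysis",
]

# Published seed coordinates (MNI mm) anchoring each canonical network.
CANONICAL_SEEDS = {
    "PCC": SphereSeed("PCC", (-8.0, -56.0, 26.0), 4.0),
    "amPFC": SphereSeed("amPFC", (6.0, 52.0, -2.0), 4.0),
    "riFI": SphereSeed("riFI", (36.0, 18.0, 4.0), 4.0),
    "riDLPFC": SphereSeed("riDLPFC", (44.0, 36.0, 20.0), 4.0),
}

# network -> seed anchoring it
SEED_TEMPLATE_PAIRING = {
    "pDMN": "PCC",
    "aDMN": "amPFC",
    "SN": "riFI",
    "ECN": "riDLPFC",
}


@dataclass
class NetworkTemplate:
    """A binary mask of a canonical functional network."""

    name: str
    mask: BinaryMask
    source_label: str = ""

    def __post_init__(self) -> None:
        self.mask.require_nonempty(f"network template {self.name!r}")


@dataclass
class CovarianceMap:
    group: str
    seed: SphereSeed
    tmap: TMap


@dataclass
class GOFScore:
    group: str
    network: str
    t_inside: float
    t_outside: float

    @property
    def gof(self) -> float:
        return self.t_inside - self.t_outside


@dataclass
class InteractionResult:
    group_pair: tuple[str, str]
    seed: SphereSeed
    tmap: TMap
    clusters_p001: pd.DataFrame
    clusters_p05: pd.DataFrame


class SeedSlopeModel(BaseEstimator):
    """Voxelwise regression of each voxel on a seed signal plus covariates.

    fit(X, Y): X has columns [seed, *covariates] (one row per subject),
    Y is (n_subjects, n_voxels). An intercept is prepended internally.

    Attributes
    ----------
    t_ : (v,) ndarray — seed-slope t per voxel.
    df_ : int — n - (2 + n_covariates).
    """

    def __init__(self, min_subjects_margin: int = 3):
        self.min_subjects_margin = min_subjects_margin

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "SeedSlopeModel":
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        n, k = X.shape
        n_cov = k - 1
        if n < n_cov + self.min_subjects_margin:
            raise SampleSizeError(
                f"group of {n} subjects too small for {n_cov} covariates "
                f"(need >= {n_cov + self.min_subjects_margin})"
            )
        design = np.column_stack([np.ones(n), X])
        self.ols_ = MassUnivariateOLS(
            column_labels=["intercept", "seed"] + [f"cov{i}" for i in range(n_cov)]
        ).fit(design, Y)
        c = np.zeros(design.shape[1])
        c[1] = 1.0
        self.t_, self.df_ = self.ols_.contrast(c)
        return self


class SlopeInteractionModel(BaseEstimator):
    """Two-group model with per-group seed slopes; tests slope equality.

    fit(seed, group_is_b, covariates, Y) builds the design
    [1[g=A], 1[g=B], seed*1[g=A], seed*1[g=B], covariates...] and stores
    the t-map for the contrast slope_A - slope_B (shared covariate
    effects across groups).
    """

    def fit(
        self,
        seed_values: np.ndarray,
        group_is_b: np.ndarray,
        covariates: np.ndarray,
        Y: np.ndarray,
    ) -> "SlopeInteractionModel":
        seed_values = np.asarray(seed_values, dtype=float)
        gb = np.asarray(group_is_b, dtype=bool)
        if gb.all() or not gb.any():
            raise DesignError("interaction model needs subjects from both groups")
        ga = ~gb
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        design = np.column_stack(
            [
                ga.astype(float),
                gb.astype(float),
                seed_values * ga,
                seed_values * gb,
                cov,
            ]
        )
        labels = ["groupA", "groupB", "slopeA", "slopeB"] + [
            f"cov{i}" for i in range(cov.shape[1])
        ]
        self.ols_ = MassUnivariateOLS(column_labels=labels).fit(design, Y)
        c = np.zeros(design.shape[1])
        c[2], c[3] = 1.0, -1.0
        self.t_, self.df_ = self.ols_.contrast(c)
        return self


# --------------------------------------------------------------------------
# Functional surface


def extract_seed_values(
    scans: dict[str, ScalarVolume],
    subject_ids: list[str],
    seed: SphereSeed,
    gm_mask: BinaryMask,
) -> np.ndarray:
    """Per-subject mean SUVr inside the seed sphere ∩ gray-matter mask."""
    sphere = make_sphere_mask(gm_mask.grid, seed)
    if not (sphere.membership & gm_mask.membership).any():
        raise EmptyROIError(
            f"seed sphere {seed.name!r} lies entirely outside the gray-matter mask"
        )
    return np.array(
        [extract_roi_mean(scans[s], sphere, restrict=gm_mask) for s in subject_ids]
    )


def irca_covariance_map(
    scans: dict[str, ScalarVolume],
    cohort_rows: pd.DataFrame,
    seed: SphereSeed,
    gm_mask: BinaryMask,
    covariates: list[str] = ("age", "sex"),
) -> CovarianceMap:
    """One group's interregional covariance t-map for one seed.

    cohort_rows must contain a single diagnostic group; the stored t is
    the seed-slope t at each gray-matter voxel, adjusted for age and sex.
    """
    groups = cohort_rows["group"].unique()
    if len(groups) != 1:
        raise DesignError(f"expected a single group, got {list(groups)}")
    ids = list(cohort_rows["subject_id"])
    seed_vals = extract_seed_values(scans, ids, seed, gm_mask)
    flat = gm_mask.membership.ravel()
    Y = np.vstack([scans[s].values.ravel()[flat] for s in ids])
    X = np.column_stack(
        [seed_vals] + [cohort_rows[c].to_numpy(dtype=float) for c in covariates]
    )
    model = SeedSlopeModel().fit(X, Y)
    t_full = np.zeros(gm_mask.grid.n_voxels)
    t_full[flat] = model.t_
    tmap = TMap(
        gm_mask.grid,
        t_full.reshape(gm_mask.grid.shape),
        model.df_,
        f"irca[{groups[0]}:{seed.name}]",
    )
    return CovarianceMap(str(groups[0]), seed, tmap)


def goodness_of_fit(
    covmap: CovarianceMap,
    template: NetworkTemplate,
    analysis_mask: BinaryMask,
    thresholded: bool = False,
    threshold_alpha: float = 0.001,
) -> GOFScore:
    """GOF = mean t inside the template minus mean t outside (within mask).

    Computed on the unthresholded covariance t-map by default; set
    `thresholded` to zero out sub-threshold voxels first (display-style
    variant).
    """
    t = covmap.tmap.t_values
    if thresholded:
        from scipy import stats as _st

        crit = _st.t.ppf(1 - threshold_alpha, covmap.tmap.df)
        t = np.where(t > crit, t, 0.0)
    inside = template.mask.membership & analysis_mask.membership
    outside = analysis_mask.membership & ~template.mask.membership
    if not inside.any() or not outside.any():
        raise PartitionError(
            f"template {template.name!r} does not split the analysis mask "
            "into non-empty inside and outside sets"
        )
    return GOFScore(
        covmap.group,
        template.name,
        float(t[inside].mean()),
        float(t[outside].mean()),
    )


def gof_profile(
    covmaps: dict[tuple[str, str], CovarianceMap],
    templates: dict[str, NetworkTemplate],
    analysis_mask: BinaryMask,
    pairing: dict[str, str] | None = None,
) -> pd.DataFrame:
    """GOF table: one row per (group, network), using the paired seed.

    covmaps is keyed by (group, seed_name). No inferential statistics are
    attached: GOF is a group-level descriptive score.
    """
    pairing = dict(SEED_TEMPLATE_PAIRING if pairing is None else pairing)
    rows = []
    groups = sorted({g for g, _ in covmaps})
    for network, template in templates.items():
        if network not in pairing:
            raise ConfigurationError(f"no seed paired with network {network!r}")
        seed_name = pairing[network]
        for group in groups:
            key = (group, seed_name)
            if key not in covmaps:
                raise ConfigurationError(
                    f"missing covariance map for group {group!r}, seed {seed_name!r}"
                )
            score = goodness_of_fit(covmaps[key], template, analysis_mask)
            rows.append(
                {
                    "group": group,
                    "network": network,
                    "seed": seed_name,
                    "t_inside": score.t_inside,
                    "t_outside": score.t_outside,
                    "gof": score.gof,
                }
            )
    return pd.DataFrame(rows)


def interaction_analysis(
    scans: dict[str, ScalarVolume],
    cohort_rows: pd.DataFrame,
    group_pair: tuple[str, str],
    seed: SphereSeed,
    gm_mask: BinaryMask,
    covariates: list[str] = ("age", "sex"),
    extent_k: int = 0,
) -> InteractionResult:
    """Voxelwise test of seed-slope differences between two groups.

    Reported at both p<0.001 and p<0.05 uncorrected (two-sided on the
    slope-difference t), without an extent threshold by default.
    """
    from .glm import clusters_to_frame

    a, b = group_pair
    rows = cohort_rows[cohort_rows["group"].isin(group_pair)].reset_index(drop=True)
    for g in group_pair:
        if (rows["group"] == g).sum() == 0:
            raise DesignError(f"group {g!r} has no subjects in the cohort")
    ids = list(rows["subject_id"])
    seed_vals = extract_seed_values(scans, ids, seed, gm_mask)
    flat = gm_mask.membership.ravel()
    Y = np.vstack([scans[s].values.ravel()[flat] for s in ids])
    cov = np.column_stack([rows[c].to_numpy(dtype=float) for c in covariates])
    model = SlopeInteractionModel().fit(
        seed_vals, (rows["group"] == b).to_numpy(), cov, Y
    )
    t_full = np.zeros(gm_mask.grid.n_voxels)
    t_full[flat] = model.t_
    tmap = TMap(
        gm_mask.grid,
        t_full.reshape(gm_mask.grid.shape),
        model.df_,
        f"interaction[{a}-{b}:{seed.name}]",
    )
    clusters = {}
    for alpha in (0.001, 0.05):
        spec = ThresholdSpec(
            alpha=alpha, correction="uncorrected", extent_k=extent_k,
            sidedness="two_sided",
        )
        _, cl = threshold_tmap(tmap, spec, analysis_mask=gm_mask)
        clusters[alpha] = clusters_to_frame(cl)
    return InteractionResult((a, b), seed, tmap, clusters[0.001], clusters[0.05])
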