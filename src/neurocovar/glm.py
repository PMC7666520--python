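"""Mass-univariate voxelwise group comparison with covariate adjustment.

The statistical core is :class:`MassUnivariateOLS`, a scikit-learn style
estimator fitting an identical ordinary-least-squares model independently
at every voxel of a stacked (subjects x voxels) data matrix. Group
contrasts yield t-maps; family-wise error control uses the max-statistic
permutation distribution with Freedman–Lane shuffling of nuisance-adjusted
residuals, and suprathreshold voxels are filtered by connected-cluster
extent (18-neighbourhood: faces + edges).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from sklearn.base import BaseEstimator

from .errors import (
    DesignError,
    DomainError,
    GridError,
    InsufficientPermutationsError,
    SampleSizeError,
)
from .volume import BinaryMask, VolumeGrid

__all__ = [
    "MassUnivariateOLS",
    "TMap",
    "ThresholdSpec",
    "Cluster",
    "build_design_matrix",
    "fit_voxelwise_glm",
    "group_contrast_tmap",
    "build_permutation_null",
    "threshold_tmap",
    "overlay_significance_maps",
]

# faces + edges connectivity for cluster labelling
CLUSTER_STRUCTURE = ndimage.generate_binary_structure(3, 2)


@dataclass
class TMap:
    """A voxelwise t statistic map with its residual degrees of freedom."""

    grid: VolumeGrid
    t_values: np.ndarray
    df: int
    contrast_label: str = ""

    def __post_init__(self) -> None:
        self.t_values = np.asarray(self.t_values, dtype=float)
        if self.t_values.shape != self.grid.shape:
            raise GridError("t map shape does not match grid")


@dataclass
class ThresholdSpec:
    """How to threshold a t-map.

    alpha: significance level; correction: 'uncorrected' (voxelwise
    Student-t p) or 'fwe_permutation' (max-statistic null quantile);
    extent_k: minimum cluster size in voxels; sidedness: 'one_sided'
    (positive direction) or 'two_sided'.
    """

    alpha: float = 0.05
    correction: str = "uncorrected"
    extent_k: int = 50
    sidedness: str = "one_sided"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise DomainError(f"alpha must be in (0,1), got {self.alpha}")
        if self.extent_k < 0:
            raise DomainError("extent_k must be >= 0")
        if self.correction not in ("uncorrected", "fwe_permutation"):
            raise DomainError(f"unknown correction {self.correction!r}")
        if self.sidedness not in ("one_sided", "two_sided"):
            raise DomainError(f"unknown sidedness {self.sidedness!r}")


@dataclass
class Cluster:
    cluster_id: int
    n_voxels: int
    peak_t: float
    peak_xyz_mm: tuple[float, float, float]


class MassUnivariateOLS(BaseEstimator):
    """Voxelwise OLS: the same design, an independent fit per voxel.

    Parameters
    ----------
    column_labels : list of str, optional
        Names for the design columns (used in error messages and reports).

    Attributes
    ----------
    coef_ : (p, v) ndarray — per-voxel coefficients.
    sigma2_ : (v,) ndarray — residual variance (RSS / df).
    df_ : int — residual degrees of freedom, n - rank(X).
    xtx_inv_ : (p, p) ndarray — (X'X)^-1 for contrast variances.
    residuals_ : (n, v) ndarray — fit residuals.
    """

    def __init__(self, column_labels: list[str] | None = None):
        self.column_labels = column_labels

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "MassUnivariateOLS":
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        n, p = X.shape
        if Y.shape[0] != n:
            raise DesignError(f"design has {n} rows but data has {Y.shape[0]}")
        if n < p + 2:
            raise SampleSizeError(
                f"need at least {p + 2} subjects for {p} design columns, got {n}"
            )
        rank = np.linalg.matrix_rank(X)
        if rank < p:
            raise DesignError(self._collinearity_message(X))
        self.n_samples_, self.n_features_ = n, p
        self.xtx_inv_ = np.linalg.inv(X.T @ X)
        self.coef_ = self.xtx_inv_ @ X.T @ Y
        fitted = X @ self.coef_
        self.residuals_ = Y - fitted
        self.df_ = n - p
        rss = np.einsum("nv,nv->v", self.residuals_, self.residuals_)
        self.sigma2_ = rss / self.df_
        self.X_ = X
        return self

    def _collinearity_message(self, X: np.ndarray) -> str:
        labels = self.column_labels or [f"col{i}" for i in range(X.shape[1])]
        # name columns whose removal restores full rank
        culprits = []
        full_rank = np.linalg.matrix_rank(X)
        for j in range(X.shape[1]):
            reduced = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(reduced) == full_rank:
                culprits.append(labels[j])
        return f"design matrix is rank deficient; collinear columns include {culprits}"

    def contrast(self, c: np.ndarray) -> tuple[np.ndarray, int]:
        """t statistic per voxel for the linear contrast c'beta = 0."""
        c = np.asarray(c, dtype=float)
        if c.shape != (self.n_features_,):
            raise DesignError(
                f"contrast length {c.shape} does not match {self.n_features_} columns"
            )
        if np.all(c == 0):
            raise DomainError("contrast vector is identically zero")
        effect = c @ self.coef_
        var = self.sigma2_ * float(c @ self.xtx_inv_ @ c)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(var > 0, effect / np.sqrt(var), 0.0)
        return t, self.df_


# --------------------------------------------------------------------------
# Design matrices


def build_design_matrix(
    cohort: pd.DataFrame,
    groups: list[str],
    covariates: list[str] = ("age", "sex"),
    center_covariates: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Cell-means design: one indicator per group plus mean-centered covariates.

    Column order: [group indicators in `groups` order] + covariates. The
    cell-means coding makes pairwise group contrasts simple +1/-1 vectors.
    """
    rows = cohort[cohort["group"].isin(groups)]
    if rows.empty:
        raise DesignError(f"no subjects in groups {groups}")
    cols, labels = [], []
    for g in groups:
        ind = (rows["group"] == g).to_numpy(dtype=float)
        if ind.sum() == 0:
            raise DesignError(f"group {g!r} has no subjects")
        cols.append(ind)
        labels.append(f"group[{g}]")
    for cov in covariates:
        v = rows[cov].to_numpy(dtype=float)
        if center_covariates:
            v = v - v.mean()
        cols.append(v)
        labels.append(cov)
    return np.column_stack(cols), labels


def pairwise_contrast(labels: list[str], group_a: str, group_b: str) -> np.ndarray:
    """Contrast vector testing mean(group_a) - mean(group_b)."""
    c = np.zeros(len(labels))
    c[labels.index(f"group[{group_a}]")] = 1.0
    c[labels.index(f"group[{group_b}]")] = -1.0
    return c


# --------------------------------------------------------------------------
# Functional wrappers over MassUnivariateOLS


def fit_voxelwise_glm(
    data: np.ndarray,
    design: np.ndarray,
    analysis_mask: BinaryMask,
    column_labels: list[str] | None = None,
) -> MassUnivariateOLS:
    """Fit the voxelwise OLS on in-mask voxels of an (n, v) data matrix.

    `data` rows are subjects; columns are raveled voxels of the mask's
    grid. The fitted estimator remembers the mask for map reconstruction.
    """
    analysis_mask.require_nonempty("analysis mask")
    flat = analysis_mask.membership.ravel()
    if data.shape[1] == flat.size:
        Y = data[:, flat]
    elif data.shape[1] == int(flat.sum()):
        Y = data
    else:
        raise GridError(
            f"data has {data.shape[1]} voxel columns; mask grid has {flat.size} "
            f"voxels ({int(flat.sum())} in-mask)"
        )
    est = MassUnivariateOLS(column_labels=column_labels).fit(design, Y)
    est.mask_ = analysis_mask
    return est


def _embed(mask: BinaryMask, flat_values: np.ndarray, fill: float = 0.0) -> np.ndarray:
    out = np.full(mask.grid.n_voxels, fill)
    out[mask.membership.ravel()] = flat_values
    return out.reshape(mask.grid.shape)


def group_contrast_tmap(
    fit: MassUnivariateOLS, contrast: np.ndarray, label: str = ""
) -> TMap:
    """t-map for a linear contrast of a fitted voxelwise model."""
    t, df = fit.contrast(contrast)
    return TMap(fit.mask_.grid, _embed(fit.mask_, t), df, label)


# --------------------------------------------------------------------------
# Permutation null (max statistic, Freedman–Lane)


def build_permutation_null(
    data: np.ndarray,
    design: np.ndarray,
    contrast: np.ndarray,
    analysis_mask: BinaryMask,
    n_perm: int = 1000,
    rng_seed: int = 0,
    two_sided: bool = False,
    column_labels: list[str] | None = None,
) -> np.ndarray:
    """Max-t permutation null for FWE control.

    Freedman–Lane: nuisance columns (zero contrast weight) are fitted
    first; their residuals are row-permuted, the nuisance fit is added
    back, and the full-model contrast t-map is recomputed; the maximum
    (of t, or |t| when two_sided) over in-mask voxels is stored per
    permutation. Deterministic given rng_seed.
    """
    if n_perm < 100:
        raise DomainError(f"n_perm must be >= 100, got {n_perm}")
    contrast = np.asarray(contrast, dtype=float)
    flat = analysis_mask.membership.ravel()
    if data.shape[1] == flat.size:
        Y = data[:, flat]
    else:
        Y = data
    rng = np.random.default_rng(rng_seed)
    # nuisance space: intercept + zero-weight columns. The explicit
    # intercept matters with cell-means group coding: without it the
    # grand mean stays in the residuals and permutation mixes it across
    # groups, destroying the null.
    nuisance = np.column_stack(
        [np.ones(design.shape[0]), design[:, contrast == 0]]
    )
    hat_n = nuisance @ np.linalg.pinv(nuisance)
    fitted_n = hat_n @ Y
    resid_n = Y - fitted_n
    n = Y.shape[0]
    maxima = np.empty(n_perm)
    est = MassUnivariateOLS(column_labels=column_labels)
    for b in range(n_perm):
        perm = rng.permutation(n)
        Y_star = fitted_n + resid_n[perm]
        est.fit(design, Y_star)
        t, _ = est.contrast(contrast)
        maxima[b] = np.max(np.abs(t)) if two_sided else np.max(t)
    return maxima


# --------------------------------------------------------------------------
# Thresholding and clusters


def _label_clusters(mask3d: np.ndarray) -> tuple[np.ndarray, int]:
    return ndimage.label(mask3d, structure=CLUSTER_STRUCTURE)


def threshold_tmap(
    tmap: TMap,
    spec: ThresholdSpec,
    null_max_t: np.ndarray | None = None,
    analysis_mask: BinaryMask | None = None,
) -> tuple[BinaryMask, list[Cluster]]:
    """Apply voxelwise threshold + cluster extent filter to a t-map.

    Uncorrected: voxel p from Student-t(df) per sidedness, pass iff p <
    alpha. FWE: pass iff the statistic exceeds the (1 - alpha) quantile
    of the permutation max-statistic null. Connected components (18-
    neighbourhood) smaller than extent_k are then dropped.
    """
    t = tmap.t_values
    stat = np.abs(t) if spec.sidedness == "two_sided" else t
    if spec.correction == "uncorrected":
        crit = (
            stats.t.ppf(1 - spec.alpha / 2, tmap.df)
            if spec.sidedness == "two_sided"
            else stats.t.ppf(1 - spec.alpha, tmap.df)
        )
        passed = stat > crit
    else:
        if null_max_t is None:
            raise DomainError("fwe_permutation requires a permutation null stack")
        if len(null_max_t) < 1 / spec.alpha:
            raise InsufficientPermutationsError(
                f"{len(null_max_t)} permutations cannot resolve alpha={spec.alpha}; "
                f"need at least {int(np.ceil(1 / spec.alpha))}"
            )
        crit = float(np.quantile(null_max_t, 1 - spec.alpha))
        passed = stat > crit
    if analysis_mask is not None:
        passed = passed & analysis_mask.membership
    labels, n_lab = _label_clusters(passed)
    clusters: list[Cluster] = []
    keep = np.zeros_like(passed)
    cid = 0
    for lab in range(1, n_lab + 1):
        comp = labels == lab
        size = int(comp.sum())
        if size < spec.extent_k:
            continue
        cid += 1
        keep |= comp
        masked_t = np.where(comp, stat, -np.inf)
        peak_idx = np.unravel_index(int(np.argmax(masked_t)), stat.shape)
        peak_world = tmap.grid.voxel_to_world(np.array(peak_idx))[0]
        clusters.append(
            Cluster(cid, size, float(t[peak_idx]), tuple(float(x) for x in peak_world))
        )
    return BinaryMask(tmap.grid, keep), clusters


def clusters_to_frame(clusters: list[Cluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cluster_id": c.cluster_id,
                "n_voxels": c.n_voxels,
                "peak_t": c.peak_t,
                "x_mm": c.peak_xyz_mm[0],
                "y_mm": c.peak_xyz_mm[1],
                "z_mm": c.peak_xyz_mm[2],
            }
            for c in clusters
        ],
        columns=["cluster_id", "n_voxels", "peak_t", "x_mm", "y_mm", "z_mm"],
    )


def overlay_significance_maps(masks: dict[str, BinaryMask]) -> tuple[np.ndarray, dict[str, int]]:
    """Combine labeled significance masks into one bit-coded overlay volume.

    Each input mask gets a bit; a voxel's integer value is the bit-set of
    the masks containing it, so overlaps between contrasts are explicit.
    """
    if not masks:
        raise DomainError("no masks to overlay")
    items = list(masks.items())
    grid = items[0][1].grid
    out = np.zeros(grid.shape, dtype=np.int64)
    bits: dict[str, int] = {}
    for i, (name, mask) in enumerate(items):
        if mask.grid != grid:
            raise GridError(f"mask {name!r} is on a different grid")
        bits[name] = 1 << i
        out[mask.membership] |= 1 << i
    return out, bits
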