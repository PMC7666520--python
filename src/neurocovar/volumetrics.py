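"""Group statistics on subcortical volumes and regional WMH volumes.

Subcortical gray-matter volumes (bilateral sums, cm³) are compared across
diagnostic groups with an ordinary linear model adjusting for age, sex,
scanner field strength and total intracranial volume; pairwise group
contrasts are Bonferroni-corrected over the full family (structures x
pairs). Regional white-matter-hyperintensity volumes are strictly
positive and right-skewed, so group effects are modelled with a gamma GLM
with log link (multiplicative group factors); following the source
convention, no multiplicity correction is applied there because the
regional outcomes are strongly correlated.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import CompletenessError, FitError, NormalizationError

__all__ = [
    "SUBCORTICAL_STRUCTURES",
    "WMH_REGIONS",
    "GroupComparisonResult",
    "subcortical_group_comparison",
    "wmh_normalize_to_controls",
    "wmh_group_comparison",
    "results_to_frame",
]

SUBCORTICAL_STRUCTURES = (
    "amygdala",
    "nucleus_accumbens",
    "caudate",
    "putamen",
    "globus_pallidus",
    "hippocampus",
    "thalamus",
)

COVARIATES = ("age", "sex", "field_strength_t", "icv_cm3")


def wmh_region_names() -> list[str]:
    """lobe_side_layerN regions plus the basal-ganglia/infratentorial pool.

    Layers run 1 (periventricular) to 4 (juxtacortical)."""
    names = [
        f"{lobe}_{side}_layer{layer}"
        for lobe in ("frontal", "parietal", "temporal", "occipital")
        for side in ("left", "right")
        for layer in (1, 2, 3, 4)
    ]
    names.append("bgit")
    return names


WMH_REGIONS = tuple(wmh_region_names())


@dataclass
class GroupComparisonResult:
    measure: str
    pair: tuple[str, str]
    adjusted_effect: float
    p_raw: float
    p_adjusted: float
    family_m: int

    @property
    def significant(self) -> bool:
        return self.p_adjusted < 0.05


def _check_columns(table: pd.DataFrame, cols, what: str) -> None:
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise CompletenessError(f"{what} is missing columns {missing}")


def _merged(table: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    _check_columns(cohort, ("subject_id", "group") + COVARIATES, "cohort table")
    merged = table.merge(cohort, on="subject_id", how="inner")
    if len(merged) < len(table):
        raise CompletenessError("some measured subjects are absent from the cohort table")
    return merged


def _design(merged: pd.DataFrame, groups: list[str]) -> tuple[np.ndarray, list[str]]:
    cols = [(merged["group"] == g).to_numpy(float) for g in groups]
    labels = [f"group[{g}]" for g in groups]
    for cov in COVARIATES:
        v = merged[cov].to_numpy(float)
        cols.append(v - v.mean())
        labels.append(cov)
    return np.column_stack(cols), labels


def subcortical_group_comparison(
    table: pd.DataFrame,
    cohort: pd.DataFrame,
    structures=SUBCORTICAL_STRUCTURES,
) -> list[GroupComparisonResult]:
    """OLS per structure with covariates; Bonferroni over structures x pairs."""
    cols = [f"{s}_cm3" for s in structures]
    _check_columns(table, ["subject_id"] + cols, "subcortical volume table")
    merged = _merged(table, cohort)
    groups = sorted(merged["group"].unique())
    if len(groups) < 2:
        raise CompletenessError("need at least two groups")
    pairs = list(combinations(groups, 2))
    family_m = len(structures) * len(pairs)
    X, labels = _design(merged, groups)
    results = []
    for s, col in zip(structures, cols):
        y = merged[col].to_numpy(float)
        fit = sm.OLS(y, X).fit()
        for a, b in pairs:
            c = np.zeros(X.shape[1])
            c[labels.index(f"group[{a}]")] = 1.0
            c[labels.index(f"group[{b}]")] = -1.0
            tt = fit.t_test(c)
            p_raw = float(tt.pvalue)
            results.append(
                GroupComparisonResult(
                    measure=s,
                    pair=(a, b),
                    adjusted_effect=float(tt.effect[0]),
                    p_raw=p_raw,
                    p_adjusted=min(1.0, family_m * p_raw),
                    family_m=family_m,
                )
            )
    return results


def wmh_normalize_to_controls(
    table: pd.DataFrame,
    cn_subjects: list[str],
    regions=WMH_REGIONS,
) -> pd.DataFrame:
    """Divide each regional WMH volume by the control-group mean for that
    region (multiplicative-factor convention: CN regional means become 1)."""
    _check_columns(table, ["subject_id"] + list(regions), "WMH table")
    cn = table[table["subject_id"].isin(cn_subjects)]
    if cn.empty:
        raise NormalizationError("control subject list matches no rows")
    out = table.copy()
    for r in regions:
        mean = float(cn[r].mean())
        if mean <= 0:
            raise NormalizationError(f"control mean for region {r!r} is not positive")
        out[r] = out[r] / mean
    return out


def wmh_group_comparison(
    table: pd.DataFrame,
    cohort: pd.DataFrame,
    regions=WMH_REGIONS,
    zero_offset: str | float = "auto",
) -> list[GroupComparisonResult]:
    """Gamma GLM (log link) per region; pairwise Wald contrasts, uncorrected.

    Exact zeros are shifted by half the smallest positive observed value
    in that region (gamma support excludes 0); set `zero_offset` to a
    number to override, or 0 to forbid zeros. Dispersion is the default
    Pearson chi²/df estimate.
    """
    _check_columns(table, ["subject_id"] + list(regions), "WMH table")
    merged = _merged(table, cohort)
    groups = sorted(merged["group"].unique())
    pairs = list(combinations(groups, 2))
    X, labels = _design(merged, groups)
    results = []
    for r in regions:
        y = merged[r].to_numpy(float).copy()
        if (y < 0).any():
            raise FitError(f"negative WMH volume in region {r!r}")
        if (y == 0).any():
            if zero_offset == "auto":
                positive = y[y > 0]
                if positive.size == 0:
                    raise FitError(f"region {r!r} is identically zero")
                y = y + positive.min() / 2.0
            elif zero_offset:
                y = y + float(zero_offset)
            else:
                raise FitError(f"region {r!r} contains zeros and no offset is allowed")
        try:
            fit = sm.GLM(
                y, X, family=sm.families.Gamma(link=sm.families.links.Log())
            ).fit()
        except Exception as exc:
            raise FitError(f"gamma GLM failed to converge for region {r!r}: {exc}") from exc
        if not np.all(np.isfinite(fit.params)):
            raise FitError(f"gamma GLM produced non-finite estimates for region {r!r}")
        for a, b in pairs:
            c = np.zeros(X.shape[1])
            c[labels.index(f"group[{a}]")] = 1.0
            c[labels.index(f"group[{b}]")] = -1.0
            tt = fit.t_test(c)
            p_raw = float(tt.pvalue)
            results.append(
                GroupComparisonResult(
                    measure=r,
                    pair=(a, b),
                    adjusted_effect=float(tt.effect[0]),  # log ratio of group means
                    p_raw=p_raw,
                    p_adjusted=p_raw,  # deliberately uncorrected
                    family_m=1,
                )
            )
    return results


def results_to_frame(results: list[GroupComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "measure": r.measure,
                "pair": f"{r.pair[0]}:{r.pair[1]}",
                "effect": r.adjusted_effect,
                "p_raw": r.p_raw,
                "p_adjusted": r.p_adjusted,
                "family_m": r.family_m,
                "significant": r.significant,
            }
            for r in results
        ]
    )
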