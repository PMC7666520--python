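"""Reference-region normalization (SUVr), ROI extraction, and cohort tables.

FDG uptake images are normalized to the mean activity within a reference
region (the pons, whose glucose metabolism is relatively preserved in AD),
yielding standardized uptake value ratio (SUVr) maps whose reference-region
mean is exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    CompletenessError,
    DomainError,
    EmptyROIError,
    FormatError,
    GridError,
    NormalizationError,
)
from .volume import BinaryMask, ScalarVolume, read_volume

GROUPS = ("bvAD", "tAD", "bvFTD", "CN")

COHORT_COLUMNS = ["subject_id", "group", "age", "sex", "field_strength_t", "icv_cm3"]

MODALITIES = ("fdg_suvr", "gm_density")


@dataclass
class SubjectScan:
    """One subject's volume in one modality."""

    subject_id: str
    modality: str
    volume: ScalarVolume

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise DomainError(f"unknown modality {self.modality!r}; expected {MODALITIES}")


def compute_suvr(uptake: ScalarVolume, reference: BinaryMask) -> ScalarVolume:
    """Divide every voxel by the mean uptake within the reference mask."""
    if uptake.grid != reference.grid:
        raise GridError("uptake volume and reference mask are on different grids")
    reference.require_nonempty("reference region")
    ref_mean = float(uptake.values[reference.membership].mean())
    if not np.isfinite(ref_mean) or ref_mean <= 0:
        raise NormalizationError(
            f"reference-region mean must be positive, got {ref_mean}"
        )
    return ScalarVolume(uptake.grid, uptake.values / ref_mean)


def extract_roi_mean(
    volume: ScalarVolume,
    roi: BinaryMask,
    restrict: BinaryMask | None = None,
) -> float:
    """Mean value over roi ∩ restrict (restrict optional, e.g. a GM mask)."""
    if volume.grid != roi.grid:
        raise GridError("volume and ROI are on different grids")
    member = roi.membership
    if restrict is not None:
        if restrict.grid != roi.grid:
            raise GridError("restrict mask is on a different grid")
        member = member & restrict.membership
    if not member.any():
        raise EmptyROIError("ROI ∩ restriction mask is empty")
    return float(volume.values[member].mean())


def compute_icv(gm_volume: float, wm_volume: float, csf_volume: float) -> float:
    """Intracranial volume = gray matter + white matter + CSF (cm³)."""
    parts = (gm_volume, wm_volume, csf_volume)
    for v in parts:
        if v < 0:
            raise DomainError(f"tissue volumes must be >= 0, got {parts}")
    return float(sum(parts))


# --------------------------------------------------------------------------
# Cohort table


def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a cohort table; returns a normalized copy.

    Required columns: subject_id, group, age, sex, field_strength_t, icv_cm3.
    """
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"cohort table is missing columns {missing}")
    out = table.copy()
    out["subject_id"] = out["subject_id"].astype(str)
    if out["subject_id"].duplicated().any():
        dupes = out.loc[out["subject_id"].duplicated(), "subject_id"].tolist()
        raise FormatError(f"duplicate subject_ids: {dupes}")
    unknown = set(out["group"]) - set(GROUPS)
    if unknown:
        raise FormatError(f"unknown group labels {sorted(unknown)}; expected {GROUPS}")
    if (out["age"] <= 0).any() or (out["icv_cm3"] <= 0).any():
        raise DomainError("age and icv_cm3 must be positive")
    if not out["sex"].isin([0, 1]).all():
        raise DomainError("sex must be coded 0/1")
    if not out["field_strength_t"].isin([1.5, 3.0]).all():
        raise DomainError("field_strength_t must be 1.5 or 3")
    return out


def read_cohort(path) -> pd.DataFrame:
    return validate_cohort(pd.read_csv(path))


def load_scans(manifest: pd.DataFrame, modality: str = "fdg_suvr") -> dict[str, ScalarVolume]:
    """Load per-subject volumes from a manifest with columns
    subject_id, modality, path. All volumes must share a grid."""
    need = {"subject_id", "modality", "path"}
    if not need.issubset(manifest.columns):
        raise FormatError(f"manifest needs columns {sorted(need)}")
    sub = manifest[manifest["modality"] == modality]
    scans: dict[str, ScalarVolume] = {}
    grid = None
    for row in sub.itertuples():
        vol = read_volume(row.path)
        if grid is None:
            grid = vol.grid
        elif vol.grid != grid:
            raise GridError(f"volume for subject {row.subject_id} is on a different grid")
        scans[str(row.subject_id)] = vol
    return scans


def stack_group(
    scans: dict[str, ScalarVolume],
    cohort: pd.DataFrame,
    groups: list[str] | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Stack volumes into an (n_subjects, n_voxels) matrix in cohort order.

    Returns the data matrix and the matching cohort rows. Raises if any
    requested subject lacks a scan.
    """
    rows = cohort if groups is None else cohort[cohort["group"].isin(groups)]
    missing = [s for s in rows["subject_id"] if s not in scans]
    if missing:
        raise CompletenessError(f"missing volumes for subjects {missing}")
    mats = [scans[s].values.ravel() for s in rows["subject_id"]]
    return np.vstack(mats), rows.reset_index(drop=True)
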