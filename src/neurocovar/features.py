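"""Subject-level scalar features for discriminating dementia variants.

Two feature families come off the images: within/outside-network ratios
(mean signal inside a functional network template divided by the mean
signal in the rest of the analysis mask) for both FDG-SUVr and gray-matter
maps, and mean signal within disease-signature ROIs. Tabular features
(amygdala volume, lobar WMH burdens) are merged in from the volumetric
tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectivity import NetworkTemplate
from .errors import CompletenessError, PartitionError, RatioError
from .suvr import extract_roi_mean
from .volume import BinaryMask, ScalarVolume

__all__ = [
    "SignatureROI",
    "network_ratio",
    "signature_roi_mean",
    "lobar_wmh_burden",
    "assemble_feature_table",
]

SIGNATURE_ROI_NAMES = ("AD_temporoparietal", "AD_parietal", "FTD_signature")

WMH_LOBES = ("frontal", "parietal", "temporal", "occipital")


@dataclass
class SignatureROI:
    """A disease-signature region (e.g. AD temporoparietal cortex)."""

    name: str
    mask: BinaryMask

    def __post_init__(self) -> None:
        self.mask.require_nonempty(f"signature ROI {self.name!r}")


def network_ratio(
    subject_map: ScalarVolume,
    template: NetworkTemplate,
    analysis_mask: BinaryMask,
) -> float:
    """mean(map inside template ∩ mask) / mean(map over mask \\ template)."""
    inside = template.mask.membership & analysis_mask.membership
    outside = analysis_mask.membership & ~template.mask.membership
    if not inside.any() or not outside.any():
        raise PartitionError(
            f"template {template.name!r} does not partition the analysis mask"
        )
    denom = float(subject_map.values[outside].mean())
    if denom == 0:
        raise RatioError(f"outside-template mean is zero for {template.name!r}")
    return float(subject_map.values[inside].mean()) / denom


def signature_roi_mean(subject_map: ScalarVolume, roi: SignatureROI) -> float:
    """Mean map value over the signature ROI."""
    return extract_roi_mean(subject_map, roi.mask)


def lobar_wmh_burden(
    wmh_table: pd.DataFrame,
    lobe: str,
    layer_weights: np.ndarray | None = None,
) -> pd.Series:
    """Per-subject WMH burden for one lobe: weighted sum over sides and
    the four concentric layers (default weights uniform)."""
    cols = [
        c
        for c in wmh_table.columns
        if c.startswith(f"{lobe}_") and c.split("_")[-1].startswith("layer")
    ]
    if not cols:
        raise CompletenessError(f"no WMH columns found for lobe {lobe!r}")
    w = np.ones(4) if layer_weights is None else np.asarray(layer_weights, dtype=float)
    weights = {f"layer{i + 1}": w[i] for i in range(4)}
    out = pd.Series(0.0, index=wmh_table.index)
    for c in cols:
        out = out + wmh_table[c] * weights[c.split("_")[-1]]
    return out


def assemble_feature_table(
    cohort: pd.DataFrame,
    maps: dict[str, dict[str, ScalarVolume]],
    templates: dict[str, NetworkTemplate],
    rois: dict[str, SignatureROI],
    analysis_mask: BinaryMask,
    subcortical: pd.DataFrame | None = None,
    wmh: pd.DataFrame | None = None,
    wmh_layer_weights: np.ndarray | None = None,
) -> pd.DataFrame:
    """One row per subject, deterministic column order.

    maps: modality -> subject_id -> volume (modalities 'fdg'/'mri' etc).
    Features: '{modality}_{network}_ratio', '{modality}_{roi}',
    'amygdala_cm3' (from the subcortical table), 'wmh_{lobe}' burdens.
    Subjects missing a required volume raise a completeness error.
    """
    rows = []
    for rec in cohort.itertuples():
        row: dict[str, object] = {"subject_id": rec.subject_id, "group": rec.group}
        missing = [m for m, d in maps.items() if rec.subject_id not in d]
        if missing:
            raise CompletenessError(
                f"subject {rec.subject_id} lacks volumes for modalities {missing}"
            )
        for modality, d in maps.items():
            vol = d[rec.subject_id]
            for net, tpl in templates.items():
                row[f"{modality}_{net}_ratio"] = network_ratio(vol, tpl, analysis_mask)
            for roi_name, roi in rois.items():
                row[f"{modality}_{roi_name}"] = signature_roi_mean(vol, roi)
        rows.append(row)
    table = pd.DataFrame(rows)
    if subcortical is not None:
        table = table.merge(
            subcortical[["subject_id", "amygdala_cm3"]], on="subject_id", how="left"
        )
        if table["amygdala_cm3"].isna().any():
            bad = table.loc[table["amygdala_cm3"].isna(), "subject_id"].tolist()
            raise CompletenessError(f"subjects missing subcortical volumes: {bad}")
    if wmh is not None:
        wmh = wmh.set_index("subject_id")
        for lobe in WMH_LOBES:
            burden = lobar_wmh_burden(wmh, lobe, wmh_layer_weights)
            table[f"wmh_{lobe}"] = table["subject_id"].map(burden)
        if table[[f"wmh_{lo}" for lo in WMH_LOBES]].isna().any().any():
            raise CompletenessError("subjects missing WMH rows")
    return table.sort_values("subject_id", ignore_index=True)
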