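"""Configuration-driven orchestration of the analysis stages.

`run_pipeline` executes the enabled stages in dependency order on a
synthetic cohort (simulate → suvr → contrast → connectivity → features →
discriminate; volumetrics independent), writes stage outputs under the
configured output directory, and emits a machine-readable JSON report
(stage, inputs hash, outputs, elapsed seconds). A single rng_seed fans
out deterministically to per-stage child seeds, so a rerun on an
identical configuration reproduces every number.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

from . import connectivity as conn
from . import discrimination as disc
from . import features as feat
from . import glm
from . import simulate as sim
from . import suvr as suvr_mod
from . import volumetrics as volm
from .errors import ConfigurationError
from .volume import gaussian_smooth, write_mask, write_volume

STAGES = (
    "simulate",
    "suvr",
    "contrast",
    "connectivity",
    "features",
    "discriminate",
    "volumetrics",
)

PATIENT_GROUPS = ("bvAD", "tAD", "bvFTD")


@dataclass
class RunConfig:
    """Everything a pipeline run depends on."""

    output_dir: str = "neurocovar_run"
    rng_seed: int = 0
    shape: tuple[int, int, int] = (32, 38, 32)
    spacing_mm: float = 4.0
    stages: tuple[str, ...] = STAGES
    smoothing_fwhm_mm: float = 12.0
    alpha: float = 0.05
    correction: str = "fwe_permutation"
    extent_k: int = 50
    n_perm: int = 500
    patient_alpha: float = 0.001  # patient-vs-patient contrasts, uncorrected
    roc_pairs: tuple[tuple[str, str], ...] = (("bvAD", "tAD"), ("bvAD", "bvFTD"))
    top_k: int = 5

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages {sorted(unknown)}")

    def child_seed(self, stage: str) -> int:
        payload = f"{self.rng_seed}:{stage}".encode()
        return int.from_bytes(hashlib.sha256(payload).digest()[:4], "big") % 2**31

    def inputs_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages; returns (and writes) the run report.

    A stage failure aborts the run with that stage's error; the report is
    still written, with the failed stage marked and earlier outputs
    flagged as partial.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "rng_seed": config.rng_seed,
        "inputs_hash": config.inputs_hash(),
        "stages": [],
    }
    state: dict = {}
    try:
        _run_stages(config, out, report, state)
    except Exception as exc:
        done = {s["stage"] for s in report["stages"]}
        failed = next((s for s in config.stages if s not in done), "?")
        report["stages"].append(
            {"stage": failed, "status": "failed", "error": str(exc)}
        )
        report["partial"] = True
        (out / "run_report.json").write_text(json.dumps(report, indent=2))
        raise
    report_path = out / "run_report.json"
    report_path.write_text(json.dumps(report, indent=2))
    return report


def _run_stages(config: RunConfig, out: Path, report: dict, state: dict) -> None:

    def record(stage: str, outputs: list[str], t0: float) -> None:
        report["stages"].append(
            {
                "stage": stage,
                "status": "ok",
                "outputs": outputs,
                "elapsed_s": round(time.time() - t0, 3),
            }
        )

    # ---- simulate (data source for every imaging stage)
    if "simulate" in config.stages:
        t0 = time.time()
        sim_cfg = sim.SimulationConfig(
            shape=config.shape,
            spacing_mm=config.spacing_mm,
            rng_seed=config.child_seed("simulate"),
        )
        cohort, scans, masks, templates, rois, _ = sim.simulate_fdg_cohort(sim_cfg)
        subcortical, wmh = sim.simulate_volume_tables(sim_cfg, cohort)
        state.update(
            cohort=cohort, scans=scans, masks=masks, templates=templates,
            rois=rois, subcortical=subcortical, wmh=wmh,
        )
        cohort_path = out / "cohort.csv"
        cohort.to_csv(cohort_path, index=False)
        subcortical.to_csv(out / "subcortical.csv", index=False)
        wmh.to_csv(out / "wmh.csv", index=False)
        record("simulate", ["cohort.csv", "subcortical.csv", "wmh.csv"], t0)

    # ---- suvr: pons normalization + smoothing
    if "suvr" in config.stages:
        _require(state, "scans", "suvr")
        t0 = time.time()
        suvr_scans = {}
        for sid, vol in state["scans"].items():
            norm = suvr_mod.compute_suvr(vol, state["masks"]["pons"])
            if config.smoothing_fwhm_mm > 0:
                norm = gaussian_smooth(norm, config.smoothing_fwhm_mm)
            suvr_scans[sid] = norm
        state["suvr"] = suvr_scans
        record("suvr", [], t0)

    # ---- voxelwise contrasts
    if "contrast" in config.stages:
        _require(state, "suvr", "contrast")
        t0 = time.time()
        outputs = []
        cohort = state["cohort"]
        brain = state["masks"]["brain"]
        all_groups = ["bvAD", "tAD", "bvFTD", "CN"]
        data, rows = suvr_mod.stack_group(state["suvr"], cohort, all_groups)
        design, labels = glm.build_design_matrix(rows, all_groups)
        fit = glm.fit_voxelwise_glm(data, design, brain, column_labels=labels)
        sig_masks = {}
        for g in PATIENT_GROUPS:
            # hypometabolism direction: CN - patient > 0
            c = glm.pairwise_contrast(labels, "CN", g)
            tmap = glm.group_contrast_tmap(fit, c, label=f"CN>{g}")
            if config.correction == "fwe_permutation":
                null = glm.build_permutation_null(
                    data, design, c, brain,
                    n_perm=config.n_perm,
                    rng_seed=config.child_seed(f"perm:{g}"),
                )
            else:
                null = None
            spec = glm.ThresholdSpec(
                alpha=config.alpha, correction=config.correction,
                extent_k=config.extent_k, sidedness="one_sided",
            )
            mask, clusters = glm.threshold_tmap(tmap, spec, null_max_t=null,
                                                analysis_mask=brain)
            sig_masks[g] = mask
            write_volume(tmap_to_volume(tmap), out / f"tmap_CN_gt_{g}.nii.gz")
            write_mask(mask, out / f"sig_CN_gt_{g}.nii.gz")
            glm.clusters_to_frame(clusters).to_csv(
                out / f"clusters_CN_gt_{g}.csv", index=False
            )
            outputs += [f"tmap_CN_gt_{g}.nii.gz", f"sig_CN_gt_{g}.nii.gz",
                        f"clusters_CN_gt_{g}.csv"]
        overlay, bits = glm.overlay_significance_maps(sig_masks)
        from .volume import ScalarVolume

        write_volume(ScalarVolume(brain.grid, overlay.astype(float)),
                     out / "overlay_patients_vs_CN.nii.gz")
        (out / "overlay_bits.json").write_text(json.dumps(bits))
        outputs += ["overlay_patients_vs_CN.nii.gz", "overlay_bits.json"]
        state["sig_masks"] = sig_masks
        record("contrast", outputs, t0)

    # ---- metabolic connectivity
    if "connectivity" in config.stages:
        _require(state, "suvr", "connectivity")
        t0 = time.time()
        gm = state["masks"]["gm"]
        covmaps = {}
        for g in ("bvAD", "tAD", "bvFTD", "CN"):
            rows = state["cohort"][state["cohort"]["group"] == g]
            for seed_name, seed in conn.CANONICAL_SEEDS.items():
                covmaps[(g, seed_name)] = conn.irca_covariance_map(
                    state["suvr"], rows, seed, gm
                )
        gof = conn.gof_profile(covmaps, state["templates"], gm)
        gof.to_csv(out / "gof_profile.csv", index=False)
        inter = conn.interaction_analysis(
            state["suvr"], state["cohort"], ("bvAD", "tAD"),
            conn.CANONICAL_SEEDS["PCC"], gm,
        )
        inter.clusters_p001.to_csv(out / "interaction_PCC_bvAD_tAD_p001.csv", index=False)
        inter.clusters_p05.to_csv(out / "interaction_PCC_bvAD_tAD_p05.csv", index=False)
        state["gof"] = gof
        record("connectivity", ["gof_profile.csv",
                                "interaction_PCC_bvAD_tAD_p001.csv",
                                "interaction_PCC_bvAD_tAD_p05.csv"], t0)

    # ---- subject-level features
    if "features" in config.stages:
        _require(state, "suvr", "features")
        t0 = time.time()
        table = feat.assemble_feature_table(
            state["cohort"],
            {"fdg": state["suvr"]},
            state["templates"],
            state["rois"],
            state["masks"]["gm"],
            subcortical=state["subcortical"],
            wmh=state["wmh"],
        )
        table.to_csv(out / "features.csv", index=False)
        state["features"] = table
        record("features", ["features.csv"], t0)

    # ---- ROC discrimination
    if "discriminate" in config.stages:
        _require(state, "features", "discriminate")
        t0 = time.time()
        outputs = []
        for pair in config.roc_pairs:
            ranked = disc.rank_discriminators(state["features"], pair, top_k=config.top_k)
            name = f"roc_{pair[0]}_vs_{pair[1]}.csv"
            disc.roc_results_to_frame(ranked).to_csv(out / name, index=False)
            outputs.append(name)
        record("discriminate", outputs, t0)

    # ---- volumetric statistics (independent branch)
    if "volumetrics" in config.stages:
        _require(state, "subcortical", "volumetrics")
        t0 = time.time()
        sub_res = volm.subcortical_group_comparison(state["subcortical"], state["cohort"])
        volm.results_to_frame(sub_res).to_csv(out / "subcortical_stats.csv", index=False)
        cn_ids = list(
            state["cohort"].loc[state["cohort"]["group"] == "CN", "subject_id"]
        )
        wmh_norm = volm.wmh_normalize_to_controls(state["wmh"], cn_ids)
        wmh_norm.to_csv(out / "wmh_normalized.csv", index=False)
        wmh_res = volm.wmh_group_comparison(state["wmh"], state["cohort"])
        volm.results_to_frame(wmh_res).to_csv(out / "wmh_stats.csv", index=False)
        record("volumetrics",
               ["subcortical_stats.csv", "wmh_normalized.csv", "wmh_stats.csv"], t0)


def _require(state: dict, key: str, stage: str) -> None:
    if key not in state:
        raise ConfigurationError(
            f"stage {stage!r} requires {key!r}; enable the producing stage first"
        )


def tmap_to_volume(tmap: glm.TMap):
    from .volume import ScalarVolume

    return ScalarVolume(tmap.grid, tmap.t_values)
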