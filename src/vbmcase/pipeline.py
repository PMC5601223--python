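"""End-to-end orchestration: simulate -> segment -> maps -> stats -> evaluate.

A :class:`RunConfig` (schema-validated, unknown keys rejected) drives the
whole study: a phantom cohort is generated in a common template space, every
subject is segmented (single-channel T1 for the T1 stream, multispectral
T1+FLAIR for the FLAIR stream), the four feature maps are built in template
space via the known deformation, each patient (and each control, leave-one-
out) is tested against the control group, and the findings are tallied into
specificity/sensitivity tables.

All stages are deterministic given (config, master_seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import phantom as ph
from .evaluation import classify_clusters, loo_specificity, map_colocalization, proportion_with_ci
from .feature_maps import FeatureMap, brain_mask, gmc_map, gmv_map, junction_map, nfsi_map
from .segmentation import TissueSegmentation, segment_em, total_intracranial_volume
from .single_case import DesignSpec, single_case_glm, threshold_map
from .volume import Volume

log = logging.getLogger("vbmcase")

MAP_KINDS = ("GMC", "GMV", "JM", "NFSI")


# ----------------------------------------------------------------- config schema
class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CohortSection(_Strict):
    n_controls: int = 10
    n_patients: int = 2
    shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size_mm: float = 1.5
    age_range: tuple[float, float] = (19.0, 64.0)
    deformation_amplitude_mm: float = 2.0
    deformation_smoothness_mm: float = 8.0
    bias_order: int = 2
    bias_amplitude: float = 0.05
    noise_sd_t1: float = 0.02
    noise_sd_flair: float = 0.02
    lesion_radius_mm: tuple[float, float] = (6.0, 9.0)
    lesion_junction_blur: tuple[float, float] = (0.8, 1.0)
    lesion_flair_delta: tuple[float, float] = (4.0, 6.0)
    lesion_thickness_factor: tuple[float, float] = (1.0, 1.0)


class SegmentationSection(_Strict):
    bias_order: int = 3
    tol: float = 1e-6
    max_iter: int = 60


class MapsSection(_Strict):
    fwhm_mm: float = 8.0
    mask_threshold: float = 0.5
    nfsi_form: Literal["zscore", "ratio"] = "zscore"
    junction_band_sds: float = 0.5


class StatsSection(_Strict):
    uncorrected_alpha: float = 1e-4
    fwe_alpha: float = 0.05
    fwe_mode: Literal["fwe_bonferroni", "fwe_rft"] = "fwe_bonferroni"
    min_cluster: int = 0
    connectivity: Literal[6, 18, 26] = 26
    per_side_alpha: bool = True

    @model_validator(mode="after")
    def _check(self) -> "StatsSection":
        if not (0 < self.uncorrected_alpha < 1 and 0 < self.fwe_alpha < 1):
            raise ValueError("alphas must lie in (0, 1)")
        return self


class EvaluationSection(_Strict):
    ci_method: Literal["wilson", "clopper_pearson"] = "wilson"
    concordance_rule: Literal["any_voxel", "peak"] = "any_voxel"


class RunConfig(_Strict):
    cohort: CohortSection = Field(default_factory=CohortSection)
    segmentation: SegmentationSection = Field(default_factory=SegmentationSection)
    maps: MapsSection = Field(default_factory=MapsSection)
    stats: StatsSection = Field(default_factory=StatsSection)
    evaluation: EvaluationSection = Field(default_factory=EvaluationSection)
    master_seed: int = 0
    out_dir: str = "results/run"
    write_volumes: bool = False

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.maps.fwhm_mm <= 0:
            raise ValueError("smoothing FWHM must be positive")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.model_validate(payload)


def cohort_config(cfg: CohortSection) -> ph.CohortConfig:
    return ph.CohortConfig(
        n_controls=cfg.n_controls,
        n_patients=cfg.n_patients,
        age_range=cfg.age_range,
        shape=cfg.shape,
        voxel_size_mm=cfg.voxel_size_mm,
        variability=ph.VariabilitySpec(
            deformation_amplitude_mm=cfg.deformation_amplitude_mm,
            deformation_smoothness_mm=cfg.deformation_smoothness_mm,
            bias_order=cfg.bias_order,
            bias_amplitude=cfg.bias_amplitude,
            noise_sd_t1=cfg.noise_sd_t1,
            noise_sd_flair=cfg.noise_sd_flair,
        ),
        lesion_radius_mm=cfg.lesion_radius_mm,
        lesion_junction_blur=cfg.lesion_junction_blur,
        lesion_flair_delta=cfg.lesion_flair_delta,
        lesion_thickness_factor=cfg.lesion_thickness_factor,
    )


# ----------------------------------------------------------------- per-subject
@dataclass
class SubjectFeatures:
    record: ph.SubjectRecord
    maps: dict[str, FeatureMap]
    mask: Volume
    tiv_ml: float
    lesion_mask_template: Volume | None = None


def _normalized_segmentation(seg: TissueSegmentation, deformation: ph.DeformationField) -> TissueSegmentation:
    """Carry a native-space segmentation into template space via the known warp.

    Class statistics are intensity quantities and are warp-invariant; the
    probability and bias-corrected maps are resampled.
    """
    probs = {k: ph.normalize_to_template(v, deformation) for k, v in seg.probabilities.items()}
    return TissueSegmentation(
        probabilities=probs,
        bias_fields=seg.bias_fields,
        bias_corrected=[ph.normalize_to_template(v, deformation) for v in seg.bias_corrected],
        class_means=seg.class_means,
        class_sds=seg.class_sds,
        mixing_weights=seg.mixing_weights,
        convergence=seg.convergence,
        converged=seg.converged,
    )


def process_subject(
    subj: ph.SubjectData,
    seg_cfg: SegmentationSection | None = None,
    maps_cfg: MapsSection | None = None,
    kinds: tuple[str, ...] = MAP_KINDS,
) -> SubjectFeatures:
    """Segment one subject and build its feature maps in template space."""
    seg_cfg = seg_cfg or SegmentationSection()
    maps_cfg = maps_cfg or MapsSection()

    seg_t1 = segment_em(subj.t1, bias_order=seg_cfg.bias_order, tol=seg_cfg.tol,
                        max_iter=seg_cfg.max_iter)
    need_flair = "NFSI" in kinds
    seg_multi = (
        segment_em([subj.t1, subj.flair], bias_order=seg_cfg.bias_order,
                   tol=seg_cfg.tol, max_iter=seg_cfg.max_iter)
        if need_flair else None
    )
    tiv = total_intracranial_volume(seg_t1)

    seg_t1_norm = _normalized_segmentation(seg_t1, subj.deformation)
    mask = brain_mask(seg_t1_norm, threshold=maps_cfg.mask_threshold)

    fm: dict[str, FeatureMap] = {}
    if "GMC" in kinds:
        fm["GMC"] = gmc_map(seg_t1_norm, fwhm_mm=maps_cfg.fwhm_mm, mask=mask)
    if "GMV" in kinds:
        fm["GMV"] = gmv_map(seg_t1_norm, subj.deformation.jacobian_det,
                            fwhm_mm=maps_cfg.fwhm_mm, mask=mask)
    if "JM" in kinds:
        fm["JM"] = junction_map(seg_t1_norm.bias_corrected[0], seg_t1_norm,
                                fwhm_mm=maps_cfg.fwhm_mm, mask=mask,
                                band_sds=maps_cfg.junction_band_sds)
    if need_flair:
        seg_multi_norm = _normalized_segmentation(seg_multi, subj.deformation)
        fm["NFSI"] = nfsi_map(seg_multi_norm.bias_corrected[1], seg_multi_norm,
                              fwhm_mm=maps_cfg.fwhm_mm, mask=mask,
                              form=maps_cfg.nfsi_form)

    lesion_t = None
    if subj.lesion_mask is not None:
        warped = ph.normalize_to_template(subj.lesion_mask, subj.deformation, order=0)
        lesion_t = warped.like((warped.data > 0.5).astype(np.uint8))
    return SubjectFeatures(record=subj.record, maps=fm, mask=mask, tiv_ml=tiv,
                           lesion_mask_template=lesion_t)


def _covariates(features: list[SubjectFeatures], patient: SubjectFeatures, kind: str):
    """Age for every design; TIV only for the volumetric (GMC/GMV) analyses."""
    rows = [(f.record.age, f.tiv_ml) for f in features] + [(patient.record.age, patient.tiv_ml)]
    arr = np.asarray(rows, dtype=float)
    if kind in ("GMC", "GMV"):
        return arr, ("age", "tiv")
    return arr[:, :1], ("age",)


# ----------------------------------------------------------------- full study
def run_pipeline(config: RunConfig) -> dict:
    """Execute the whole study; returns the summary dict written to out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("generating cohort (%d controls, %d patients, seed %d)",
             config.cohort.n_controls, config.cohort.n_patients, config.master_seed)
    cohort = ph.generate_cohort(cohort_config(config.cohort), config.master_seed,
                                out_dir=out / "cohort" if config.write_volumes else None)
    cohort.metadata.to_csv(out / "subjects.tsv", sep="\t", index=False)

    features: list[SubjectFeatures] = []
    for subj in cohort.subjects:
        try:
            features.append(process_subject(subj, config.segmentation, config.maps))
        except Exception as err:  # pragma: no cover - error path
            raise RuntimeError(f"stage 'process_subject' failed for {subj.record.id}") from err
    controls = [f for f in features if f.record.group == "control"]
    patients = [f for f in features if f.record.group == "patient"]

    # common analysis mask: voxels inside every subject's brain mask
    common = np.all(np.stack([f.mask.data.astype(bool) for f in features]), axis=0)
    mask = features[0].mask.like(common.astype(np.uint8))

    thresholds = {
        "uncorrected": dict(mode="uncorrected", alpha=config.stats.uncorrected_alpha),
        "fwe": dict(mode=config.stats.fwe_mode, alpha=config.stats.fwe_alpha),
    }
    rows = []
    cluster_sets: dict[tuple[str, str, str], object] = {}
    for pat in patients:
        for kind in MAP_KINDS:
            cov, names = _covariates(controls, pat, kind)
            design = DesignSpec.for_kind(kind, covariates=cov, covariate_names=names)
            tmap = single_case_glm(pat.maps[kind].data, [c.maps[kind].data for c in controls],
                                   design=design, mask=mask)
            for tname, kw in thresholds.items():
                cs = threshold_map(tmap, min_cluster=config.stats.min_cluster,
                                   connectivity=config.stats.connectivity,
                                   per_side_alpha=config.stats.per_side_alpha, **kw)
                cluster_sets[(pat.record.id, kind, tname)] = cs
                row = {"id": pat.record.id, "map": kind, "threshold": tname,
                       "n_clusters": len(cs), "critical_t": cs.threshold["critical_t"]}
                if pat.lesion_mask_template is not None:
                    cc = classify_clusters(cs, pat.lesion_mask_template,
                                           subject_id=pat.record.id,
                                           rule=config.evaluation.concordance_rule)
                    row.update(concordant=cc.concordant, discordant=cc.discordant,
                               patient_concordant=cc.patient_concordant,
                               patient_discordant=cc.patient_discordant)
                rows.append(row)
    findings = pd.DataFrame(rows)
    findings.to_csv(out / "patient_findings.tsv", sep="\t", index=False)

    summary: dict = {"config": config.model_dump(), "n_controls": len(controls),
                     "n_patients": len(patients), "specificity": {}, "sensitivity": {},
                     "colocalization": {}}
    for kind in MAP_KINDS:
        cmaps = [c.maps[kind].data for c in controls]
        cov = np.asarray([(c.record.age, c.tiv_ml) for c in controls], dtype=float)
        cov = cov if kind in ("GMC", "GMV") else cov[:, :1]
        prop, flags = loo_specificity(cmaps, map_kind=kind, mask=mask, covariates=cov,
                                      mode=config.stats.fwe_mode, alpha=config.stats.fwe_alpha,
                                      min_cluster=config.stats.min_cluster,
                                      connectivity=config.stats.connectivity,
                                      ci_method=config.evaluation.ci_method)
        summary["specificity"][kind] = {
            "estimate_pct": prop.estimate_pct, "ci_pct": [prop.ci_low_pct, prop.ci_high_pct],
            "false_positives": int(sum(flags)), "n": prop.n,
        }
        if patients and patients[0].lesion_mask_template is not None:
            sel = findings[(findings["map"] == kind) & (findings["threshold"] == "fwe")]
            hits = [bool(sel.loc[sel["id"] == p.record.id, "patient_concordant"].iloc[0])
                    for p in patients]
            prop_s = proportion_with_ci(sum(hits), len(hits), method=config.evaluation.ci_method)
            summary["sensitivity"][kind] = {
                "estimate_pct": prop_s.estimate_pct,
                "ci_pct": [prop_s.ci_low_pct, prop_s.ci_high_pct], "n": prop_s.n,
            }

    for pat in patients:
        sets = {kind: cluster_sets[(pat.record.id, kind, "fwe")] for kind in MAP_KINDS}
        coloc = map_colocalization(sets, shape=mask.shape, target_mask=pat.lesion_mask_template)
        summary["colocalization"][pat.record.id] = {
            f"{a}/{b}": v for (a, b), v in coloc.items() if v["overlap"]
        }

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    log.info("pipeline complete: %s", out / "summary.json")
    return summary
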