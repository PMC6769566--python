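"""End-to-end orchestration: simulate -> preprocess -> train -> validate.

The whole pipeline is a pure function of (input files, config, seed): two
runs with the same inputs produce byte-identical CSV/JSON outputs. A
frozen copy of the resolved configuration is written alongside every run.

On disk, a cohort is a directory of imzML/ibd pairs plus one ROI JSON per
specimen and a ``manifest.json`` tying specimens to patient ids and class
labels; ``run_simulate`` emits exactly that layout, so simulated and real
cohorts flow through the same code path.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from . import io as msi_io
from .classifier import CVResult, MalignancyModel, fit_lasso_logistic, save_model
from .preprocessing import ProcessingParams, align_peaks, peaks_from_processed
from .roi_features import (
    ROIGroup,
    adequacy_check,
    group_mean_observations,
    intra_patient_filter,
    inter_patient_filter,
    make_equivalent_groups,
    roi_mean_spectrum,
)
from .synthetic import GroundTruth, SyntheticConfig, simulate_cohort, simulate_validation_cohort
from .types import (
    CytologyClass,
    FeatureMatrix,
    InadequateROIError,
    MSIDataset,
    ROIAnnotation,
)
from .validation import (
    Mode,
    QuartileSummary,
    TriageDecision,
    cohort_report,
    score_specimen,
    summarize_quartiles,
    triage,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "TrainingResult",
    "run_simulate",
    "load_cohort",
    "run_training",
    "run_validation",
]


@dataclass
class PipelineConfig:
    """Single configuration object for a full run.

    Defaults reproduce the training-study design: 25% intra- and
    inter-patient prevalence filters, 5 equivalent groups per benign and 4
    per malignant patient, S/N >= 6 peak picking with a 0.0003 post-TIC
    intensity floor, and the observed 7%/28% third-quartile triage gap.
    """

    preprocessing: ProcessingParams = field(default_factory=ProcessingParams)
    intra_min_fraction: float = 0.25
    inter_min_fraction: float = 0.25
    inter_mode: str = "union"
    groups_benign: int = 5
    groups_malignant: int = 4
    cv_folds: int = 5
    seed: int = 0
    triage_low: float = 0.07
    triage_high: float = 0.28
    exclude_inadequate: bool = False
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        kwargs = dict(doc)
        if "preprocessing" in kwargs:
            kwargs["preprocessing"] = ProcessingParams(**kwargs["preprocessing"])
        if "synthetic" in kwargs:
            syn = dict(kwargs["synthetic"])
            if "panel" in syn:
                from .synthetic import PeakPanel

                panel = dict(syn["panel"])
                for key in ("shared_peaks", "benign_peaks", "malignant_peaks"):
                    if key in panel:
                        panel[key] = [tuple(p) for p in panel[key]]
                syn["panel"] = PeakPanel(**panel)
            for key in ("rois_per_patient_range", "pixels_per_roi_range"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            kwargs["synthetic"] = SyntheticConfig(**syn)
        return cls(**kwargs)

    def to_yaml(self, path: str) -> str:
        doc = dataclasses.asdict(self)
        doc["synthetic"]["scenario"] = self.synthetic.scenario.value
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)
        return path


@dataclass
class TrainingResult:
    """Everything the training stage produces."""

    model: MalignancyModel
    cv: CVResult
    feature_funnel: Dict[str, int]  # total -> filtered -> selected counts
    groups: List[ROIGroup]
    group_matrix: FeatureMatrix
    filtered_mz: List[float]
    training_summaries: Dict[str, QuartileSummary]
    training_decisions: Dict[str, TriageDecision]
    adequacy: Dict[str, Optional[bool]]


# ---------------------------------------------------------------------------
# cohort on disk
# ---------------------------------------------------------------------------

def run_simulate(config: PipelineConfig, out_dir: str,
                 validation: bool = False) -> Tuple[List[MSIDataset], List[ROIAnnotation], GroundTruth]:
    """Generate a cohort and write it in the on-disk layout.

    ``validation=True`` emits the validation-style cohort (new patients
    plus the three challenge specimens) instead of the training cohort.
    """
    os.makedirs(out_dir, exist_ok=True)
    if validation:
        datasets, rois, truth = simulate_validation_cohort(config.synthetic)
    else:
        datasets, rois, truth = simulate_cohort(config.synthetic)
    manifest = {}
    for ds in datasets:
        base = os.path.join(out_dir, ds.specimen_id)
        msi_io.write_imzml(ds, base + ".imzML")
        specimen_rois = [r for r in rois if r.specimen_id == ds.specimen_id]
        msi_io.write_roi_annotations(specimen_rois, base + ".rois.json")
        manifest[ds.specimen_id] = {
            "patient_id": ds.patient_id,
            "class": truth.specimen_class[ds.specimen_id],
            "imzml": ds.specimen_id + ".imzML",
            "rois": ds.specimen_id + ".rois.json",
        }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    truth_doc = {
        "specimen_class": truth.specimen_class,
        "discriminant_mz": [[mz, sign] for mz, sign in truth.discriminant_mz],
    }
    with open(os.path.join(out_dir, "ground_truth.json"), "w") as fh:
        json.dump(truth_doc, fh, indent=1, sort_keys=True)
        fh.write("\n")
    config.to_yaml(os.path.join(out_dir, "config.resolved.yaml"))
    return datasets, rois, truth


def load_cohort(cohort_dir: str) -> Tuple[List[MSIDataset], List[ROIAnnotation], Dict[str, str]]:
    """Read a manifest-described cohort directory back into memory."""
    with open(os.path.join(cohort_dir, "manifest.json")) as fh:
        manifest = json.load(fh)
    datasets, rois, labels = [], [], {}
    for sid in sorted(manifest):
        entry = manifest[sid]
        cls = {
            "benign": CytologyClass.THY2,
            "malignant": CytologyClass.THY5,
        }.get(entry.get("class", ""), CytologyClass.UNKNOWN)
        ds = msi_io.read_imzml(
            os.path.join(cohort_dir, entry["imzml"]),
            specimen_id=sid,
            patient_id=entry["patient_id"],
            cytology_class=cls,
        )
        datasets.append(ds)
        rois.extend(msi_io.read_roi_annotations(os.path.join(cohort_dir, entry["rois"])))
        if "class" in entry:
            labels[sid] = entry["class"]
    return datasets, rois, labels


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def run_training(
    config: PipelineConfig,
    datasets: Sequence[MSIDataset],
    rois: Sequence[ROIAnnotation],
    labels: Dict[str, str],
    out_dir: Optional[str] = None,
) -> TrainingResult:
    """Process -> ROI means -> groups -> prevalence filters -> Lasso fit.

    ``labels`` maps specimen_id to 'benign'/'malignant'; every training
    specimen must be labeled. Inadequate specimens are flagged (and
    excluded when ``config.exclude_inadequate``).
    """
    missing = [ds.specimen_id for ds in datasets if ds.specimen_id not in labels]
    if missing:
        raise ValueError(f"unlabeled training specimens: {missing}")
    params = config.preprocessing
    by_specimen: Dict[str, List[ROIAnnotation]] = {}
    for r in rois:
        by_specimen.setdefault(r.specimen_id, []).append(r)

    adequacy: Dict[str, Optional[bool]] = {}
    kept: List[MSIDataset] = []
    for ds in datasets:
        specimen_rois = by_specimen.get(ds.specimen_id, [])
        if not specimen_rois:
            raise ValueError(f"training specimen {ds.specimen_id} has no ROIs")
        ok = adequacy_check(specimen_rois)
        adequacy[ds.specimen_id] = ok
        if ok is False and config.exclude_inadequate:
            logger.warning("excluding inadequate specimen %s", ds.specimen_id)
            continue
        if ok is False:
            logger.warning("specimen %s fails adequacy; kept (flagged)", ds.specimen_id)
        kept.append(ds)

    # per-ROI mean profiles and peak lists
    roi_profiles, roi_peaklists, roi_patient, roi_ids = {}, [], [], []
    for ds in kept:
        for roi in sorted(by_specimen[ds.specimen_id], key=lambda r: r.roi_id):
            try:
                ms = roi_mean_spectrum(ds, roi, params)
            except InadequateROIError:
                logger.warning("skipping empty ROI %s", roi.roi_id)
                continue
            roi_profiles[roi.roi_id] = ms
            roi_peaklists.append(
                peaks_from_processed(ms.mz, ms.intensity, params, source=roi.roi_id)
            )
            roi_patient.append(ds.patient_id)
            roi_ids.append(roi.roi_id)

    grid, roi_fm = align_peaks(roi_peaklists, params.tolerance_ppm)
    roi_fm = FeatureMatrix(
        observation_ids=roi_ids,
        feature_mz=roi_fm.feature_mz,
        intensities=roi_fm.intensities,
        detected=roi_fm.detected,
        patient_of=roi_patient,
    )
    n_total = roi_fm.n_features

    # prevalence filters (detection-based)
    presence = intra_patient_filter(roi_fm, config.intra_min_fraction)
    benign_pat = sorted({ds.patient_id for ds in kept if labels[ds.specimen_id] == "benign"})
    malignant_pat = sorted({ds.patient_id for ds in kept if labels[ds.specimen_id] == "malignant"})
    filtered_mz = inter_patient_filter(
        presence, benign_pat, malignant_pat, config.inter_min_fraction, config.inter_mode
    )

    # equivalent groups and group-mean observations
    groups: List[ROIGroup] = []
    for ds in kept:
        usable = [r for r in by_specimen[ds.specimen_id] if r.roi_id in roi_profiles]
        n_groups = (
            config.groups_benign
            if labels[ds.specimen_id] == "benign"
            else config.groups_malignant
        )
        groups.extend(
            make_equivalent_groups(usable, n_groups, seed=config.seed, patient_id=ds.patient_id)
        )
    label_code = {
        ds.patient_id: (1 if labels[ds.specimen_id] == "malignant" else 0) for ds in kept
    }
    group_fm = group_mean_observations(groups, roi_profiles, grid, params, labels=label_code)
    group_fm = group_fm.subset_features(filtered_mz)

    model, cv = fit_lasso_logistic(
        group_fm, cv_folds=config.cv_folds, seed=config.seed, grid=grid
    )
    n_selected = len(model.coefficients)
    funnel = {
        "features_total": int(n_total),
        "features_after_filters": len(filtered_mz),
        "features_selected": int(n_selected),
    }

    # re-test the training specimens (the complete-overlap check);
    # ROI-mode probabilities from the already-computed ROI mean profiles
    from .validation import _score_profile

    training_summaries, training_decisions = {}, {}
    for ds in kept:
        probs = [
            _score_profile(model, roi_profiles[r.roi_id].mz,
                           roi_profiles[r.roi_id].intensity, params, r.roi_id)
            for r in by_specimen[ds.specimen_id]
            if r.roi_id in roi_profiles
        ]
        summary = summarize_quartiles(probs, Mode.ROI)
        training_summaries[ds.specimen_id] = summary
        training_decisions[ds.specimen_id] = triage(
            summary, ds.specimen_id, config.triage_low, config.triage_high
        )

    result = TrainingResult(
        model=model,
        cv=cv,
        feature_funnel=funnel,
        groups=groups,
        group_matrix=group_fm,
        filtered_mz=filtered_mz,
        training_summaries=training_summaries,
        training_decisions=training_decisions,
        adequacy=adequacy,
    )
    if out_dir:
        _write_training_outputs(config, result, out_dir)
    return result


def _write_training_outputs(config: PipelineConfig, result: TrainingResult, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    save_model(result.model, os.path.join(out_dir, "model.json"))
    doc = {
        "feature_funnel": result.feature_funnel,
        "adequacy": result.adequacy,
        "groups": {
            g.group_id: {"patient_id": g.patient_id, "roi_ids": g.roi_ids}
            for g in result.groups
        },
        "training_q3": {
            sid: round(s.q3, 6) for sid, s in sorted(result.training_summaries.items())
        },
        "training_calls": {
            sid: d.call.value for sid, d in sorted(result.training_decisions.items())
        },
    }
    with open(os.path.join(out_dir, "training_report.json"), "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")
    fm = result.group_matrix
    import pandas as pd

    df = pd.DataFrame(
        fm.intensities, index=fm.observation_ids,
        columns=[f"{mz:.2f}" for mz in fm.feature_mz],
    )
    df.index.name = "observation_id"
    df.to_csv(os.path.join(out_dir, "feature_matrix.csv"), float_format="%.8g")
    config.to_yaml(os.path.join(out_dir, "config.resolved.yaml"))


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def run_validation(
    config: PipelineConfig,
    model: MalignancyModel,
    datasets: Sequence[MSIDataset],
    rois: Sequence[ROIAnnotation],
    truth: Optional[Dict[str, str]] = None,
    out_dir: Optional[str] = None,
    modes: Sequence[Mode] = (Mode.ROI, Mode.WHOLE_AVERAGE, Mode.PIXEL),
) -> Dict[str, object]:
    """Score specimens in the requested modes and assemble the report.

    Blind by construction: ``truth`` is consumed only by the final report
    stage, and only when provided.
    """
    params = config.preprocessing
    by_specimen: Dict[str, List[ROIAnnotation]] = {}
    for r in rois:
        by_specimen.setdefault(r.specimen_id, []).append(r)

    decisions: List[TriageDecision] = []
    summaries: List[QuartileSummary] = []
    maps = {}
    for ds in datasets:
        wanted = [
            m for m in modes
            if not (m is Mode.ROI and not by_specimen.get(ds.specimen_id))
        ]
        scored = score_specimen(
            model, ds, by_specimen.get(ds.specimen_id, []), params, modes=wanted
        )
        for m in wanted:
            if m is Mode.WHOLE_AVERAGE:
                summary = summarize_quartiles([scored[m]], Mode.WHOLE_AVERAGE)
            else:
                _, summary = scored[m]
            summaries.append(summary)
            decisions.append(
                triage(summary, ds.specimen_id, config.triage_low, config.triage_high)
            )
        if "map" in scored:
            maps[ds.specimen_id] = scored["map"]

    report = cohort_report(decisions, summaries, truth)
    report["maps"] = maps
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        report["table"].to_csv(
            os.path.join(out_dir, "decisions.csv"), index=False, float_format="%.8g"
        )
        summary_doc = {
            "accuracy": report.get("accuracy"),
            "class_q3": report["class_q3"].to_dict(orient="records")
            if hasattr(report["class_q3"], "to_dict")
            else report["class_q3"],
        }
        with open(os.path.join(out_dir, "summary.json"), "w") as fh:
            json.dump(summary_doc, fh, indent=1, sort_keys=True, default=str)
            fh.write("\n")
        for sid, pmap in maps.items():
            msi_io.render_probability_map(
                pmap, os.path.join(out_dir, f"map_{sid}.png"), scale=4
            )
    return report
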