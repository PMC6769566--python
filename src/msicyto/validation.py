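"""Three-mode specimen scoring and quartile-based triage.

A fitted malignancy model can score a new specimen three ways: per ROI
(mean spectrum of each pathologist-selected region), whole-average (one
mean spectrum of every non-empty pixel, ignoring the morphological
selection), or pixel by pixel (a probability per pixel, rendered as a
green-to-red map). Each produces a quartile summary; the triage call uses
the third quartile against the observed training gap — q3 below 7% reads
benign, above 28% malignant, anything between is a signal of alert for
pathologist review.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .classifier import MalignancyModel, predict_probability
from .preprocessing import (
    ProcessingParams,
    peaks_from_processed,
    process_profiles_matrix,
    project_onto_grid,
)
from .roi_features import mean_spectrum_of_pixels, roi_mean_spectrum
from .types import (
    InadequateROIError,
    MSIDataset,
    ProbabilityMap,
    ROIAnnotation,
)

__all__ = [
    "Mode",
    "TriageCall",
    "QuartileSummary",
    "TriageDecision",
    "summarize_quartiles",
    "triage",
    "classify_by_roi",
    "classify_whole_average",
    "classify_pixelwise",
    "score_specimen",
    "cohort_report",
]


class Mode(str, enum.Enum):
    ROI = "roi"
    WHOLE_AVERAGE = "whole_average"
    PIXEL = "pixel"


class TriageCall(str, enum.Enum):
    BENIGN = "benign"
    MALIGNANT = "malignant"
    ALERT_INDETERMINATE = "alert_indeterminate"


@dataclass
class QuartileSummary:
    """Quartile statistics of malignancy probabilities in one mode."""

    n: int
    q1: float
    median: float
    q3: float
    mean: float
    sd: float
    mode: Mode

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("summary needs at least one probability")
        if not (0.0 <= self.q1 <= self.median <= self.q3 <= 1.0):
            raise ValueError("quartiles must be ordered probabilities")


@dataclass
class TriageDecision:
    specimen_id: str
    mode: Mode
    call: TriageCall
    q3: float
    thresholds: Tuple[float, float]


def summarize_quartiles(probs: Sequence[float], mode: Mode) -> QuartileSummary:
    """Quartiles by linear interpolation between order statistics (type 7)."""
    p = np.asarray(list(probs), dtype=np.float64)
    if p.size == 0:
        raise ValueError("no probabilities to summarize")
    q1, med, q3 = np.quantile(p, [0.25, 0.5, 0.75], method="linear")
    return QuartileSummary(
        n=int(p.size),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        mean=float(p.mean()),
        sd=float(p.std(ddof=1)) if p.size > 1 else 0.0,
        mode=mode,
    )


def triage(
    summary: QuartileSummary,
    specimen_id: str = "",
    low: float = 0.07,
    high: float = 0.28,
) -> TriageDecision:
    """Call benign (q3 < low), malignant (q3 > high), else signal of alert."""
    if not (0.0 <= low < high <= 1.0):
        raise ValueError("thresholds must satisfy 0 <= low < high <= 1")
    if summary.q3 < low:
        call = TriageCall.BENIGN
    elif summary.q3 > high:
        call = TriageCall.MALIGNANT
    else:
        call = TriageCall.ALERT_INDETERMINATE
    return TriageDecision(
        specimen_id=specimen_id,
        mode=summary.mode,
        call=call,
        q3=summary.q3,
        thresholds=(low, high),
    )


def _score_profile(
    model: MalignancyModel,
    mz: np.ndarray,
    intensity: np.ndarray,
    params: ProcessingParams,
    source: str,
) -> float:
    pl = peaks_from_processed(mz, intensity, params, source=source)
    x, _ = project_onto_grid(pl, model.training_feature_grid)
    return predict_probability(model, x)


def classify_by_roi(
    model: MalignancyModel,
    dataset: MSIDataset,
    rois: Sequence[ROIAnnotation],
    params: Optional[ProcessingParams] = None,
) -> Tuple[List[float], QuartileSummary]:
    """One probability per ROI mean spectrum; inadequate ROIs are skipped."""
    params = params or ProcessingParams()
    probs: List[float] = []
    for roi in rois:
        try:
            ms = roi_mean_spectrum(dataset, roi, params)
        except InadequateROIError:
            continue
        probs.append(_score_profile(model, ms.mz, ms.intensity, params, ms.source))
    if not probs:
        raise InadequateROIError(
            f"specimen {dataset.specimen_id}: every ROI is empty"
        )
    return probs, summarize_quartiles(probs, Mode.ROI)


def classify_whole_average(
    model: MalignancyModel,
    dataset: MSIDataset,
    params: Optional[ProcessingParams] = None,
) -> float:
    """Probability of the whole-specimen average spectrum (ROIs ignored)."""
    params = params or ProcessingParams()
    ms = mean_spectrum_of_pixels(
        dataset, dataset.coordinates, params, source=f"whole:{dataset.specimen_id}"
    )
    return _score_profile(model, ms.mz, ms.intensity, params, ms.source)


def _score_rows(
    model: MalignancyModel,
    axis: np.ndarray,
    processed: np.ndarray,
    params: ProcessingParams,
) -> np.ndarray:
    """Score each row of an already processed profile matrix."""
    from .preprocessing import _noise_vector, filter_low_intensity, pick_peaks_vector
    from .types import PeakList

    noise = _noise_vector(processed)
    probs = np.empty(processed.shape[0])
    for i in range(processed.shape[0]):
        apex, snr = pick_peaks_vector(processed[i], float(noise[i]), params.snr_min)
        pl = PeakList(source=f"row:{i}", mz=axis[apex],
                      intensity=processed[i][apex], snr=snr)
        pl = filter_low_intensity(pl, params.intensity_threshold, params.keep_below)
        x, _ = project_onto_grid(pl, model.training_feature_grid)
        probs[i] = predict_probability(model, x)
    return probs


def classify_pixelwise(
    model: MalignancyModel,
    dataset: MSIDataset,
    params: Optional[ProcessingParams] = None,
) -> Tuple[ProbabilityMap, QuartileSummary]:
    """Score every non-empty pixel independently; empty pixels are masked."""
    params = params or ProcessingParams()
    coords = dataset.coordinates
    axis = dataset.shared_axis()
    M = np.stack([dataset.spectra[c].intensity for c in coords])
    processed, empty = process_profiles_matrix(M, params)
    if empty.all():
        raise InadequateROIError(f"specimen {dataset.specimen_id}: no non-empty pixels")
    keep = ~empty
    probs = _score_rows(model, axis, processed[keep], params)
    entries: Dict[Tuple[int, int], float] = {}
    masked = set()
    j = 0
    for i, c in enumerate(coords):
        if empty[i]:
            masked.add(c)
        else:
            entries[c] = float(probs[j])
            j += 1
    pmap = ProbabilityMap(specimen_id=dataset.specimen_id, entries=entries, masked=masked)
    summary = summarize_quartiles(list(entries.values()), Mode.PIXEL)
    return pmap, summary


def score_specimen(
    model: MalignancyModel,
    dataset: MSIDataset,
    rois: Sequence[ROIAnnotation],
    params: Optional[ProcessingParams] = None,
    modes: Sequence[Mode] = (Mode.ROI, Mode.WHOLE_AVERAGE, Mode.PIXEL),
) -> Dict[Mode, object]:
    """All requested modes from one pass over the specimen's pixels.

    Processes the pixel matrix once; ROI means, the whole-specimen mean
    and per-pixel scores are all derived from the same processed profiles,
    so results are identical to the standalone mode functions. Returns a
    dict mode -> (probabilities, QuartileSummary) for ROI and pixel modes,
    mode -> probability for whole-average; pixel mode also stores the
    :class:`ProbabilityMap` under the key ``"map"``.
    """
    params = params or ProcessingParams()
    coords = dataset.coordinates
    index_of = {c: i for i, c in enumerate(coords)}
    axis = dataset.shared_axis()
    M = np.stack([dataset.spectra[c].intensity for c in coords])
    processed, empty = process_profiles_matrix(M, params)
    if empty.all():
        raise InadequateROIError(f"specimen {dataset.specimen_id}: no non-empty pixels")
    out: Dict[Mode, object] = {}
    if Mode.ROI in modes:
        probs = []
        for roi in rois:
            roi.validate_against(dataset)
            rows = np.array([index_of[c] for c in sorted(roi.pixels)])
            rows = rows[~empty[rows]]
            if rows.size == 0:
                continue
            mean = processed[rows].mean(axis=0)
            probs.append(
                _score_profile(model, axis, mean, params, source=f"roi:{roi.roi_id}")
            )
        if not probs:
            raise InadequateROIError(
                f"specimen {dataset.specimen_id}: every ROI is empty"
            )
        out[Mode.ROI] = (probs, summarize_quartiles(probs, Mode.ROI))
    if Mode.WHOLE_AVERAGE in modes:
        mean = processed[~empty].mean(axis=0)
        out[Mode.WHOLE_AVERAGE] = _score_profile(
            model, axis, mean, params, source=f"whole:{dataset.specimen_id}"
        )
    if Mode.PIXEL in modes:
        probs = _score_rows(model, axis, processed[~empty], params)
        entries = {}
        masked = set()
        j = 0
        for i, c in enumerate(coords):
            if empty[i]:
                masked.add(c)
            else:
                entries[c] = float(probs[j])
                j += 1
        pmap = ProbabilityMap(
            specimen_id=dataset.specimen_id, entries=entries, masked=masked
        )
        out[Mode.PIXEL] = (list(probs), summarize_quartiles(list(probs), Mode.PIXEL))
        out["map"] = pmap
    return out


def cohort_report(
    decisions: Sequence[TriageDecision],
    summaries: Sequence[QuartileSummary],
    truth: Optional[Dict[str, str]] = None,
) -> Dict[str, object]:
    """Tabulate per-specimen calls and, when truth is given, accuracy.

    Returns a dict with a per-specimen DataFrame (``table``), per-class
    mean/sd of q3 per mode (``class_q3``), and, when ``truth`` maps
    specimen_id -> 'benign'/'malignant', confusion counts and accuracy.
    Alert calls are never counted as correct: they defer to the pathologist.
    """
    if not decisions:
        raise ValueError("no decisions to report")
    if len(decisions) != len(summaries):
        raise ValueError("decisions and summaries must align")
    rows = []
    for d, s in zip(decisions, summaries):
        row = {
            "specimen_id": d.specimen_id,
            "mode": d.mode.value,
            "n": s.n,
            "q1": s.q1,
            "median": s.median,
            "q3": s.q3,
            "mean": s.mean,
            "sd": s.sd,
            "call": d.call.value,
        }
        if truth is not None and d.specimen_id in truth:
            row["truth"] = truth[d.specimen_id]
            row["correct"] = d.call.value == truth[d.specimen_id]
        rows.append(row)
    table = pd.DataFrame(rows).sort_values(["mode", "specimen_id"]).reset_index(drop=True)

    report: Dict[str, object] = {"table": table}
    if truth is not None and "truth" in table.columns:
        class_q3 = (
            table.groupby(["mode", "truth"])["q3"]
            .agg(["mean", "std", "count"])
            .reset_index()
        )
        report["class_q3"] = class_q3
        confusion = (
            table.groupby(["truth", "call"]).size().unstack(fill_value=0)
        )
        report["confusion"] = confusion
        report["accuracy"] = float(table["correct"].mean())
    else:
        report["class_q3"] = (
            table.groupby("mode")["q3"].agg(["mean", "std", "count"]).reset_index()
        )
    return report
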