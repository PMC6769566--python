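"""Training-observation construction from pathologist ROIs.

Builds per-ROI mean spectra, partitions each patient's ROIs into balanced
"equivalent groups" (5 per benign, 4 per malignant patient; 1-7 ROIs each)
whose averages become the training observations, applies the SIAPEC
adequacy rule (at least 6 groups of 10 thyrocytes), and runs the two
prevalence filters: intra-patient (feature detected in >= 25% of a
patient's ROIs) then inter-patient (feature present in >= 25% of the
patients of a class).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .preprocessing import (
    ProcessingParams,
    peaks_from_processed,
    process_profiles_matrix,
    project_onto_grid,
)
from .types import (
    FeatureGrid,
    FeatureMatrix,
    InadequateROIError,
    MSIDataset,
    PeakList,
    ROIAnnotation,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MeanSpectrum",
    "ROIGroup",
    "roi_mean_spectrum",
    "mean_spectrum_of_pixels",
    "make_equivalent_groups",
    "group_mean_observations",
    "intra_patient_filter",
    "inter_patient_filter",
    "adequacy_check",
]


@dataclass
class MeanSpectrum:
    """A coordinate-free processed profile (mean over pixels)."""

    source: str
    mz: np.ndarray
    intensity: np.ndarray
    n_pixels: int


@dataclass
class ROIGroup:
    """One equivalent group of a patient's ROIs (1-7 members)."""

    patient_id: str
    group_id: str
    roi_ids: List[str]
    mean_spectrum: Optional[MeanSpectrum] = None

    def __post_init__(self) -> None:
        if not (1 <= len(self.roi_ids) <= 7):
            raise ValueError("an equivalent group holds between 1 and 7 ROIs")


def _stack(dataset: MSIDataset, coords: Sequence) -> Tuple[np.ndarray, np.ndarray]:
    axis = dataset.shared_axis()
    M = np.stack([dataset.spectra[c].intensity for c in coords])
    return axis, M


def mean_spectrum_of_pixels(
    dataset: MSIDataset,
    coords: Sequence,
    params: Optional[ProcessingParams] = None,
    source: str = "mean",
) -> MeanSpectrum:
    """Process each pixel (baseline/smooth/TIC) and average the profiles.

    Pixels flagged empty (zero TIC) are excluded from the mean; if every
    pixel is empty an :class:`InadequateROIError` is raised.
    """
    params = params or ProcessingParams()
    coords = sorted(coords)
    axis, M = _stack(dataset, coords)
    processed, empty = process_profiles_matrix(M, params)
    if empty.all():
        raise InadequateROIError(f"{source}: all {len(coords)} pixels are empty")
    mean = processed[~empty].mean(axis=0)
    return MeanSpectrum(source=source, mz=axis, intensity=mean,
                        n_pixels=int((~empty).sum()))


def roi_mean_spectrum(
    dataset: MSIDataset,
    roi: ROIAnnotation,
    params: Optional[ProcessingParams] = None,
) -> MeanSpectrum:
    """Mean processed profile over one ROI's pixels (peaks picked later)."""
    roi.validate_against(dataset)
    return mean_spectrum_of_pixels(
        dataset, sorted(roi.pixels), params, source=f"roi:{roi.roi_id}"
    )


def make_equivalent_groups(
    rois: List[ROIAnnotation],
    n_groups: int,
    seed: int = 0,
    patient_id: str = "",
) -> List[ROIGroup]:
    """Partition one patient's ROIs into balanced equivalent groups.

    ROIs are sorted by pixel count descending (exact ties broken by a
    seeded shuffle) and dealt greedily to the group with the smallest
    running pixel total among groups still below the 7-ROI cap. The
    result is a deterministic, exact partition with group sizes in [1, 7].
    """
    if not rois:
        raise ValueError("no ROIs to group")
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    if n_groups > len(rois):
        logger.info("reducing n_groups from %d to %d (patient %s has few ROIs)",
                    n_groups, len(rois), patient_id or rois[0].specimen_id)
        n_groups = len(rois)
    if len(rois) > 7 * n_groups:
        raise ValueError(
            f"{len(rois)} ROIs cannot fit {n_groups} groups of at most 7"
        )
    rng = np.random.default_rng(seed)
    tiebreak = rng.permutation(len(rois))
    order = sorted(range(len(rois)), key=lambda i: (-rois[i].n_pixels, tiebreak[i]))

    totals = [0] * n_groups
    members: List[List[int]] = [[] for _ in range(n_groups)]
    for i in order:
        eligible = [g for g in range(n_groups) if len(members[g]) < 7]
        g = min(eligible, key=lambda g: (totals[g], g))
        members[g].append(i)
        totals[g] += rois[i].n_pixels

    pid = patient_id or rois[0].specimen_id
    return [
        ROIGroup(
            patient_id=pid,
            group_id=f"{pid}_g{g + 1}",
            roi_ids=[rois[i].roi_id for i in members[g]],
        )
        for g in range(n_groups)
    ]


def group_mean_observations(
    groups: List[ROIGroup],
    roi_profiles: Dict[str, MeanSpectrum],
    grid: FeatureGrid,
    params: Optional[ProcessingParams] = None,
    labels: Optional[Dict[str, int]] = None,
) -> FeatureMatrix:
    """One observation per equivalent group, projected onto the grid.

    The group profile is the pointwise mean of its member ROIs' mean
    profiles; peaks are picked on that mean and binned onto the aligned
    feature grid. ``labels`` maps patient_id -> class (1 malignant).
    """
    if not groups:
        raise ValueError("no groups")
    params = params or ProcessingParams()
    ids, rows, dets, pats = [], [], [], []
    for g in groups:
        profiles = [roi_profiles[r] for r in g.roi_ids]
        mz = profiles[0].mz
        mean = np.mean([p.intensity for p in profiles], axis=0)
        g.mean_spectrum = MeanSpectrum(
            source=g.group_id, mz=mz, intensity=mean,
            n_pixels=sum(p.n_pixels for p in profiles),
        )
        pl = peaks_from_processed(mz, mean, params, source=g.group_id)
        x, d = project_onto_grid(pl, grid)
        ids.append(g.group_id)
        rows.append(x)
        dets.append(d)
        pats.append(g.patient_id)
    return FeatureMatrix(
        observation_ids=ids,
        feature_mz=grid.features,
        intensities=np.stack(rows),
        detected=np.stack(dets),
        labels=None if labels is None else [labels[p] for p in pats],
        patient_of=pats,
    )


def intra_patient_filter(fm: FeatureMatrix, min_fraction: float = 0.25) -> pd.DataFrame:
    """Patient-level feature presence from per-ROI detections.

    For each patient independently, a feature counts as present iff it was
    detected in at least ``min_fraction`` of that patient's ROIs
    (boundary inclusive). Returns a binary DataFrame indexed by patient,
    columns = feature m/z.
    """
    if fm.patient_of is None:
        raise ValueError("per-ROI FeatureMatrix must carry patient_of")
    det = pd.DataFrame(fm.detected, columns=fm.feature_mz)
    det["__patient"] = fm.patient_of
    grouped = det.groupby("__patient", sort=True)
    counts = grouped.size()
    if (counts == 0).any():
        raise ValueError("patient with zero ROIs")
    frac = grouped.mean()
    presence = (frac >= min_fraction).astype(np.int8)
    presence.index.name = "patient"
    return presence


def inter_patient_filter(
    patient_presence: pd.DataFrame,
    benign_ids: Sequence[str],
    malignant_ids: Sequence[str],
    min_fraction: float = 0.25,
    mode: str = "union",
) -> List[float]:
    """Class-representative features across patients.

    Keeps features present in >= ``min_fraction`` of benign patients or
    (``mode='union'``, default) / and (``mode='intersection'``) of
    malignant patients; returns ascending, deduplicated feature m/z.
    """
    if not len(benign_ids) or not len(malignant_ids):
        raise ValueError("both classes must be non-empty")
    if mode not in ("union", "intersection"):
        raise ValueError("mode must be 'union' or 'intersection'")
    b = patient_presence.loc[list(benign_ids)].mean(axis=0) >= min_fraction
    m = patient_presence.loc[list(malignant_ids)].mean(axis=0) >= min_fraction
    keep = (b | m) if mode == "union" else (b & m)
    features = sorted(float(c) for c in patient_presence.columns[keep])
    if not features:
        raise ValueError("no representative features survive the filters")
    return features


def adequacy_check(
    rois: List[ROIAnnotation], min_clusters: int = 6, min_cells: int = 10
) -> Optional[bool]:
    """SIAPEC adequacy: at least ``min_clusters`` clusters of ``min_cells``.

    Counts clusters over ROIs whose metadata records at least one cluster
    of ``min_cells`` thyrocytes. Returns ``None`` (indeterminate, logged)
    when no ROI carries the cell-count metadata.
    """
    with_meta = [
        r for r in rois
        if r.cell_cluster_count is not None and r.cells_per_cluster_min is not None
    ]
    if not with_meta:
        logger.info("adequacy indeterminate: no ROI carries cell-count metadata")
        return None
    qualifying = sum(
        r.cell_cluster_count
        for r in with_meta
        if r.cell_cluster_count >= 1 and r.cells_per_cluster_min >= min_cells
    )
    return qualifying >= min_clusters
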