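"""Read/write imzML MSI data, ROI annotations, and probability maps.

imzML 1.1 is handled through :mod:`pyimzml` in both continuous mode (one
shared m/z axis) and processed mode (per-pixel axes). ROI annotations use a
package-defined JSON schema with explicit pixel lists::

    {"specimen_id": "P_308",
     "rois": [{"roi_id": "r1", "pixels": [[x, y], ...],
               "cell_cluster_count": 3, "cells_per_cluster_min": 10}]}

Probability maps are emitted as a PNG raster (green = benign, red =
malignant, masked pixels transparent) with a CSV sidecar of
(x, y, probability) rows.
"""

from __future__ import annotations

import hashlib
import json
import os
import uuid as _uuid
from typing import Dict, List, Optional, Tuple
from unittest import mock

import numpy as np
from PIL import Image
from pyimzml.ImzMLParser import ImzMLParser
from pyimzml.ImzMLWriter import ImzMLWriter

from .types import (
    Coord,
    CytologyClass,
    MSIDataset,
    PixelSpectrum,
    ProbabilityMap,
    ROIAnnotation,
    SpecimenOrigin,
)

__all__ = [
    "read_imzml",
    "write_imzml",
    "read_roi_annotations",
    "write_roi_annotations",
    "render_probability_map",
    "probability_color",
]


def read_imzml(
    path: str,
    specimen_id: Optional[str] = None,
    patient_id: Optional[str] = None,
    cytology_class: CytologyClass = CytologyClass.UNKNOWN,
    origin: SpecimenOrigin = SpecimenOrigin.IN_VIVO,
    pixel_size_um: float = 50.0,
) -> MSIDataset:
    """Load an imzML/ibd pair into an :class:`MSIDataset`.

    One :class:`PixelSpectrum` per listed pixel; unsorted m/z axes are
    repaired (sorted with intensities permuted consistently). The file's
    spectrum mode (continuous/processed) is recorded on the dataset.
    Metadata not representable in imzML (patient id, cytology class) is
    supplied by the caller; the specimen id defaults to the file stem.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"imzML file not found: {path}")
    ibd = os.path.splitext(path)[0] + ".ibd"
    if not os.path.exists(ibd):
        raise FileNotFoundError(f"imzML binary file not found: {ibd}")
    try:
        parser = ImzMLParser(path)
    except Exception as exc:  # corrupt XML/binary
        raise IOError(f"failed to parse imzML file {path}: {exc}") from exc
    if len(parser.coordinates) == 0:
        raise ValueError(f"empty dataset: {path} lists zero pixels")

    mode = "processed"
    if "continuous" in parser.metadata.file_description.param_by_name:
        mode = "continuous"

    stem = os.path.splitext(os.path.basename(path))[0]
    dataset = MSIDataset(
        specimen_id=specimen_id or stem,
        patient_id=patient_id or stem,
        cytology_class=cytology_class,
        origin=origin,
        pixel_size_um=pixel_size_um,
        mode=mode,
    )
    for i, coord in enumerate(parser.coordinates):
        x, y = int(coord[0]), int(coord[1])
        mzs, ints = parser.getspectrum(i)
        dataset.add(PixelSpectrum(x=x, y=y, mz=np.asarray(mzs), intensity=np.asarray(ints)))
    # re-run the shared-axis invariant now that all spectra are present
    if mode == "continuous":
        MSIDataset.__post_init__(dataset)
    return dataset


def write_imzml(dataset: MSIDataset, path: str, mode: Optional[str] = None) -> str:
    """Write a dataset as an imzML/ibd pair; returns the imzML path.

    ``mode`` defaults to the dataset's own mode. Continuous mode requires a
    shared m/z axis across pixels. Intensities are stored as float32, m/z
    as float64 (round-trips preserve coordinates and values to float32
    precision).
    """
    if dataset.n_pixels == 0:
        raise ValueError("cannot write an empty dataset")
    mode = mode or dataset.mode
    if mode not in ("continuous", "processed"):
        raise ValueError("mode must be 'continuous' or 'processed'")
    if mode == "continuous":
        ref = dataset.shared_axis()
        for s in dataset.spectra.values():
            if s.mz.shape != ref.shape or not np.array_equal(s.mz, ref):
                raise ValueError("continuous mode requires a shared m/z axis")
    # derive the imzML UUID from the content so identical runs write
    # byte-identical files (the UUID stays unique per specimen/data)
    digest = hashlib.sha256()
    digest.update(dataset.specimen_id.encode())
    for coord in dataset.coordinates:
        s = dataset.spectra[coord]
        digest.update(np.asarray(coord, dtype=np.int64).tobytes())
        digest.update(s.intensity.astype(np.float32).tobytes())
    content_uuid = _uuid.UUID(bytes=digest.digest()[:16], version=4)
    with mock.patch("uuid.uuid4", return_value=content_uuid):
        with ImzMLWriter(path, mode=mode, spec_type="profile") as writer:
            for coord in dataset.coordinates:
                s = dataset.spectra[coord]
                writer.addSpectrum(s.mz, s.intensity.astype(np.float32), (s.x, s.y, 1))
    # the writer stamps the absolute output path into the run id; replace it
    # with the basename so identical runs in different directories produce
    # byte-identical files (the ibd checksum covers only the binary file)
    abs_stem = os.path.splitext(os.path.abspath(path))[0]
    stem = os.path.basename(abs_stem)
    with open(path) as fh:
        xml = fh.read()
    for needle in (abs_stem, os.path.splitext(path)[0]):
        xml = xml.replace(f'id="{needle}"', f'id="{stem}"')
    with open(path, "w") as fh:
        fh.write(xml)
    return path


def read_roi_annotations(path: str) -> List[ROIAnnotation]:
    """Read ROI annotations from the package's JSON schema.

    Duplicate coordinates within one ROI are deduplicated (set semantics);
    empty pixel lists are rejected. Membership against a dataset grid is
    checked on first use via :meth:`ROIAnnotation.validate_against`.
    """
    with open(path) as fh:
        doc = json.load(fh)
    specimen_id = doc["specimen_id"]
    rois = []
    for entry in doc["rois"]:
        pixels = {(int(x), int(y)) for x, y in entry["pixels"]}
        rois.append(
            ROIAnnotation(
                roi_id=str(entry["roi_id"]),
                specimen_id=specimen_id,
                pixels=pixels,
                cell_cluster_count=entry.get("cell_cluster_count"),
                cells_per_cluster_min=entry.get("cells_per_cluster_min"),
            )
        )
    return rois


def write_roi_annotations(rois: List[ROIAnnotation], path: str) -> str:
    if not rois:
        raise ValueError("no ROIs to write")
    specimen_ids = {r.specimen_id for r in rois}
    if len(specimen_ids) != 1:
        raise ValueError("one ROI JSON file holds ROIs of a single specimen")
    doc = {
        "specimen_id": rois[0].specimen_id,
        "rois": [
            {
                "roi_id": r.roi_id,
                "pixels": [[x, y] for x, y in sorted(r.pixels)],
                "cell_cluster_count": r.cell_cluster_count,
                "cells_per_cluster_min": r.cells_per_cluster_min,
            }
            for r in rois
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return path


def probability_color(p: float) -> Tuple[int, int, int, int]:
    """Two-color ramp: 0 -> green, 1 -> red (RGBA)."""
    p = float(min(max(p, 0.0), 1.0))
    r = int(round(255 * p))
    g = int(round(255 * (1.0 - p)))
    return (r, g, 0, 255)


def render_probability_map(pmap: ProbabilityMap, path: str, scale: int = 1) -> str:
    """Render a probability map as PNG (plus a ``.csv`` sidecar).

    Low probability renders green, high renders red; masked or absent
    pixels are transparent. ``scale`` magnifies each pixel to a
    scale x scale block for visual inspection. Returns the PNG path.
    """
    if not pmap.entries:
        raise ValueError("cannot render an empty probability map")
    coords = list(pmap.entries) + list(pmap.masked)
    xs = [c[0] for c in coords]
    ys = [c[1] for c in coords]
    x0, y0 = min(xs), min(ys)
    width = max(xs) - x0 + 1
    height = max(ys) - y0 + 1
    img = np.zeros((height, width, 4), dtype=np.uint8)  # transparent background
    for (x, y), p in pmap.entries.items():
        img[y - y0, x - x0] = probability_color(p)
    if scale > 1:
        img = np.repeat(np.repeat(img, scale, axis=0), scale, axis=1)
    Image.fromarray(img, mode="RGBA").save(path)

    csv_path = os.path.splitext(path)[0] + ".csv"
    with open(csv_path, "w") as fh:
        fh.write("x,y,probability\n")
        for (x, y) in sorted(pmap.entries):
            fh.write(f"{x},{y},{pmap.entries[(x, y)]:.6f}\n")
    return path
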