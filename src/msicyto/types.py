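"""Core in-memory containers for pixel-resolved MALDI-MSI cytology data.

Conventions follow the imzML standard: pixel coordinates are 1-based
positive integers, m/z axes are strictly ascending float64 arrays in Da,
intensities are non-negative float arrays in arbitrary units (stored as
float32 on disk). A "continuous" dataset shares one m/z axis across pixels;
a "processed" dataset stores one axis per pixel.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

Coord = Tuple[int, int]


class CytologyClass(str, enum.Enum):
    """SIAPEC cytological category of the aspirated nodule."""

    THY2 = "Thy2"
    THY3 = "Thy3"
    THY4 = "Thy4"
    THY5 = "Thy5"
    METASTASIS = "Metastasis"
    UNKNOWN = "Unknown"


class SpecimenOrigin(str, enum.Enum):
    IN_VIVO = "in_vivo"
    EX_VIVO = "ex_vivo"


class EmptyPixelError(ValueError):
    """Raised when a pixel carries no signal (all-zero spectrum).

    Callers mask such pixels rather than scoring them.
    """


class InadequateROIError(ValueError):
    """Raised when every pixel of a region of interest is empty."""


@dataclass
class PixelSpectrum:
    """One profile spectrum at an integer pixel coordinate.

    ``x``/``y`` are 1-based column/row indices (imzML convention). ``mz``
    is strictly ascending; ``intensity`` is the same length and finite.
    """

    x: int
    y: int
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if self.mz.size < 2:
            raise ValueError("a spectrum needs at least two points")
        if not np.all(np.isfinite(self.mz)) or not np.all(np.isfinite(self.intensity)):
            raise ValueError("non-finite values in spectrum")
        if np.any(np.diff(self.mz) < 0):
            # acquisition software variants emit unsorted axes; repair
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
        if np.any(np.diff(self.mz) <= 0):
            raise ValueError("m/z axis contains duplicate values")
        if self.x < 1 or self.y < 1:
            raise ValueError("pixel coordinates are 1-based positive integers")

    @property
    def coord(self) -> Coord:
        return (int(self.x), int(self.y))

    def is_empty(self) -> bool:
        return bool(np.all(self.intensity == 0))


@dataclass
class MSIDataset:
    """All pixel spectra of one specimen plus patient/class metadata."""

    specimen_id: str
    patient_id: str
    cytology_class: CytologyClass = CytologyClass.UNKNOWN
    origin: SpecimenOrigin = SpecimenOrigin.IN_VIVO
    pixel_size_um: float = 50.0
    mode: str = "continuous"
    spectra: Dict[Coord, PixelSpectrum] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.mode not in ("continuous", "processed"):
            raise ValueError("mode must be 'continuous' or 'processed'")
        if self.mode == "continuous" and len(self.spectra) > 1:
            axes = iter(self.spectra.values())
            ref = next(axes).mz
            for s in axes:
                if s.mz.shape != ref.shape or not np.array_equal(s.mz, ref):
                    raise ValueError("continuous dataset requires a shared m/z axis")

    def add(self, spectrum: PixelSpectrum) -> None:
        if spectrum.coord in self.spectra:
            raise ValueError(f"duplicate pixel coordinate {spectrum.coord}")
        self.spectra[spectrum.coord] = spectrum

    @property
    def coordinates(self) -> List[Coord]:
        return sorted(self.spectra)

    @property
    def n_pixels(self) -> int:
        return len(self.spectra)

    def shared_axis(self) -> np.ndarray:
        if not self.spectra:
            raise ValueError("empty dataset")
        first = next(iter(self.spectra.values()))
        return first.mz


@dataclass
class ROIAnnotation:
    """Pathologist-annotated pixel set containing thyrocyte clusters.

    ``cell_cluster_count`` / ``cells_per_cluster_min`` carry the SIAPEC
    adequacy metadata (at least 6 groups of 10 thyrocytes) when recorded.
    """

    roi_id: str
    specimen_id: str
    pixels: Set[Coord]
    cell_cluster_count: Optional[int] = None
    cells_per_cluster_min: Optional[int] = None

    def __post_init__(self) -> None:
        self.pixels = {(int(x), int(y)) for x, y in self.pixels}
        if not self.pixels:
            raise ValueError(f"ROI {self.roi_id!r} has an empty pixel list")
        for c in (self.cell_cluster_count, self.cells_per_cluster_min):
            if c is not None and c < 0:
                raise ValueError("cell counts must be non-negative")

    def validate_against(self, dataset: MSIDataset) -> None:
        if dataset.specimen_id != self.specimen_id:
            raise ValueError(
                f"ROI {self.roi_id!r} references specimen {self.specimen_id!r}, "
                f"not {dataset.specimen_id!r}"
            )
        missing = self.pixels - set(dataset.spectra)
        if missing:
            raise ValueError(
                f"ROI {self.roi_id!r} has pixels outside the dataset grid: "
                f"{sorted(missing)[:5]}"
            )

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)


@dataclass
class ProbabilityMap:
    """Per-pixel malignancy probabilities for one specimen.

    ``masked`` lists pixels excluded as empty/invalid; entries and masked
    are disjoint by construction.
    """

    specimen_id: str
    entries: Dict[Coord, float]
    masked: Set[Coord] = field(default_factory=set)

    def __post_init__(self) -> None:
        for c, p in self.entries.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {p} at {c} outside [0, 1]")
        overlap = set(self.entries) & self.masked
        if overlap:
            raise ValueError(f"pixels both scored and masked: {sorted(overlap)[:5]}")


@dataclass
class PeakList:
    """Picked peaks of one observation (pixel, ROI mean, or group mean)."""

    source: str
    mz: np.ndarray
    intensity: np.ndarray
    snr: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        self.snr = np.asarray(self.snr, dtype=np.float64)
        if not (self.mz.shape == self.intensity.shape == self.snr.shape):
            raise ValueError("mz, intensity and snr must have equal length")
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            raise ValueError("peak m/z must be strictly ascending")
        if np.any(self.intensity < 0):
            raise ValueError("negative peak intensity")

    def __len__(self) -> int:
        return int(self.mz.size)


@dataclass
class FeatureGrid:
    """Reference m/z grid produced by peak alignment."""

    features: np.ndarray
    tolerance_ppm: float

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.size == 0:
            raise ValueError("empty feature grid")
        if np.any(np.diff(self.features) <= 0):
            raise ValueError("grid features must be strictly ascending")
        if self.tolerance_ppm <= 0:
            raise ValueError("tolerance_ppm must be positive")

    def __len__(self) -> int:
        return int(self.features.size)


@dataclass
class FeatureMatrix:
    """Observations x aligned-feature intensities with provenance.

    ``detected`` is a same-shape binary mask: the prevalence filters are
    defined on detection, not intensity; absent features carry intensity 0.
    """

    observation_ids: List[str]
    feature_mz: np.ndarray
    intensities: np.ndarray
    detected: np.ndarray
    labels: Optional[List[int]] = None  # 1 = malignant, 0 = benign
    patient_of: Optional[List[str]] = None

    def __post_init__(self) -> None:
        self.feature_mz = np.asarray(self.feature_mz, dtype=np.float64)
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        self.detected = np.asarray(self.detected, dtype=np.int8)
        n_obs, n_feat = self.intensities.shape
        if len(self.observation_ids) != n_obs:
            raise ValueError("observation_ids length mismatch")
        if self.feature_mz.size != n_feat:
            raise ValueError("feature_mz length mismatch")
        if self.detected.shape != self.intensities.shape:
            raise ValueError("detected mask shape mismatch")
        if np.any((self.detected == 0) & (self.intensities != 0)):
            raise ValueError("undetected feature with nonzero intensity")
        if self.labels is not None and len(self.labels) != n_obs:
            raise ValueError("labels length mismatch")
        if self.patient_of is not None and len(self.patient_of) != n_obs:
            raise ValueError("patient_of length mismatch")

    @property
    def n_observations(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    def subset_features(self, keep_mz: Sequence[float]) -> "FeatureMatrix":
        """Restrict to the given feature m/z values (must exist in the grid)."""
        keep = np.asarray(sorted(keep_mz), dtype=np.float64)
        idx = np.searchsorted(self.feature_mz, keep)
        if np.any(idx >= self.feature_mz.size) or not np.allclose(
            self.feature_mz[np.minimum(idx, self.feature_mz.size - 1)], keep
        ):
            raise ValueError("requested features not present in the grid")
        return FeatureMatrix(
            observation_ids=list(self.observation_ids),
            feature_mz=self.feature_mz[idx],
            intensities=self.intensities[:, idx],
            detected=self.detected[:, idx],
            labels=None if self.labels is None else list(self.labels),
            patient_of=None if self.patient_of is None else list(self.patient_of),
        )
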