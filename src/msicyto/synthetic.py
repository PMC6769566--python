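"""Synthetic FNA cytospin MSI cohorts with known ground truth.

Emulates the statistical structure a thyroid-cytology MSI triage analysis
assumes: per-pixel linear-mode profile spectra (m/z 3000-20000) built from
Gaussian protein peaks with class-specific panels, a smooth decaying
baseline, additive truncated-Gaussian noise, per-pixel multiplicative TIC
variation, per-patient mass miscalibration within +/- 30 ppm, background
(non-thyrocyte) pixels with their own broad low-mass spectral family, and
pathologist-style ROI annotations over contiguous thyrocyte blocks.

Challenge scenarios reproduce the failure modes seen with real aspirates:
``paucicellular`` (malignant thyrocytes reduced to <= 10% of a standard
specimen), ``heterogeneous_mixture`` (malignant cells interleaved with
>= 70% benign thyrocytes), and ``colloid_rich`` (>= 70% background pixels
with elevated broad background signal).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from .types import (
    Coord,
    CytologyClass,
    MSIDataset,
    PixelSpectrum,
    ROIAnnotation,
)

__all__ = [
    "Scenario",
    "PeakPanel",
    "SyntheticConfig",
    "GroundTruth",
    "simulate_cohort",
    "simulate_specimen",
    "make_challenge_specimen",
    "simulate_validation_cohort",
    "TISSUE_BENIGN",
    "TISSUE_MALIGNANT",
    "TISSUE_BACKGROUND",
]

TISSUE_BENIGN = "thyrocyte_benign"
TISSUE_MALIGNANT = "thyrocyte_malignant"
TISSUE_BACKGROUND = "background"


class Scenario(str, enum.Enum):
    STANDARD = "standard"
    PAUCICELLULAR = "paucicellular"
    HETEROGENEOUS_MIXTURE = "heterogeneous_mixture"
    COLLOID_RICH = "colloid_rich"


def _default_shared_peaks() -> List[Tuple[float, float]]:
    # 20 nuisance proteins common to benign and malignant thyrocytes
    return [
        (3200.0, 90.0), (3600.0, 60.0), (4100.0, 140.0), (4700.0, 80.0),
        (5300.0, 110.0), (5900.0, 70.0), (6500.0, 160.0), (7200.0, 95.0),
        (7900.0, 75.0), (8600.0, 120.0), (9400.0, 85.0), (10300.0, 100.0),
        (11200.0, 65.0), (12200.0, 90.0), (13300.0, 55.0), (14400.0, 70.0),
        (15600.0, 50.0), (16900.0, 60.0), (18300.0, 45.0), (19500.0, 40.0),
    ]


@dataclass
class PeakPanel:
    """Planted Gaussian peak panels (m/z in Da, mean apex height in a.u.).

    ``shared_peaks`` appear in every thyrocyte pixel; ``benign_peaks`` and
    ``malignant_peaks`` are the class-discriminant signals (disjoint m/z).
    ``peak_fwhm_da`` is the common full width at half maximum, broad as in
    linear-TOF protein spectra.
    """

    shared_peaks: List[Tuple[float, float]] = field(default_factory=_default_shared_peaks)
    benign_peaks: List[Tuple[float, float]] = field(
        default_factory=lambda: [(4400.0, 120.0), (8200.0, 100.0)]
    )
    malignant_peaks: List[Tuple[float, float]] = field(
        default_factory=lambda: [(5600.0, 100.0), (9800.0, 120.0), (11800.0, 90.0)]
    )
    sporadic_pool: List[float] = field(
        default_factory=lambda: [
            3850.0, 5000.0, 6200.0, 6850.0, 7550.0, 8900.0,
            10050.0, 10750.0, 12750.0, 13850.0, 15000.0, 17600.0,
        ]
    )
    peak_fwhm_da: float = 40.0

    def __post_init__(self) -> None:
        for mz, h in self.shared_peaks + self.benign_peaks + self.malignant_peaks:
            if not (3000.0 <= mz <= 20000.0):
                raise ValueError(f"peak m/z {mz} outside [3000, 20000]")
            if h <= 0:
                raise ValueError("peak heights must be positive")
        b = {mz for mz, _ in self.benign_peaks}
        m = {mz for mz, _ in self.malignant_peaks}
        if b & m:
            raise ValueError("benign and malignant peak m/z must be disjoint")
        if set(self.sporadic_pool) & (b | m | {mz for mz, _ in self.shared_peaks}):
            raise ValueError("sporadic pool must be disjoint from the panel peaks")
        if self.peak_fwhm_da <= 0:
            raise ValueError("peak_fwhm_da must be positive")

    @property
    def discriminant_mz(self) -> List[Tuple[float, int]]:
        """Truly discriminant m/z with sign: +1 up in malignant, -1 up in benign."""
        out = [(mz, -1) for mz, _ in self.benign_peaks]
        out += [(mz, +1) for mz, _ in self.malignant_peaks]
        return sorted(out)


@dataclass
class SyntheticConfig:
    """Cohort-level generator settings.

    Defaults mirror the training-study statistics: 9 benign + 9 malignant
    patients, 4-22 ROIs per patient, 3-162 pixels per ROI (log-uniformly
    sampled, so medians sit near the observed medians of 5-13 despite the
    long upper tail), mass miscalibration within the instrument's
    +/- 30 ppm external-calibration accuracy.
    """

    n_benign_patients: int = 9
    n_malignant_patients: int = 9
    # None -> the per-class study statistics: benign 5-22 ROIs of 3-39 px,
    # malignant 4-19 ROIs of 3-162 px
    rois_per_patient_range: Optional[Tuple[int, int]] = None
    pixels_per_roi_range: Optional[Tuple[int, int]] = None
    panel: PeakPanel = field(default_factory=PeakPanel)
    baseline_amplitude: float = 20.0
    baseline_decay_da: float = 3000.0
    noise_sd: float = 2.0
    tic_variation_cv: float = 0.15
    mass_jitter_ppm: float = 30.0
    # standard scenario = adequate cytospin: off-target pixels stay a
    # minority below the 25% weight of the q3 triage statistic
    background_fraction: float = 0.2
    # per-patient private nuisance peaks, present in a random minority of
    # that patient's ROIs -- what the intra-patient prevalence filter removes
    sporadic_peaks_per_patient: int = 3
    sporadic_roi_fraction: float = 0.15
    sporadic_height: float = 60.0
    scenario: Scenario = Scenario.STANDARD
    seed: int = 0
    n_axis_points: int = 4000
    mz_min: float = 3000.0
    mz_max: float = 20000.0

    def __post_init__(self) -> None:
        if isinstance(self.scenario, str):
            self.scenario = Scenario(self.scenario)
        for rng_ in (self.rois_per_patient_range, self.pixels_per_roi_range):
            if rng_ is not None:
                lo, hi = rng_
                if not (0 < lo <= hi):
                    raise ValueError("ranges must satisfy 0 < min <= max")
        for frac in (self.tic_variation_cv, self.background_fraction):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("fractions must lie in [0, 1]")
        if abs(self.mass_jitter_ppm) > 30.0:
            raise ValueError("mass_jitter_ppm bounded by the +/-30 ppm accuracy")
        if self.n_benign_patients < 1 or self.n_malignant_patients < 1:
            raise ValueError("need at least one patient per class")


@dataclass
class GroundTruth:
    """What the generator planted, for scoring recovery."""

    specimen_class: Dict[str, str]  # specimen_id -> "benign" | "malignant"
    discriminant_mz: List[Tuple[float, int]]  # (m/z, +1 malignant-up / -1 benign-up)
    pixel_labels: Dict[str, Dict[Coord, str]]  # specimen -> coord -> tissue label


# ---------------------------------------------------------------------------
# spectral templates
# ---------------------------------------------------------------------------

_BACKGROUND_BUMPS = [(3400.0, 600.0, 60.0), (4600.0, 500.0, 40.0), (6600.0, 800.0, 30.0)]


def _gaussian(mz: np.ndarray, center: float, fwhm: float, height: float) -> np.ndarray:
    sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    return height * np.exp(-0.5 * ((mz - center) / sigma) ** 2)


def _templates(
    mz: np.ndarray, config: SyntheticConfig, background_boost: float = 1.0
) -> Dict[str, np.ndarray]:
    """Noise-free clean signal per tissue label on the given axis."""
    panel = config.panel
    baseline = config.baseline_amplitude * np.exp(
        -(mz - config.mz_min) / config.baseline_decay_da
    )
    shared = np.zeros_like(mz)
    for center, h in panel.shared_peaks:
        shared += _gaussian(mz, center, panel.peak_fwhm_da, h)
    benign = shared.copy()
    for center, h in panel.benign_peaks:
        benign += _gaussian(mz, center, panel.peak_fwhm_da, h)
    malignant = shared.copy()
    for center, h in panel.malignant_peaks:
        malignant += _gaussian(mz, center, panel.peak_fwhm_da, h)
    background = np.zeros_like(mz)
    for center, fwhm, h in _BACKGROUND_BUMPS:
        background += _gaussian(mz, center, fwhm, h * background_boost)
    return {
        TISSUE_BENIGN: benign + baseline,
        TISSUE_MALIGNANT: malignant + baseline,
        TISSUE_BACKGROUND: background + baseline * background_boost,
    }


def _sample_roi_sizes(
    config: SyntheticConfig, rng: np.random.Generator, malignant: bool
) -> List[int]:
    roi_range = config.rois_per_patient_range or ((4, 19) if malignant else (5, 22))
    px_range = config.pixels_per_roi_range or ((3, 162) if malignant else (3, 39))
    n_rois = int(rng.integers(roi_range[0], roi_range[1] + 1))
    lo, hi = px_range
    # log-uniform: long-tailed like real cluster sizes, median near sqrt(lo*hi)
    sizes = np.exp(rng.uniform(math.log(lo), math.log(hi + 1), size=n_rois))
    return [int(min(max(int(s), lo), hi)) for s in sizes]


# ---------------------------------------------------------------------------
# specimen generation
# ---------------------------------------------------------------------------

def simulate_specimen(
    config: SyntheticConfig,
    rng: np.random.Generator,
    specimen_id: str,
    patient_id: str,
    malignant: bool,
    scenario: Scenario = Scenario.STANDARD,
) -> Tuple[MSIDataset, List[ROIAnnotation], Dict[Coord, str]]:
    """Generate one specimen: dataset, ROI annotations, per-pixel labels."""
    roi_sizes = _sample_roi_sizes(config, rng, malignant)

    # per-patient mass miscalibration, uniform within the stated accuracy
    jitter_ppm = float(rng.uniform(-config.mass_jitter_ppm, config.mass_jitter_ppm))
    base_axis = np.linspace(config.mz_min, config.mz_max, config.n_axis_points)
    axis = base_axis * (1.0 + jitter_ppm * 1e-6)

    # grid sized so thyrocyte pixels occupy ~ (1 - background_fraction)
    total_thyro_standard = sum(roi_sizes)
    bg_frac = config.background_fraction
    if scenario is Scenario.COLLOID_RICH:
        bg_frac = max(bg_frac, 0.75)
    n_total = max(int(math.ceil(total_thyro_standard / max(1.0 - bg_frac, 1e-9))),
                  total_thyro_standard + 1)
    side = int(math.ceil(math.sqrt(n_total)))

    if scenario is Scenario.PAUCICELLULAR:
        # malignant thyrocytes cut to <= 10% of the standard count; grid unchanged
        target = max(1, int(math.floor(0.1 * total_thyro_standard)))
        shrunk: List[int] = []
        remaining = target
        for s in roi_sizes:
            take = min(s, max(1, int(round(s * target / total_thyro_standard))))
            take = min(take, remaining)
            if take > 0:
                shrunk.append(take)
                remaining -= take
            if remaining == 0:
                break
        roi_sizes = shrunk or [1]

    # snake-order coordinate list keeps each ROI spatially contiguous;
    # only n_total pixels are acquired, so the realized background
    # fraction stays at the configured value (the pixel set need not
    # tile a full rectangle)
    coords: List[Coord] = []
    for row in range(1, side + 1):
        cols = range(1, side + 1) if row % 2 == 1 else range(side, 0, -1)
        coords.extend((c, row) for c in cols)
    coords = coords[:n_total]

    thyro_class = TISSUE_MALIGNANT if malignant else TISSUE_BENIGN
    labels: Dict[Coord, str] = {}
    rois: List[ROIAnnotation] = []
    roi_slices: List[Tuple[int, int]] = []
    pos = 0
    n_thyro_seen = 0
    for k, size in enumerate(roi_sizes):
        roi_coords = coords[pos:pos + size]
        roi_slices.append((pos, pos + size))
        pos += size
        for c in roi_coords:
            labels[c] = thyro_class
        if scenario is Scenario.HETEROGENEOUS_MIXTURE:
            # every 4th thyrocyte pixel (globally) malignant: 25% malignant
            # interleaved with >= 70% benign regardless of ROI sizes
            for c in roi_coords:
                labels[c] = (
                    TISSUE_MALIGNANT if n_thyro_seen % 4 == 0 else TISSUE_BENIGN
                )
                n_thyro_seen += 1
        clusters = max(1, size // 10)
        cells_min = 10 if scenario is not Scenario.PAUCICELLULAR else 4
        rois.append(
            ROIAnnotation(
                roi_id=f"{specimen_id}_roi{k + 1}",
                specimen_id=specimen_id,
                pixels=set(roi_coords),
                cell_cluster_count=clusters,
                cells_per_cluster_min=cells_min,
            )
        )
    for c in coords[pos:]:
        labels[c] = TISSUE_BACKGROUND

    boost = 3.0 if scenario is Scenario.COLLOID_RICH else 1.0
    templates = _templates(axis, config, background_boost=boost)

    ordered = coords  # generation order fixed for reproducibility
    label_arr = [labels[c] for c in ordered]
    clean = np.stack([templates[l] for l in label_arr])

    # patient-private sporadic peaks: appear in every pixel of a random
    # minority of this patient's ROIs, so the intra-patient prevalence
    # filter has realistic nuisance features to remove
    if config.sporadic_peaks_per_patient > 0 and config.panel.sporadic_pool:
        chosen = rng.choice(
            len(config.panel.sporadic_pool),
            size=min(config.sporadic_peaks_per_patient, len(config.panel.sporadic_pool)),
            replace=False,
        )
        for pool_idx in chosen:
            center = config.panel.sporadic_pool[int(pool_idx)]
            bump = _gaussian(axis, center, config.panel.peak_fwhm_da,
                             config.sporadic_height)
            for (lo_i, hi_i) in roi_slices:
                if rng.random() < config.sporadic_roi_fraction:
                    clean[lo_i:hi_i] += bump

    n_px = clean.shape[0]
    if config.tic_variation_cv > 0:
        sigma2 = math.log(1.0 + config.tic_variation_cv ** 2)
        tic_mult = rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=n_px)
    else:
        tic_mult = np.ones(n_px)
    M = clean * tic_mult[:, None]
    if config.noise_sd > 0:
        M = M + rng.normal(0.0, config.noise_sd, size=M.shape)
    np.maximum(M, 0.0, out=M)
    M = M.astype(np.float32).astype(np.float64)  # match on-disk precision

    cls = CytologyClass.THY5 if malignant else CytologyClass.THY2
    dataset = MSIDataset(
        specimen_id=specimen_id,
        patient_id=patient_id,
        cytology_class=cls,
        mode="continuous",
    )
    for c, row in zip(ordered, M):
        dataset.spectra[c] = PixelSpectrum(x=c[0], y=c[1], mz=axis, intensity=row)
    MSIDataset.__post_init__(dataset)
    return dataset, rois, labels


def simulate_cohort(
    config: Optional[SyntheticConfig] = None,
) -> Tuple[List[MSIDataset], List[ROIAnnotation], GroundTruth]:
    """Generate a full training-style cohort under the standard scenario.

    One specimen per patient; benign patients are named ``B1..Bn`` and
    malignant ``M1..Mn``. Fully reproducible from ``config.seed``.
    """
    config = config or SyntheticConfig()
    if config.scenario is not Scenario.STANDARD:
        raise ValueError("simulate_cohort generates standard-scenario specimens; "
                         "use make_challenge_specimen for challenge scenarios")
    root = np.random.SeedSequence(config.seed)
    n = config.n_benign_patients + config.n_malignant_patients
    streams = root.spawn(n)
    datasets: List[MSIDataset] = []
    all_rois: List[ROIAnnotation] = []
    truth = GroundTruth(
        specimen_class={},
        discriminant_mz=config.panel.discriminant_mz,
        pixel_labels={},
    )
    idx = 0
    for i in range(config.n_benign_patients):
        pid = f"B{i + 1}"
        ds, rois, labels = simulate_specimen(
            config, np.random.default_rng(streams[idx]), pid, pid, malignant=False
        )
        idx += 1
        datasets.append(ds)
        all_rois.extend(rois)
        truth.specimen_class[pid] = "benign"
        truth.pixel_labels[pid] = labels
    for i in range(config.n_malignant_patients):
        pid = f"M{i + 1}"
        ds, rois, labels = simulate_specimen(
            config, np.random.default_rng(streams[idx]), pid, pid, malignant=True
        )
        idx += 1
        datasets.append(ds)
        all_rois.extend(rois)
        truth.specimen_class[pid] = "malignant"
        truth.pixel_labels[pid] = labels
    return datasets, all_rois, truth


def make_challenge_specimen(
    config: SyntheticConfig,
) -> Tuple[MSIDataset, List[ROIAnnotation], GroundTruth]:
    """Generate one malignant challenge specimen per ``config.scenario``."""
    if config.scenario is Scenario.STANDARD:
        raise ValueError("challenge scenarios exclude 'standard'")
    sid = f"CH_{config.scenario.value}"
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    ds, rois, labels = simulate_specimen(
        config, rng, sid, sid, malignant=True, scenario=config.scenario
    )
    truth = GroundTruth(
        specimen_class={sid: "malignant"},
        discriminant_mz=config.panel.discriminant_mz,
        pixel_labels={sid: labels},
    )
    return ds, rois, truth


def simulate_validation_cohort(
    config: Optional[SyntheticConfig] = None,
    n_benign: int = 5,
    n_malignant: int = 5,
    include_challenges: bool = True,
) -> Tuple[List[MSIDataset], List[ROIAnnotation], GroundTruth]:
    """Standard validation specimens plus the three challenge specimens.

    Seeds are derived from ``config.seed`` but disjoint from the training
    stream (different spawn keys), so validation patients are new.
    """
    config = config or SyntheticConfig()
    root = np.random.SeedSequence((config.seed, 0x5EED))
    streams = root.spawn(n_benign + n_malignant)
    datasets: List[MSIDataset] = []
    all_rois: List[ROIAnnotation] = []
    truth = GroundTruth(
        specimen_class={},
        discriminant_mz=config.panel.discriminant_mz,
        pixel_labels={},
    )
    for i in range(n_benign + n_malignant):
        malignant = i >= n_benign
        pid = f"VM{i - n_benign + 1}" if malignant else f"VB{i + 1}"
        ds, rois, labels = simulate_specimen(
            config, np.random.default_rng(streams[i]), pid, pid, malignant=malignant
        )
        datasets.append(ds)
        all_rois.extend(rois)
        truth.specimen_class[pid] = "malignant" if malignant else "benign"
        truth.pixel_labels[pid] = labels
    if include_challenges:
        for j, scen in enumerate(
            (Scenario.PAUCICELLULAR, Scenario.HETEROGENEOUS_MIXTURE, Scenario.COLLOID_RICH)
        ):
            ch_cfg = replace(config, scenario=scen, seed=config.seed * 1000 + 7 + j)
            ds, rois, ch_truth = make_challenge_specimen(ch_cfg)
            datasets.append(ds)
            all_rois.extend(rois)
            truth.specimen_class.update(ch_truth.specimen_class)
            truth.pixel_labels.update(ch_truth.pixel_labels)
    return datasets, all_rois, truth
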