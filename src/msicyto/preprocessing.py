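"""Per-spectrum processing chain for linear-mode MALDI profile spectra.

The chain, applied in order, is: baseline subtraction (running median),
smoothing (moving average), TIC normalization, peak picking (S/N >= 6),
low-intensity filtering (post-TIC floor 0.0003), and finally peak
alignment across observations onto a common feature grid.

All window operators use truncated windows at the spectrum edges, so every
output point is a statistic of observed data only. Batched variants
(``*_matrix``) operate on a (n_spectra, n_points) matrix sharing one m/z
axis and are what the dataset-level pipeline uses; the per-spectrum
operators are thin wrappers over them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

try:
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

from .types import EmptyPixelError, FeatureGrid, FeatureMatrix, PeakList, PixelSpectrum

__all__ = [
    "ProcessingParams",
    "subtract_baseline",
    "smooth",
    "tic_normalize",
    "estimate_noise",
    "pick_peaks",
    "filter_low_intensity",
    "align_peaks",
    "process_spectrum",
    "baseline_matrix",
    "smooth_matrix",
    "tic_normalize_matrix",
    "pick_peaks_vector",
    "project_onto_grid",
]


@dataclass
class ProcessingParams:
    """Tunable knobs of the processing chain.

    baseline_half_window: points on each side of the running-median window.
    smooth_half_window: points on each side of the moving-average window
        (2 approximates the nominal half-width 2.5, which no integer
        window can realize).
    snr_min: minimum apex signal-to-noise ratio for a peak (inclusive).
    intensity_threshold: post-TIC intensity floor; peaks below it are
        treated as noise. ``keep_below`` inverts the comparison for
        compatibility with sources that discard strong peaks instead.
    tolerance_ppm: relative gap (ppm) at which the single-linkage
        alignment splits adjacent peak clusters.
    """

    baseline_half_window: int = 50
    smooth_half_window: int = 2
    snr_min: float = 6.0
    intensity_threshold: float = 0.0003
    keep_below: bool = False
    tolerance_ppm: float = 2000.0


# ---------------------------------------------------------------------------
# batched matrix operators (shared m/z axis)
# ---------------------------------------------------------------------------

if _HAVE_NUMBA:

    @numba.njit(cache=False)
    def _rolling_median_rows(M: np.ndarray, hw: int) -> np.ndarray:
        """Truncated centered rolling median of each row.

        Maintains a sorted window buffer (binary-search insert/remove);
        median of an even-sized edge window is the mean of the two middle
        values, matching ``np.median``.
        """
        n_rows, n = M.shape
        out = np.empty_like(M)
        buf = np.empty(2 * hw + 1, dtype=M.dtype)
        for r in range(n_rows):
            x = M[r]
            m = hw + 1
            for k in range(m):
                buf[k] = x[k]
            buf[:m].sort()
            for i in range(n):
                if i > 0:
                    if i - hw - 1 >= 0:
                        v = x[i - hw - 1]
                        lo, hi = 0, m
                        while lo < hi:
                            mid = (lo + hi) // 2
                            if buf[mid] < v:
                                lo = mid + 1
                            else:
                                hi = mid
                        for k in range(lo, m - 1):
                            buf[k] = buf[k + 1]
                        m -= 1
                    if i + hw <= n - 1:
                        v = x[i + hw]
                        lo, hi = 0, m
                        while lo < hi:
                            mid = (lo + hi) // 2
                            if buf[mid] < v:
                                lo = mid + 1
                            else:
                                hi = mid
                        for k in range(m, lo, -1):
                            buf[k] = buf[k - 1]
                        buf[lo] = v
                        m += 1
                if m % 2 == 1:
                    out[r, i] = buf[m // 2]
                else:
                    out[r, i] = 0.5 * (buf[m // 2 - 1] + buf[m // 2])
        return out


def baseline_matrix(M: np.ndarray, half_window_points: int) -> np.ndarray:
    """Running-median baseline subtraction on each row of ``M``.

    baseline(i) = median of the row over [i - hw, i + hw], truncated at the
    edges; output = max(0, row - baseline).
    """
    if half_window_points < 1:
        raise ValueError("half_window_points must be >= 1")
    n = M.shape[1]
    if n < 2 * half_window_points + 1:
        raise ValueError(
            f"spectrum of {n} points shorter than window "
            f"{2 * half_window_points + 1}"
        )
    M = np.ascontiguousarray(M, dtype=np.float64)
    if _HAVE_NUMBA:
        baseline = _rolling_median_rows(M, half_window_points)
    else:
        # pandas implements the same truncated centered rolling median
        baseline = (
            pd.DataFrame(M.T)
            .rolling(2 * half_window_points + 1, center=True, min_periods=1)
            .median()
            .to_numpy()
            .T
        )
    return np.maximum(M - baseline, 0.0)


def smooth_matrix(M: np.ndarray, half_window_points: int) -> np.ndarray:
    """Unweighted moving average over 2*hw + 1 points, truncated at edges."""
    if half_window_points < 1:
        raise ValueError("half_window_points must be >= 1")
    n = M.shape[1]
    if n < 2 * half_window_points + 1:
        raise ValueError(
            f"spectrum of {n} points shorter than window "
            f"{2 * half_window_points + 1}"
        )
    hw = half_window_points
    csum = np.cumsum(M, axis=1, dtype=np.float64)
    csum = np.concatenate([np.zeros((M.shape[0], 1)), csum], axis=1)
    idx = np.arange(n)
    lo = np.maximum(idx - hw, 0)
    hi = np.minimum(idx + hw, n - 1)
    sums = csum[:, hi + 1] - csum[:, lo]
    return sums / (hi - lo + 1)


def tic_normalize_matrix(M: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Divide each row by its total ion current.

    Returns (normalized matrix, boolean mask of empty rows). Empty rows
    (zero TIC) are left as zeros and flagged; callers mask those pixels.
    """
    tic = M.sum(axis=1)
    empty = tic <= 0
    out = np.zeros_like(M, dtype=np.float64)
    np.divide(M, tic[:, None], out=out, where=~empty[:, None])
    return out, empty


def _noise_vector(M: np.ndarray) -> np.ndarray:
    """Scaled MAD (1.4826 * median |x - median x|) per row."""
    med = np.median(M, axis=1, keepdims=True)
    return 1.4826 * np.median(np.abs(M - med), axis=1)


def pick_peaks_vector(
    intensity: np.ndarray, noise: float, snr_min: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Local-maximum peak indices and S/N of one intensity vector.

    A peak is strictly greater than its neighboring distinct values;
    plateaus count once, at their leftmost point. Endpoint runs are never
    peaks. Apex S/N uses the given noise level; zero noise admits every
    positive apex (infinite S/N).
    """
    n = intensity.size
    # run-length encode so plateaus resolve to their leftmost point
    change = np.empty(n, dtype=bool)
    change[0] = True
    np.not_equal(intensity[1:], intensity[:-1], out=change[1:])
    starts = np.flatnonzero(change)
    vals = intensity[starts]
    if vals.size < 3:
        return np.empty(0, dtype=np.intp), np.empty(0)
    is_peak = np.zeros(vals.size, dtype=bool)
    is_peak[1:-1] = (vals[1:-1] > vals[:-2]) & (vals[1:-1] > vals[2:])
    apex = starts[is_peak]
    heights = intensity[apex]
    if noise > 0:
        snr = heights / noise
    else:
        snr = np.where(heights > 0, np.inf, 0.0)
    keep = snr >= snr_min
    return apex[keep], snr[keep]


# ---------------------------------------------------------------------------
# per-spectrum operators
# ---------------------------------------------------------------------------

def subtract_baseline(s: PixelSpectrum, half_window_points: int = 50) -> PixelSpectrum:
    """Median-method baseline subtraction; clips the result at zero."""
    out = baseline_matrix(s.intensity[None, :], half_window_points)[0]
    return PixelSpectrum(x=s.x, y=s.y, mz=s.mz.copy(), intensity=out)


def smooth(s: PixelSpectrum, half_window_points: int = 2) -> PixelSpectrum:
    """Moving-average smoothing; preserves total signal up to edge effects."""
    out = smooth_matrix(s.intensity[None, :], half_window_points)[0]
    return PixelSpectrum(x=s.x, y=s.y, mz=s.mz.copy(), intensity=out)


def tic_normalize(s: PixelSpectrum) -> PixelSpectrum:
    """Divide by total ion current so intensities sum to one."""
    out, empty = tic_normalize_matrix(s.intensity[None, :])
    if empty[0]:
        raise EmptyPixelError(f"pixel {s.coord} has zero total ion current")
    return PixelSpectrum(x=s.x, y=s.y, mz=s.mz.copy(), intensity=out[0])


def estimate_noise(s: PixelSpectrum) -> float:
    """Robust noise level: scaled median absolute deviation (MAD * 1.4826).

    Computed on the (baseline-subtracted) intensities; resistant to sparse
    large peaks, and exactly zero only for an identically flat signal.
    """
    if s.intensity.size < 16:
        raise ValueError("need at least 16 points to estimate noise")
    return float(_noise_vector(s.intensity[None, :])[0])


def pick_peaks(s: PixelSpectrum, snr_min: float = 6.0) -> PeakList:
    """Detect local maxima with apex S/N >= ``snr_min`` (inclusive).

    Expects a baseline-subtracted, smoothed, TIC-normalized spectrum; the
    reported intensity is the apex value.
    """
    noise = float(_noise_vector(s.intensity[None, :])[0])
    apex, snr = pick_peaks_vector(s.intensity, noise, snr_min)
    return PeakList(
        source=f"pixel:{s.x},{s.y}",
        mz=s.mz[apex],
        intensity=s.intensity[apex],
        snr=snr,
    )


def filter_low_intensity(
    pl: PeakList, threshold: float = 0.0003, keep_below: bool = False
) -> PeakList:
    """Drop peaks below the post-TIC intensity floor (boundary inclusive).

    ``keep_below=True`` inverts the comparison (retain peaks with
    intensity < threshold), for sources that specify the filter that way.
    """
    if keep_below:
        keep = pl.intensity < threshold
    else:
        keep = pl.intensity >= threshold
    return PeakList(
        source=pl.source, mz=pl.mz[keep], intensity=pl.intensity[keep], snr=pl.snr[keep]
    )


def align_peaks(
    peaklists: Sequence[PeakList], tolerance_ppm: float = 2000.0
) -> Tuple[FeatureGrid, FeatureMatrix]:
    """Bin peaks across observations into a shared feature grid.

    Single-linkage in one dimension: all peak m/z values are pooled and
    sorted, and the sequence is cut wherever the gap between adjacent
    values exceeds ``tolerance_ppm`` relative to the lower value. Each
    cluster becomes one feature at the intensity-weighted mean m/z. The
    matrix entry is the summed intensity of an observation's peaks in the
    cluster (0 if absent), with a parallel binary detection mask.
    """
    if not peaklists:
        raise ValueError("no peak lists to align")
    all_mz, all_int, all_obs = [], [], []
    for i, pl in enumerate(peaklists):
        all_mz.append(pl.mz)
        all_int.append(pl.intensity)
        all_obs.append(np.full(len(pl), i, dtype=np.intp))
    mz = np.concatenate(all_mz)
    if mz.size == 0:
        raise ValueError("no features: every peak list is empty")
    inten = np.concatenate(all_int)
    obs = np.concatenate(all_obs)
    order = np.argsort(mz, kind="stable")
    mz, inten, obs = mz[order], inten[order], obs[order]

    gaps = np.diff(mz)
    cut = gaps > mz[:-1] * (tolerance_ppm * 1e-6)
    cluster = np.concatenate([[0], np.cumsum(cut)])
    n_clusters = int(cluster[-1]) + 1

    weights = np.where(inten > 0, inten, 1e-300)  # weighted mean falls back to plain mean
    centers = np.bincount(cluster, weights=mz * weights, minlength=n_clusters)
    centers /= np.bincount(cluster, weights=weights, minlength=n_clusters)

    n_obs = len(peaklists)
    intensities = np.zeros((n_obs, n_clusters))
    detected = np.zeros((n_obs, n_clusters), dtype=np.int8)
    np.add.at(intensities, (obs, cluster), inten)
    detected[obs, cluster] = 1

    grid = FeatureGrid(features=centers, tolerance_ppm=tolerance_ppm)
    fm = FeatureMatrix(
        observation_ids=[pl.source for pl in peaklists],
        feature_mz=centers,
        intensities=intensities,
        detected=detected,
    )
    return grid, fm


def process_spectrum(
    s: PixelSpectrum, params: Optional[ProcessingParams] = None
) -> PeakList:
    """Full chain: baseline -> smooth -> TIC -> pick peaks -> intensity filter."""
    params = params or ProcessingParams()
    out = subtract_baseline(s, params.baseline_half_window)
    out = smooth(out, params.smooth_half_window)
    out = tic_normalize(out)  # raises EmptyPixelError on zero TIC
    pl = pick_peaks(out, params.snr_min)
    return filter_low_intensity(pl, params.intensity_threshold, params.keep_below)


def process_profiles_matrix(
    M: np.ndarray, params: Optional[ProcessingParams] = None
) -> Tuple[np.ndarray, np.ndarray]:
    """Baseline + smooth + TIC on a (n_spectra, n_points) matrix.

    Returns (processed matrix, empty mask); empty rows stay all-zero.
    """
    params = params or ProcessingParams()
    out = baseline_matrix(M, params.baseline_half_window)
    out = smooth_matrix(out, params.smooth_half_window)
    return tic_normalize_matrix(out)


def peaks_from_processed(
    mz: np.ndarray, intensity: np.ndarray, params: Optional[ProcessingParams] = None,
    source: str = "profile",
) -> PeakList:
    """Pick + intensity-filter peaks on an already processed profile."""
    params = params or ProcessingParams()
    noise = float(_noise_vector(intensity[None, :])[0])
    apex, snr = pick_peaks_vector(intensity, noise, params.snr_min)
    pl = PeakList(source=source, mz=mz[apex], intensity=intensity[apex], snr=snr)
    return filter_low_intensity(pl, params.intensity_threshold, params.keep_below)


def project_onto_grid(pl: PeakList, grid: FeatureGrid) -> Tuple[np.ndarray, np.ndarray]:
    """Map a peak list onto a feature grid (nearest feature within tolerance).

    Returns (intensity vector, detection vector) over the grid; peaks
    matching no feature are dropped, features with no peak get 0 — the
    same absent-as-zero convention used at training time.
    """
    x = np.zeros(len(grid))
    d = np.zeros(len(grid), dtype=np.int8)
    if len(pl) == 0:
        return x, d
    idx = np.searchsorted(grid.features, pl.mz)
    for j, (m, h) in enumerate(zip(pl.mz, pl.intensity)):
        candidates = []
        if idx[j] > 0:
            candidates.append(idx[j] - 1)
        if idx[j] < len(grid):
            candidates.append(idx[j])
        best, best_err = None, np.inf
        for c in candidates:
            err = abs(m - grid.features[c])
            if err < best_err:
                best, best_err = c, err
        if best is not None and best_err <= grid.features[best] * grid.tolerance_ppm * 1e-6:
            x[best] += h
            d[best] = 1
    return x, d
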