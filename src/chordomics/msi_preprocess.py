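"""MALDI-TOF-MSI spectral preprocessing.

Turns raw profile-mode pixel spectra into a calibrated, TIC-normalized
pixels x peaks intensity matrix restricted to on-tissue, non-matrix peaks:

1. TopHat (morphological opening) baseline subtraction per pixel,
2. on/off-tissue segmentation by bisecting k-means on log TIC,
3. peak picking on the mean on-tissue spectrum at SNR > 9 (windowed-MAD
   noise, quadratic apex refinement),
4. internal calibration of the peak axis against reference masses with an
   affine ppm-error model,
5. peak-window intensity extraction per pixel, TIC normalization,
6. matrix-peak removal by ion-image correlation with the principal
   [NEDC+Cl]- matrix peak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import grey_opening, median_filter
from scipy.signal import argrelextrema
from sklearn.cluster import KMeans

from .references import ppm_error

__all__ = [
    "Spectrum",
    "PeakAxis",
    "CalibrationModel",
    "tophat_baseline",
    "pick_peaks",
    "segment_tissue",
    "tic_normalize",
    "internal_calibrate",
    "remove_matrix_peaks",
    "extract_peak_matrix",
    "preprocess_msi",
]


@dataclass
class Spectrum:
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if self.mz.size >= 2 and not (np.diff(self.mz) > 0).all():
            raise ValueError("m/z axis must be strictly ascending")


@dataclass
class PeakAxis:
    """Picked peaks: apex m/z (ascending) with profile-axis index windows."""

    mz: np.ndarray                      # refined apex m/z
    apex_index: np.ndarray              # apex sample index in the profile axis
    window: np.ndarray                  # (n_peaks, 2) profile index windows

    def __len__(self):
        return self.mz.size


@dataclass
class CalibrationModel:
    """Affine ppm-error model err_ppm(m) = a + b*m fitted to reference ions."""

    a: float = 0.0
    b: float = 0.0
    references_used: np.ndarray = field(default_factory=lambda: np.empty(0))
    residual_ppm: np.ndarray = field(default_factory=lambda: np.empty(0))
    identity: bool = False

    def predicted_ppm(self, mz):
        return self.a + self.b * np.asarray(mz, dtype=float)

    def correct(self, mz):
        mz = np.asarray(mz, dtype=float)
        return mz / (1.0 + self.predicted_ppm(mz) / 1e6)


def tophat_baseline(spec: Spectrum, width: int = 200) -> Spectrum:
    """Subtract the morphological opening (flat structuring element of
    ``width`` data points) from the intensity and clip at zero.  Removes
    baseline structure broader than ``width`` while preserving narrower
    peaks; idempotent."""
    if width < 1:
        raise ValueError("width must be >= 1 data point")
    if width >= spec.intensity.size:
        raise ValueError("width must be smaller than the spectrum length")
    opened = grey_opening(spec.intensity, size=width, mode="nearest")
    return Spectrum(spec.mz, np.maximum(spec.intensity - opened, 0.0))


def _refine_apex(mz: np.ndarray, y: np.ndarray, i: int) -> float:
    """Quadratic apex interpolation on log intensities (exact for a
    Gaussian peak); falls back to the grid apex at the edges."""
    if i == 0 or i == y.size - 1:
        return float(mz[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    if y0 <= 0 or y2 <= 0 or y1 <= 0:
        return float(mz[i])
    l0, l1, l2 = np.log(y0), np.log(y1), np.log(y2)
    denom = l0 - 2 * l1 + l2
    if denom >= 0:
        return float(mz[i])
    delta = 0.5 * (l0 - l2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    # local spacing is nearly uniform; interpolate linearly in index space
    step = (mz[i + 1] - mz[i - 1]) / 2.0
    return float(mz[i] + delta * step)


def pick_peaks(
    mean_spectrum: Spectrum,
    snr_min: float = 9.0,
    noise=None,
    noise_window: int = 501,
) -> PeakAxis:
    """Pick peaks from a baseline-corrected mean spectrum.

    Noise is the windowed median absolute deviation of the intensity scaled
    by 1.4826 (Gaussian-consistent), unless an explicit ``noise`` scalar or
    vector is given.  Local maxima whose intensity exceeds ``snr_min`` times
    the local noise *strictly* become peaks; the apex m/z is refined by
    3-point quadratic interpolation of log intensities.
    """
    y = mean_spectrum.intensity
    mz = mean_spectrum.mz
    if not y.any():
        return PeakAxis(np.empty(0), np.empty(0, int), np.empty((0, 2), int))
    if noise is None:
        # signal height is measured above the windowed median (residual
        # pedestal of the morphological correction); noise is the windowed
        # MAD scaled to a Gaussian sd
        med = median_filter(y, size=noise_window, mode="nearest")
        mad = median_filter(np.abs(y - med), size=noise_window, mode="nearest")
        noise_vec = 1.4826 * mad
        # windowed MAD collapses near the array edges (replicated samples);
        # floor it at half the global noise level
        global_noise = 1.4826 * float(np.median(np.abs(y - np.median(y))))
        noise_vec = np.maximum(noise_vec, 0.5 * global_noise)
        height = y - med
    else:
        noise_vec = np.broadcast_to(np.asarray(noise, dtype=float), y.shape)
        height = y
    floor = max(float(np.max(noise_vec)) * 1e-9, 1e-12)
    noise_vec = np.maximum(noise_vec, floor)

    maxima = argrelextrema(y, np.greater)[0]
    keep = maxima[height[maxima] / noise_vec[maxima] > snr_min]
    apex_mz, windows = [], []
    for i in keep:
        apex_mz.append(_refine_apex(mz, y, i))
        # half-FWHM window at TOF-like resolving power for provenance
        half = mz[i] * 1e-4
        j0, j1 = np.searchsorted(mz, [mz[i] - half, mz[i] + half])
        windows.append((int(j0), int(max(j1, j0 + 1))))
    return PeakAxis(
        np.asarray(apex_mz),
        keep.astype(int),
        np.asarray(windows, int).reshape(-1, 2),
    )


def segment_tissue(tic: np.ndarray, depth: int = 1, seed: int = 0) -> np.ndarray:
    """On/off-tissue labels from bisecting k-means on log TIC.

    ``depth`` bisections are applied (each split divides the leaf with the
    largest within-cluster sum of squares in two); the leaf with the highest
    mean TIC is labeled on-tissue.  Returns a boolean on-tissue mask.
    """
    tic = np.asarray(tic, dtype=float)
    if tic.size < 2:
        raise ValueError("need >=2 pixels")
    x = np.log1p(tic)
    if np.allclose(x, x[0]):
        warnings.warn("all pixels identical; labeling everything on-tissue")
        return np.ones(tic.size, bool)
    leaves = [np.arange(tic.size)]
    for _ in range(depth):
        sse = [
            ((x[idx] - x[idx].mean()) ** 2).sum() if idx.size > 1 else -1.0
            for idx in leaves
        ]
        target = int(np.argmax(sse))
        idx = leaves.pop(target)
        km = KMeans(n_clusters=2, n_init=5, random_state=seed).fit(x[idx, None])
        leaves.append(idx[km.labels_ == 0])
        leaves.append(idx[km.labels_ == 1])
    means = [tic[idx].mean() if idx.size else -np.inf for idx in leaves]
    on = leaves[int(np.argmax(means))]
    mask = np.zeros(tic.size, bool)
    mask[on] = True
    return mask


def tic_normalize(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Divide each pixel row by its total ion count; zero-TIC pixels are
    excluded and their ids returned."""
    sums = matrix.sum(axis=1)
    zero = sums[sums == 0].index.tolist()
    kept = matrix.loc[sums > 0]
    return kept.div(sums[sums > 0], axis=0), zero


def internal_calibrate(
    axis_mz: np.ndarray,
    references: np.ndarray,
    match_tol_ppm: float = 100.0,
) -> tuple[np.ndarray, CalibrationModel]:
    """Fit an affine ppm-error model to reference ions and correct the axis.

    Each reference mass is matched to the nearest observed peak within
    ``match_tol_ppm``; the signed ppm errors are regressed on m/z by least
    squares and the whole axis corrected as m/(1 + err_ppm(m)/1e6).  With
    fewer than two matches the identity model is returned with a warning.
    """
    axis_mz = np.asarray(axis_mz, dtype=float)
    references = np.asarray(references, dtype=float)
    obs, errs = [], []
    for ref in references:
        if axis_mz.size == 0:
            break
        i = int(np.argmin(np.abs(axis_mz - ref)))
        e = ppm_error(axis_mz[i], ref)
        if abs(e) <= match_tol_ppm:
            obs.append(axis_mz[i])
            errs.append(e)
    if len(obs) < 2:
        warnings.warn("fewer than 2 calibration references matched; axis unchanged")
        return axis_mz.copy(), CalibrationModel(identity=True)
    obs = np.asarray(obs)
    errs = np.asarray(errs)
    b, a = np.polyfit(obs, errs, 1)
    model = CalibrationModel(a=float(a), b=float(b), references_used=obs,
                             residual_ppm=errs - (a + b * obs))
    return model.correct(axis_mz), model


def remove_matrix_peaks(
    matrix: pd.DataFrame, principal_mz: float, r_min: float = 0.5
) -> tuple[pd.DataFrame, list]:
    """Remove matrix-derived peaks by ion-image correlation.

    The principal matrix peak is located as the nearest peak column within
    100 ppm of ``principal_mz``; every peak whose ion image has Pearson
    r >= ``r_min`` with the principal image is removed (the principal peak
    always is).  Zero-variance images get r = 0 and are retained.
    """
    cols = np.asarray(matrix.columns, dtype=float)
    i = int(np.argmin(np.abs(cols - principal_mz)))
    if abs(ppm_error(cols[i], principal_mz)) > 100:
        raise ValueError("principal matrix peak not found within 100 ppm")
    principal_col = matrix.columns[i]
    pimg = matrix[principal_col].values
    psd = pimg.std()
    removed = [principal_col]
    for c in matrix.columns:
        if c == principal_col:
            continue
        img = matrix[c].values
        sd = img.std()
        r = 0.0 if sd == 0 or psd == 0 else float(np.corrcoef(pimg, img)[0, 1])
        if r >= r_min:
            removed.append(c)
    return matrix.drop(columns=removed), removed


def extract_peak_matrix(spectra, mz_axis: np.ndarray, peaks: PeakAxis,
                        pixel_ids=None) -> pd.DataFrame:
    """Sum baseline-corrected intensity inside each peak's half-FWHM window
    for every pixel spectrum in ``spectra`` (iterable of (id, intensity))."""
    rows, ids = [], []
    for pid, y in spectra:
        rows.append([y[j0:j1].sum() for j0, j1 in peaks.window])
        ids.append(pid)
    return pd.DataFrame(rows, index=pixel_ids if pixel_ids is not None else ids,
                        columns=list(peaks.mz))


@dataclass
class MsiPipelineResult:
    matrix: pd.DataFrame                 # on-tissue pixels x retained peak m/z
    peaks: PeakAxis                      # calibrated axis (all picked peaks)
    raw_peak_mz: np.ndarray              # axis before calibration
    calibration: CalibrationModel
    tissue_mask: np.ndarray
    tic: np.ndarray
    removed_matrix_peaks: list
    zero_tic_pixels: list


def preprocess_msi(
    dataset,
    calibration_refs: np.ndarray,
    principal_mz: float,
    tophat_width: int = 200,
    snr_min: float = 9.0,
    r_min: float = 0.5,
    seed: int = 0,
) -> MsiPipelineResult:
    """Full preprocessing pipeline over an :class:`MsiDataset`-like object
    (anything with ``mz``, ``n_pixels`` and ``spectrum(i)``)."""
    mz = dataset.mz
    n = dataset.n_pixels

    # pass 1: per-pixel baseline-corrected TIC
    tic = np.empty(n)
    for i in range(n):
        s = tophat_baseline(Spectrum(mz, dataset.spectrum(i)), tophat_width)
        tic[i] = s.intensity.sum()
    tissue = segment_tissue(tic, seed=seed)

    # pass 2: mean baseline-corrected spectrum over on-tissue pixels
    mean_y = np.zeros(mz.size)
    on_idx = np.flatnonzero(tissue)
    for i in on_idx:
        mean_y += tophat_baseline(Spectrum(mz, dataset.spectrum(i)), tophat_width).intensity
    mean_y /= max(len(on_idx), 1)
    peaks = pick_peaks(Spectrum(mz, mean_y), snr_min=snr_min)

    calibrated_mz, model = internal_calibrate(peaks.mz, calibration_refs)
    raw_mz = peaks.mz
    peaks = PeakAxis(calibrated_mz, peaks.apex_index, peaks.window)

    # pass 3: per-pixel peak intensities over ALL pixels -- matrix-peak
    # image correlation needs the off-tissue pixels, where matrix ions
    # dominate
    def corrected_spectra():
        for i in range(n):
            yield i, tophat_baseline(
                Spectrum(mz, dataset.spectrum(i)), tophat_width
            ).intensity

    mat = extract_peak_matrix(corrected_spectra(), mz, peaks)
    mat, zero_pixels = tic_normalize(mat)
    # columns carry calibrated m/z, so the theoretical principal ion matches
    mat, removed = remove_matrix_peaks(mat, principal_mz, r_min=r_min)
    # restrict to on-tissue pixels for all downstream analysis
    mat = mat.loc[[i for i in mat.index if tissue[i]]]
    return MsiPipelineResult(
        matrix=mat,
        peaks=peaks,
        raw_peak_mz=raw_mz,
        calibration=model,
        tissue_mask=tissue,
        tic=tic,
        removed_matrix_peaks=removed,
        zero_tic_pixels=zero_pixels,
    )
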