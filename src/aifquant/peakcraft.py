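"""Extracted-ion chromatograms, peak detection and integration.

The vendor integration algorithm used on the instrument is proprietary;
this module provides an open equivalent: per-scan summation of centroids
inside a ppm window, local-maximum peak picking on a lightly smoothed
trace with valley splitting, trapezoidal integration on the raw trace,
and a robust (MAD-based) baseline-noise estimate for S/N.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .chemmass import ppm_window
from .spectra_io import Run

__all__ = ["XIC", "Peak", "extract_xic", "detect_peaks", "integrate", "estimate_snr", "coelute"]

#: median absolute deviation -> Gaussian sigma
_MAD_SCALE = 1.4826


@dataclass
class XIC:
    """Intensity-vs-time trace for one m/z window at one MS level."""

    target_mz: float
    tol_ppm: float
    ms_level: int
    rt: np.ndarray  # minutes, ascending
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.rt.shape != self.intensity.shape:
            raise ValueError("rt and intensity must have equal length")
        if self.rt.size > 1 and np.any(np.diff(self.rt) < 0):
            raise ValueError("rt must be ascending")


@dataclass
class Peak:
    apex_rt: float
    left_rt: float
    right_rt: float
    height: float
    area: float
    snr: float = math.nan

    def __post_init__(self) -> None:
        if not (self.left_rt <= self.apex_rt <= self.right_rt):
            raise ValueError("apex must lie within the peak bounds")

    def overlaps(self, other: "Peak") -> bool:
        return self.left_rt <= other.right_rt and other.left_rt <= self.right_rt


def extract_xic(run: Run, mz: float, tol_ppm: float = 5.0, ms_level: int = 1) -> XIC:
    """Per-scan sum of centroid intensities inside the ppm window around
    ``mz``; scans with no matching centroid contribute zero."""
    scans = run.scans(ms_level)
    if not scans:
        raise ValueError(f"run has no scans at MS level {ms_level}")
    lo, hi = ppm_window(mz, tol_ppm)
    rt = np.empty(len(scans))
    intensity = np.empty(len(scans))
    for i, s in enumerate(scans):
        rt[i] = s.rt
        a = np.searchsorted(s.mz_array, lo, side="left")
        b = np.searchsorted(s.mz_array, hi, side="right")
        intensity[i] = s.intensity_array[a:b].sum() if b > a else 0.0
    return XIC(target_mz=mz, tol_ppm=tol_ppm, ms_level=ms_level, rt=rt, intensity=intensity)


def _smooth(y: np.ndarray, width: int = 5) -> np.ndarray:
    if y.size < width:
        return y.copy()
    kernel = np.ones(width) / width
    pad = width // 2
    padded = np.pad(y, pad, mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def integrate(xic: XIC, left_rt: float, right_rt: float) -> float:
    """Trapezoidal area (counts*min) of the raw trace over [left, right]."""
    if right_rt < left_rt:
        raise ValueError("inverted integration bounds")
    if left_rt < xic.rt[0] - 1e-9 or right_rt > xic.rt[-1] + 1e-9:
        raise ValueError("integration bounds outside the trace")
    mask = (xic.rt >= left_rt) & (xic.rt <= right_rt)
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(xic.intensity[mask], xic.rt[mask]))


def detect_peaks(
    xic: XIC, min_snr: float = 3.0, min_points: int = 5, min_fwhm_points: int = 4
) -> list[Peak]:
    """Detect chromatographic peaks.

    Local maxima are searched on a 5-point moving-mean smoothing of the
    trace; peak bounds extend to the flanking valleys or to baseline
    return, and overlapping peaks are split at the valley between them.
    Height and area are measured on the raw trace. Two filters reject
    noise: a peak must exceed ``min_snr`` (height over robust baseline
    noise), and its half-height region must span at least
    ``min_fwhm_points`` contiguous scans — sparse noise centroids form
    narrow spikes, a chromatographic peak is sampled on several
    consecutive scans.
    """
    y = xic.intensity
    if y.size < min_points:
        raise ValueError(f"trace has fewer than {min_points} points")
    if not np.any(y > 0):
        return []
    ys = _smooth(y)
    # candidate apices: strict local maxima of the smoothed trace
    candidates = [
        i
        for i in range(1, ys.size - 1)
        if ys[i] > 0 and ys[i] >= ys[i - 1] and ys[i] > ys[i + 1]
    ]
    if not candidates:
        candidates = [int(np.argmax(ys))]

    bounds = []
    for i in candidates:
        baseline = 0.02 * ys[i]  # baseline return relative to the apex itself
        left = i
        while left > 0 and ys[left - 1] <= ys[left] and ys[left - 1] > baseline:
            left -= 1
        right = i
        while right < ys.size - 1 and ys[right + 1] <= ys[right] and ys[right + 1] > baseline:
            right += 1
        bounds.append([left, i, right])

    # merge apices that share a valley-free interval (plateaux from smoothing)
    merged: list[list[int]] = []
    for b in bounds:
        if merged and b[0] <= merged[-1][2] and b[1] - merged[-1][1] < 3:
            prev = merged[-1]
            if ys[b[1]] > ys[prev[1]]:
                prev[1] = b[1]
            prev[2] = max(prev[2], b[2])
        else:
            merged.append(b)

    # split overlapping neighbours at the valley between their apices
    for a, b in zip(merged, merged[1:]):
        if a[2] >= b[0]:
            valley = a[1] + int(np.argmin(ys[a[1] : b[1] + 1]))
            a[2] = valley
            b[0] = valley

    # two-pass noise estimate: mask only clearly dominant candidates (so
    # that ordinary noise maxima stay in the baseline and do not bias the
    # spread low), then take the robust spread of what remains
    prelim = float(np.std(y))
    masked = np.ones(y.size, dtype=bool)
    for left, _, right in merged:
        if y[left : right + 1].max() > 5.0 * prelim:
            masked[left : right + 1] = False
    if masked.sum() >= 10:
        noise = _robust_noise(y[masked])
    else:
        noise = _robust_noise(y)

    peaks = []
    for left, apex, right in merged:
        if right - left + 1 < 3:
            continue
        raw_apex = left + int(np.argmax(y[left : right + 1]))
        height = float(y[raw_apex])
        if height <= 0:
            continue
        if _fwhm_run(y, left, right, raw_apex, height) < min_fwhm_points:
            continue
        snr = math.inf if noise == 0 else height / noise
        if snr < min_snr:
            continue
        area = integrate(xic, float(xic.rt[left]), float(xic.rt[right]))
        if area <= 0:
            continue
        peaks.append(
            Peak(
                apex_rt=float(xic.rt[raw_apex]),
                left_rt=float(xic.rt[left]),
                right_rt=float(xic.rt[right]),
                height=height,
                area=area,
                snr=snr,
            )
        )
    peaks.sort(key=lambda p: p.apex_rt)
    return peaks


def _fwhm_run(y: np.ndarray, left: int, right: int, apex: int, height: float) -> int:
    """Length of the contiguous run of scans around the apex with raw
    intensity at or above half the peak height."""
    half = 0.5 * height
    a = apex
    while a > left and y[a - 1] >= half:
        a -= 1
    b = apex
    while b < right and y[b + 1] >= half:
        b += 1
    return b - a + 1


def _robust_noise(baseline: np.ndarray) -> float:
    """1.4826 x MAD of the baseline; for sparse centroided noise (mostly
    zero-filled scans) the MAD collapses to 0, so fall back to the plain
    standard deviation. Returns 0 only for a truly flat baseline."""
    if baseline.size == 0:
        return 0.0
    med = np.median(baseline)
    mad = float(_MAD_SCALE * np.median(np.abs(baseline - med)))
    if mad > 0:
        return mad
    return float(np.std(baseline))


def estimate_snr(xic: XIC, peak: Peak, peaks: list[Peak] | None = None) -> float:
    """Peak height over robust baseline spread (1.4826 * MAD) of the trace
    outside all peak bounds; infinite when the baseline is exactly flat."""
    if xic.rt.size < 5:
        raise ValueError("trace too short for a baseline estimate")
    exclude = peaks if peaks else [peak]
    outside = np.ones(xic.rt.size, dtype=bool)
    for p in exclude:
        outside &= ~((xic.rt >= p.left_rt) & (xic.rt <= p.right_rt))
    noise = _robust_noise(xic.intensity[outside])
    if noise == 0:
        return math.inf
    return peak.height / noise


def coelute(peak_a: Peak, peak_b: Peak, rt_tol: float = 0.1) -> bool:
    """True iff the apices are within ``rt_tol`` minutes and the rt
    intervals overlap — the AIF precursor/fragment linking rule."""
    return abs(peak_a.apex_rt - peak_b.apex_rt) <= rt_tol and peak_a.overlaps(peak_b)
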