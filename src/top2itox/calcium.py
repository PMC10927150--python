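"""Calcium-transient feature extraction from ROI fluorescence recordings.

A representative trace per recording (per-ROI F/F0 normalization, then a
frame-wise mean), local-maximum peak detection above the 0.6 quantile of the
smoothed trace, per-transient Gaussian fits for amplitude / rising slope /
decay slope / FWHM, beat rate, and a PCA over per-condition feature means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.decomposition import PCA

GAUSSIAN_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


def representative_trace(rois: np.ndarray, f0_quantile: float = 0.10) -> np.ndarray:
    """Frame-wise mean of per-ROI F/F0 traces (F0 = 10th percentile).

    ROIs whose F0 is not positive are dropped with a warning; an error is
    raised if none survive.
    """
    rois = np.atleast_2d(np.asarray(rois, dtype=float))
    if rois.shape[0] < 1:
        raise ValueError("need at least one ROI")
    f0 = np.quantile(rois, f0_quantile, axis=1)
    keep = f0 > 0
    if not keep.all():
        warnings.warn(f"dropped {np.sum(~keep)} ROI(s) with non-positive F0")
    if not keep.any():
        raise ValueError("all ROIs dropped (non-positive F0)")
    return (rois[keep] / f0[keep, None]).mean(axis=0)


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; near the edges the window is truncated to
    the available frames."""
    x = np.asarray(x, dtype=float)
    if window < 1 or window >= x.size:
        raise ValueError("smooth window must be in [1, len(series))")
    kernel = np.ones(window)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def detect_peaks(
    intensity: np.ndarray,
    smooth_window: int = 5,
    quantile: float = 0.6,
    gate_on_smoothed: bool = True,
) -> np.ndarray:
    """Peak indices of the smoothed trace.

    After moving-average smoothing, index i is a peak iff it is strictly
    greater than both neighbours and greater than the 0.6 quantile of the
    (smoothed, by default) series. Endpoints are never peaks.
    """
    x = np.asarray(intensity, dtype=float)
    if x.size < 3:
        raise ValueError("series too short")
    s = moving_average(x, smooth_window)
    gate_series = s if gate_on_smoothed else x
    thr = np.quantile(gate_series, quantile)
    inner = np.arange(1, x.size - 1)
    is_peak = (s[inner] > s[inner - 1]) & (s[inner] > s[inner + 1]) & (s[inner] > thr)
    return inner[is_peak]


def beat_rate(peak_indices, duration_s: float) -> float:
    """Detected peaks divided by recording duration (events / s)."""
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    return len(peak_indices) / duration_s


def _gaussian(t, base, a, mu, sigma):
    return base + a * np.exp(-((t - mu) ** 2) / (2.0 * sigma**2))


@dataclass
class TransientFeatureSet:
    """Per-transient features and their per-recording means."""

    peak_indices: np.ndarray
    features: pd.DataFrame  # columns amplitude, rising_slope, decay_slope, fwhm_s
    beat_rate: float
    n_failed: int

    def means(self) -> dict:
        m = self.features.mean()
        return {
            "amplitude": float(m["amplitude"]),
            "rising_slope": float(m["rising_slope"]),
            "decay_slope": float(m["decay_slope"]),
            "fwhm_s": float(m["fwhm_s"]),
            "beat_rate": self.beat_rate,
        }


def fit_transients(
    intensity: np.ndarray,
    peak_indices,
    fs: float,
) -> TransientFeatureSet:
    """Gaussian fit of each transient on its trough-to-trough window.

    Amplitude is the fitted Gaussian height; FWHM = 2 sqrt(2 ln 2) sigma / fs
    in seconds; rising/decay slopes are the extreme discrete derivatives
    (times fs) on the rising and decaying flanks. Transients whose fit fails
    to converge, or whose fitted sigma exceeds the local inter-peak interval,
    are excluded and counted.
    """
    x = np.asarray(intensity, dtype=float)
    peaks = np.asarray(peak_indices, dtype=int)
    if peaks.size < 1:
        raise ValueError("need at least one peak")
    n = x.size
    # trough between consecutive peaks; recording edges for terminal peaks
    troughs_left, troughs_right = [], []
    for i, p in enumerate(peaks):
        if i == 0:
            tl = 0
        else:
            seg = x[peaks[i - 1]: p + 1]
            tl = peaks[i - 1] + int(np.argmin(seg))
        if i == peaks.size - 1:
            tr = n - 1
        else:
            seg = x[p: peaks[i + 1] + 1]
            tr = p + int(np.argmin(seg))
        troughs_left.append(tl)
        troughs_right.append(tr)

    gaps = np.diff(peaks)
    rows = []
    n_failed = 0
    for i, p in enumerate(peaks):
        tl, tr = troughs_left[i], troughs_right[i]
        if tr - tl < 4:
            n_failed += 1
            continue
        seg = x[tl: tr + 1]
        t = np.arange(tl, tr + 1, dtype=float)
        base0 = float(seg.min())
        a0 = float(x[p] - base0)
        sigma0 = max((tr - tl) / 6.0, 0.5)
        local_gap = np.inf
        if i > 0:
            local_gap = min(local_gap, gaps[i - 1])
        if i < peaks.size - 1:
            local_gap = min(local_gap, gaps[i])
        if not np.isfinite(local_gap):
            local_gap = n
        try:
            popt, _ = curve_fit(
                _gaussian, t, seg,
                p0=(base0, max(a0, 1e-6), float(p), sigma0),
                bounds=([-np.inf, 0.0, tl, 1e-3], [np.inf, np.inf, tr, float(n)]),
                maxfev=5000,
            )
        except (RuntimeError, ValueError):
            n_failed += 1
            continue
        base, a, mu, sigma = popt
        if sigma > local_gap:
            n_failed += 1
            continue
        rise = float(np.max(np.diff(x[tl: p + 1])) * fs) if p > tl else np.nan
        decay = float(np.min(np.diff(x[p: tr + 1])) * fs) if tr > p else np.nan
        rows.append(
            {
                "peak_index": int(p),
                "amplitude": float(a),
                "rising_slope": rise,
                "decay_slope": decay,
                "fwhm_s": float(GAUSSIAN_FWHM_FACTOR * sigma / fs),
            }
        )
    if not rows:
        raise RuntimeError(
            f"all {peaks.size} transient fits failed or were excluded"
        )
    features = pd.DataFrame(rows).set_index("peak_index")
    duration_s = n / fs
    return TransientFeatureSet(
        peak_indices=peaks,
        features=features,
        beat_rate=beat_rate(peaks, duration_s),
        n_failed=n_failed,
    )


def feature_pca(feature_means: pd.DataFrame):
    """PCA of standardized per-condition feature means.

    Returns (scores DataFrame indexed like the input, explained-variance
    fractions summing to one). Zero-variance features are dropped with a
    warning.
    """
    if feature_means.shape[0] < 2:
        raise ValueError("need at least two conditions")
    x = feature_means.astype(float)
    sd = x.std(ddof=0)
    drop = sd.index[sd == 0]
    if len(drop):
        warnings.warn(f"zero-variance features dropped: {list(drop)}")
        x = x.drop(columns=drop)
        sd = sd.drop(drop)
    z = (x - x.mean()) / sd
    pca = PCA()
    scores = pca.fit_transform(z.to_numpy())
    cols = [f"PC{i+1}" for i in range(scores.shape[1])]
    return (
        pd.DataFrame(scores, index=feature_means.index, columns=cols),
        pca.explained_variance_ratio_,
    )
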