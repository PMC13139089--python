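"""Confidence gating, gap interpolation and pixel→cm calibration.

Pose estimators report a per-frame likelihood for every landmark; frames
below the confidence cutoff are treated as missing, short occlusion gaps
are filled by linear interpolation, and anything longer stays missing so
that event logic never runs on guessed coordinates. The chain
filter → interpolate → calibrate is idempotent.
"""

from __future__ import annotations

import numpy as np

from .config import ConfigError, ExperimentConfig
from .dlc_io import PoseRecording

__all__ = [
    "filter_low_likelihood",
    "interpolate_gaps",
    "median_smooth",
    "calibrate_to_cm",
    "preprocess",
]


def filter_low_likelihood(rec: PoseRecording, cutoff: float) -> PoseRecording:
    """Mark frame-landmarks with likelihood < cutoff as missing (NaN).

    cutoff = 0 removes nothing. Drop counts are accumulated per landmark in
    ``n_dropped``.
    """
    if not 0 <= cutoff <= 1:
        raise ValueError(f"cutoff must be in [0, 1], got {cutoff}")
    out = rec.copy()
    low = out.likelihood < cutoff  # NaN likelihood compares False: already missing
    newly = low & np.isfinite(out.x)
    out.x[low] = np.nan
    out.y[low] = np.nan
    for j, name in enumerate(out.landmarks):
        out.n_dropped[name] = out.n_dropped.get(name, 0) + int(newly[:, j].sum())
    return out


def _fill_gaps_1d(values: np.ndarray, max_gap: int) -> tuple[np.ndarray, int]:
    """Linearly fill interior NaN runs of length <= max_gap. Returns filled count."""
    out = values.copy()
    isnan = np.isnan(out)
    if not isnan.any() or max_gap < 1:
        return out, 0
    filled = 0
    # run boundaries of NaN stretches
    edges = np.flatnonzero(np.diff(np.concatenate(([False], isnan, [False])).astype(int)))
    for start, stop in zip(edges[::2], edges[1::2]):  # [start, stop) is a NaN run
        if start == 0 or stop == len(out):  # never extrapolate
            continue
        gap = stop - start
        if gap > max_gap:
            continue
        x0, x1 = out[start - 1], out[stop]
        t = np.arange(1, gap + 1) / (gap + 1)
        out[start:stop] = x0 + t * (x1 - x0)
        filled += gap
    return out, filled


def interpolate_gaps(rec: PoseRecording, max_gap_s: float) -> PoseRecording:
    """Linearly interpolate missing runs no longer than ``max_gap_s``.

    Leading/trailing gaps are never extrapolated; longer interior runs stay
    missing and remain invalid for all event logic. Interpolated frames get
    likelihood 1.0 (they are as trusted as their endpoints).
    """
    out = rec.copy()
    max_gap = int(np.floor(max_gap_s * out.fps))
    for j, name in enumerate(out.landmarks):
        fx, nx = _fill_gaps_1d(out.x[:, j], max_gap)
        fy, _ = _fill_gaps_1d(out.y[:, j], max_gap)
        out.x[:, j] = fx
        out.y[:, j] = fy
        new = np.isfinite(fx) & np.isnan(rec.x[:, j])
        out.likelihood[new, j] = 1.0
        out.n_interpolated[name] = out.n_interpolated.get(name, 0) + nx
    return out


def median_smooth(rec: PoseRecording, window: int = 3) -> PoseRecording:
    """Optional odd-window running-median smoothing of each coordinate.

    Off by default in the pipeline: smoothing biases threshold crossings.
    NaNs are preserved (a window containing NaN keeps the raw value).
    """
    if window in (0, 1):
        return rec.copy()
    if window % 2 == 0:
        raise ValueError("median window must be odd")
    from scipy.ndimage import median_filter

    out = rec.copy()
    for arr in (out.x, out.y):
        for j in range(arr.shape[1]):
            col = arr[:, j]
            ok = np.isfinite(col)
            smoothed = median_filter(np.where(ok, col, 0.0), size=window, mode="nearest")
            # keep raw value wherever any window member was missing
            good_window = median_filter(ok.astype(float), size=window, mode="nearest") == 1.0
            arr[:, j] = np.where(ok & good_window, smoothed, col)
    return out


def calibrate_to_cm(rec: PoseRecording, config: ExperimentConfig) -> PoseRecording:
    """Convert pixel coordinates to cm by the scalar ``px_per_cm``."""
    if config.px_per_cm <= 0:
        raise ConfigError("px_per_cm must be > 0")
    out = rec.copy()
    if out.unit == "cm":
        return out
    out.x /= config.px_per_cm
    out.y /= config.px_per_cm
    out.unit = "cm"
    return out


def preprocess(rec: PoseRecording, config: ExperimentConfig) -> PoseRecording:
    """Full cleaning chain: confidence gate, gap fill, optional smoothing, cm units.

    The result is the analysis-ready track consumed by the events module;
    ``n_dropped`` / ``n_interpolated`` counters record what was touched.
    """
    out = filter_low_likelihood(rec, config.likelihood_cutoff)
    out = interpolate_gaps(out, config.max_interp_gap_s)
    if config.median_filter_window:
        out = median_smooth(out, config.median_filter_window)
    return calibrate_to_cm(out, config)
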