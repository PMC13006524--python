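"""Shared low-level signal helpers (smoothing, slope, noise scale)."""

from __future__ import annotations

import numpy as np

#: moving-average window for boundary/slope estimation (s)
SMOOTH_WINDOW = 0.2
#: span of the central difference used for slope estimates (s); wider
#: than the smoothing window so sensor noise cannot swamp slope-based
#: criteria at desk-scale sampling rates
SLOPE_SPAN = 0.5
#: slope magnitude below which the force curve counts as settled (mN/s)
SLOPE_THRESHOLD = 0.5


def smoothed(values: np.ndarray, dt: float, window_s: float = SMOOTH_WINDOW) -> np.ndarray:
    w = max(int(round(window_s / dt)), 1)
    if w == 1:
        return values.astype(float)
    kernel = np.ones(w) / w
    return np.convolve(values, kernel, mode="same")


def smoothed_slope(smooth: np.ndarray, dt: float, span_s: float = SLOPE_SPAN) -> np.ndarray:
    """Central-difference slope of a smoothed series over +-span/2."""
    h = max(int(round(0.5 * span_s / dt)), 1)
    if smooth.size <= 2 * h:
        return np.gradient(smooth, dt)
    slope = np.empty_like(smooth)
    slope[h:-h] = (smooth[2 * h :] - smooth[: -2 * h]) / (2 * h * dt)
    slope[:h] = slope[h]
    slope[-h:] = slope[-h - 1]
    return slope


def noise_scale(values: np.ndarray) -> float:
    """Robust per-sample noise SD estimate from first differences."""
    d = np.diff(values)
    if d.size == 0:
        return 0.0
    return float(np.median(np.abs(d)) / (0.6745 * np.sqrt(2.0)))
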