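"""Trend-slope sweat-film onset detection on the 1450 nm PPG channel.

The detector smooths the channel with a trailing moving average, computes a
trailing-window least-squares slope (signal units per minute), normalizes the
slope series by a per-run robust noise scale, and calls onset at the first
time the normalized slope keeps the expected sign above threshold for a
sustained interval.  Trailing (causal) windows ensure the slope at time t
only uses samples up to t, so a change cannot be detected before it starts.

The robust scale is the 25th percentile of |slope| divided by its Gaussian
consistency constant: unlike the plain median absolute deviation it stays a
noise estimate even when a sustained drift occupies most of the run
(breakdown point 75%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

DEFAULT_SMOOTH_S = 180.0
DEFAULT_THRESHOLD = 2.0
DEFAULT_SUSTAIN_S = 90.0
DEFAULT_DIRECTION = -1  # film growth pushes the 1450 nm signal down

# 25th percentile of |Z| for standard normal Z
_Q25_ABS_NORMAL = 0.3186393639643751


class OnsetError(ValueError):
    pass


@dataclass
class TrendSeries:
    """Smoothed signal, rolling slope (units/min) and normalized slope."""

    time_s: np.ndarray
    smoothed: np.ndarray
    slope_per_min: np.ndarray
    normalized_slope: np.ndarray
    smooth_window_s: float
    valid: np.ndarray  # mask of samples whose trailing windows are filled

    def __post_init__(self) -> None:
        n = len(self.time_s)
        for arr in (self.smoothed, self.slope_per_min, self.normalized_slope):
            if len(arr) != n:
                raise OnsetError("trend series length mismatch")


def _trailing_moving_average(x: np.ndarray, width: int) -> np.ndarray:
    kernel = np.ones(width) / width
    padded = np.concatenate([np.full(width - 1, x[0]), x])
    return np.convolve(padded, kernel, mode="valid")


def _trailing_slope(x: np.ndarray, width: int, dt: float) -> np.ndarray:
    """Least-squares slope over the trailing ``width`` samples, per second."""
    t = (np.arange(width) - (width - 1) / 2.0) * dt
    kernel = (t / np.sum(t * t))[::-1]  # correlation via convolution flip
    padded = np.concatenate([np.full(width - 1, x[0]), x])
    return np.convolve(padded, kernel, mode="valid")


def robust_noise_scale(slope: np.ndarray) -> float:
    """Gaussian-consistent noise scale from the 25th percentile of |slope|."""
    if len(slope) == 0:
        return 0.0
    return float(np.quantile(np.abs(slope), 0.25) / _Q25_ABS_NORMAL)


def trend_series(
    signal: np.ndarray,
    fs_hz: float,
    smooth_window_s: float = DEFAULT_SMOOTH_S,
) -> TrendSeries:
    """Trailing moving-average smoothing + trailing rolling slope + scaling."""
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise OnsetError("signal must be 1-D")
    if fs_hz <= 0 or smooth_window_s <= 0:
        raise OnsetError("sampling rate and smoothing window must be > 0")
    n = len(x)
    width = int(round(smooth_window_s * fs_hz))
    if width < 2:
        raise OnsetError("smoothing window shorter than 2 samples")
    if n < 2 * width:
        raise OnsetError("recording must be at least twice the smoothing window")
    dt = 1.0 / fs_hz
    smoothed = _trailing_moving_average(x, width)
    if np.ptp(x) == 0.0:
        slope = np.zeros(n)  # constant signal: avoid rounding residue
    else:
        slope = _trailing_slope(smoothed, width, dt) * 60.0  # per minute
    valid = np.zeros(n, dtype=bool)
    valid[2 * (width - 1):] = True

    scale = robust_noise_scale(slope[valid])
    if scale <= 0:
        normalized = np.zeros_like(slope)
    else:
        normalized = slope / scale
    return TrendSeries(
        time_s=np.arange(n) * dt,
        smoothed=smoothed,
        slope_per_min=slope,
        normalized_slope=normalized,
        smooth_window_s=smooth_window_s,
        valid=valid,
    )


@dataclass
class OnsetCall:
    """Detected onset time (or None), trend direction and confidence."""

    onset_s: float | None
    direction: int
    confidence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise OnsetError("confidence must be in [0, 1]")


def detect_onset(
    trend: TrendSeries,
    direction: int = DEFAULT_DIRECTION,
    threshold: float = DEFAULT_THRESHOLD,
    sustain_s: float = DEFAULT_SUSTAIN_S,
) -> OnsetCall:
    """First sustained excursion of the normalized slope in ``direction``.

    Onset is the first time the normalized slope keeps the expected sign and
    magnitude >= ``threshold`` for at least ``sustain_s`` seconds.
    """
    if direction not in (-1, 1):
        raise OnsetError("direction must be -1 or +1")
    dt = float(trend.time_s[1] - trend.time_s[0]) if len(trend.time_s) > 1 else 1.0
    need = max(int(round(sustain_s / dt)), 1)
    mask = (direction * trend.normalized_slope >= threshold) & trend.valid

    run = 0
    for i, m in enumerate(mask):
        run = run + 1 if m else 0
        if run >= need:
            start = i - need + 1
            return OnsetCall(
                onset_s=float(trend.time_s[start]),
                direction=direction,
                confidence=float(np.mean(mask[start : start + need])),
            )
    return OnsetCall(onset_s=None, direction=direction, confidence=0.0)


def aggregate_trials(
    trends: list[TrendSeries],
    bin_s: float = 300.0,
    subjects_per_group: int = 5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Time-binned mean normalized slope per subject group.

    Returns ``(group_ids, bin_edges_s, surface)`` where ``surface`` has shape
    (groups, bins).  Series are grouped in input order, ``subjects_per_group``
    at a time.
    """
    if not trends:
        raise OnsetError("need at least one trend series")
    if bin_s <= 0 or subjects_per_group < 1:
        raise OnsetError("bin width and group size must be positive")
    t_max = max(tr.time_s[-1] for tr in trends)
    edges = np.arange(0.0, t_max + bin_s, bin_s)
    n_bins = len(edges) - 1
    groups = [
        trends[i : i + subjects_per_group]
        for i in range(0, len(trends), subjects_per_group)
    ]
    surface = np.zeros((len(groups), n_bins))
    kept = []
    for gi, group in enumerate(groups):
        if not group:
            warnings.warn(f"empty subject group {gi}: skipped")
            continue
        kept.append(gi)
        for b in range(n_bins):
            vals = []
            for tr in group:
                sel = (
                    (tr.time_s >= edges[b])
                    & (tr.time_s < edges[b + 1])
                    & tr.valid
                )
                if sel.any():
                    vals.append(tr.normalized_slope[sel].mean())
            if vals:
                surface[gi, b] = float(np.mean(vals))
    return np.array(kept), edges, surface[kept]
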