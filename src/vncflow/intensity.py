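"""Fluorescence intensity dynamics and condensation traces.

Covers the Col4 induction time course (whole-frame mean intensity with a
10-frame moving average at 2-min native resolution), the AP-axis surface
gradient profile (bright intracellular puncta discarded above 70% of the
maximum, then a 200 um walking average), the tail-displacement
condensation trace from clicked tail positions, and the pairing of
intensity with condensation rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ImageStack


@dataclass
class IntensityTrace:
    times: np.ndarray  # min
    intensity: np.ndarray  # a.u., smoothed
    raw: np.ndarray
    smooth_window: int


@dataclass
class CondensationTrace:
    times: np.ndarray  # min
    displacement: np.ndarray  # um, zero at the first frame
    rate: np.ndarray  # um/min, central differences


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; the window shrinks at the edges so the
    output has the input's length."""
    if window <= 1:
        return np.asarray(x, dtype=float).copy()
    s = pd.Series(np.asarray(x, dtype=float))
    return s.rolling(window, center=True, min_periods=1).mean().to_numpy()


def intensity_timecourse(stack: ImageStack, window: int = 10) -> IntensityTrace:
    """Per-frame spatial mean intensity, smoothed with a centered
    ``window``-frame moving average."""
    raw = stack.data.reshape(stack.n_frames, -1).mean(axis=1)
    times = np.arange(stack.n_frames) * stack.frame_interval
    return IntensityTrace(
        times=times,
        intensity=moving_average(raw, window),
        raw=raw,
        smooth_window=window,
    )


def ap_profile(
    image: np.ndarray,
    pixel_size: float,
    discard_fraction: float = 0.7,
    window_um: float = 200.0,
    discard_mode: str = "fraction_of_max",
) -> tuple[np.ndarray, np.ndarray]:
    """Head-to-tail mean intensity profile with bright-signal rejection.

    Pixels brighter than ``discard_fraction`` of the image maximum
    (``discard_mode='fraction_of_max'``, the default — the brightest
    objects are intracellular puncta) or above that quantile of the
    cumulative intensity histogram (``'quantile'``) are excluded; the
    remaining pixels are averaged per AP-axis column and smoothed with a
    walking average of ``window_um``. Returns ``(x_um, profile)``.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("ap_profile expects a single 2-D image")
    if discard_mode == "fraction_of_max":
        cutoff = discard_fraction * img.max()
    elif discard_mode == "quantile":
        cutoff = np.quantile(img, discard_fraction)
    else:
        raise ValueError("discard_mode must be 'fraction_of_max' or 'quantile'")
    if np.ptp(img) == 0:
        keep = np.ones_like(img, dtype=bool)  # no outlier puncta to reject
    else:
        keep = img <= cutoff
    if not keep.any():
        raise ValueError("all pixels discarded by the intensity cutoff")
    with np.errstate(invalid="ignore"):
        col_sum = np.where(keep, img, 0.0).sum(axis=0)
        col_n = keep.sum(axis=0)
        profile = np.where(col_n > 0, col_sum / np.maximum(col_n, 1), np.nan)
    window_px = max(1, int(round(window_um / pixel_size)))
    smoothed = (
        pd.Series(profile).rolling(window_px, center=True, min_periods=1).mean().to_numpy()
    )
    x = np.arange(img.shape[1]) * pixel_size
    return x, smoothed


def tail_displacement(
    points: pd.DataFrame,
    frame_interval: float = 2.0,
    projection: str = "euclidean",
    axis: tuple[float, float] = (1.0, 0.0),
) -> CondensationTrace:
    """Tail displacement relative to the first clicked position.

    ``points`` has columns frame, x, y (or x_um, y_um). ``projection``
    is either 'euclidean' (distance to the first position) or 'ap_axis'
    (signed displacement along ``axis``). The rate is the central
    difference of the displacement trace in um/min.
    """
    cols = {c.lower(): c for c in points.columns}
    xcol = cols.get("x_um", cols.get("x"))
    ycol = cols.get("y_um", cols.get("y"))
    if xcol is None or ycol is None:
        raise ValueError("points table needs x/y (or x_um/y_um) columns")
    pts = points.sort_values(cols.get("frame", "frame"))
    xy = pts[[xcol, ycol]].to_numpy(dtype=float)
    rel = xy - xy[0]
    if projection == "euclidean":
        disp = np.linalg.norm(rel, axis=1)
    elif projection == "ap_axis":
        ax = np.asarray(axis, dtype=float)
        ax = ax / np.linalg.norm(ax)
        disp = rel @ ax
    else:
        raise ValueError("projection must be 'euclidean' or 'ap_axis'")
    times = np.arange(len(disp)) * frame_interval
    rate = np.gradient(disp, times) if len(disp) > 1 else np.zeros_like(disp)
    return CondensationTrace(times=times, displacement=disp, rate=rate)


def intensity_rate_correlation(
    trace: IntensityTrace,
    cond: CondensationTrace,
    smooth_window: int = 10,
    t_range: tuple[float, float] | None = None,
) -> dict[str, object]:
    """Pair Col4 intensity with the condensation rate and report Pearson r.

    Both series are resampled onto their overlapping time base; the rate
    is smoothed with the same moving-average window as the intensity.
    Returns the paired series and ``r`` (NaN, flagged, for zero-variance
    input). No causal claim is attached to the correlation.
    """
    t0 = max(trace.times[0], cond.times[0])
    t1 = min(trace.times[-1], cond.times[-1])
    if t_range is not None:
        t0, t1 = max(t0, t_range[0]), min(t1, t_range[1])
    if t1 <= t0:
        raise ValueError("traces do not overlap in time")
    dt = np.median(np.diff(cond.times))
    t = np.arange(t0, t1 + dt / 2, dt)
    intensity = np.interp(t, trace.times, trace.intensity)
    rate = np.interp(t, cond.times, moving_average(cond.rate, smooth_window))
    degenerate = np.std(intensity) == 0 or np.std(rate) == 0
    if degenerate:
        r, p = np.nan, np.nan
    else:
        r, p = stats.pearsonr(intensity, rate)
    return {
        "times": t,
        "intensity": intensity,
        "rate": rate,
        "pearson_r": float(r) if not degenerate else np.nan,
        "p_value": float(p) if not degenerate else np.nan,
        "zero_variance": bool(degenerate),
    }
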