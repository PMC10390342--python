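"""Photobleached-stripe tracking along the tissue midline.

Two midline intensity profiles (immediately after bleaching and 30 min
later) are each normalized to their own mean, smoothed with a 150-point
walking average, and searched for local minima — the stripe centres.
Minima are paired by rank order between the timepoints and the per-stripe
displacement is ``position_t1 - position_t0`` on the head-to-tail axis,
so head-ward motion gives a negative displacement. A graded magnitude
from head to tail stripes is the anisotropic-motion readout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .intensity import moving_average

#: Default minimum prominence of a detected stripe, as a fraction of the
#: smoothed profile's range.
DEFAULT_PROMINENCE_FRACTION = 0.05


@dataclass
class StripeAnalysis:
    x: np.ndarray  # common spatial axis, um
    profile_t0: np.ndarray  # normalized + smoothed
    profile_t1: np.ndarray
    minima_t0: np.ndarray  # stripe centre positions, um
    minima_t1: np.ndarray
    displacements: np.ndarray  # um, negative = head-ward
    smooth_points: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stripe_index": np.arange(len(self.displacements)),
                "pos_t0_um": self.minima_t0,
                "pos_t1_um": self.minima_t1,
                "displacement_um": self.displacements,
            }
        )


def _refine_parabolic(x: np.ndarray, y: np.ndarray, idx: int) -> float:
    """Sub-sample minimum localization by a parabola through three points."""
    if idx <= 0 or idx >= len(y) - 1:
        return float(x[idx])
    y0, y1, y2 = y[idx - 1], y[idx], y[idx + 1]
    denom = y0 - 2 * y1 + y2
    if denom <= 0:
        return float(x[idx])
    offset = 0.5 * (y0 - y2) / denom
    dx = x[1] - x[0]
    return float(x[idx] + np.clip(offset, -1, 1) * dx)


def detect_stripe_minima(
    x: np.ndarray,
    profile: np.ndarray,
    smooth_points: int = 150,
    prominence_fraction: float = DEFAULT_PROMINENCE_FRACTION,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalize a profile to its mean, smooth, and locate stripe minima.

    Returns (minima positions in um, the normalized smoothed profile).
    """
    prof = np.asarray(profile, dtype=float)
    mean = prof.mean()
    if mean <= 0:
        raise ValueError("profile mean must be positive for normalization")
    norm = moving_average(prof / mean, smooth_points)
    rng = norm.max() - norm.min()
    if rng == 0:
        return np.array([]), norm
    peaks, _ = find_peaks(-norm, prominence=prominence_fraction * rng)
    positions = np.array([_refine_parabolic(x, norm, p) for p in peaks])
    order = np.argsort(positions)
    return positions[order], norm


def stripe_analysis(
    x: np.ndarray,
    profile_t0: np.ndarray,
    profile_t1: np.ndarray,
    smooth_points: int = 150,
    prominence_fraction: float = DEFAULT_PROMINENCE_FRACTION,
    expected_stripes: int | None = None,
) -> StripeAnalysis:
    """Detect stripe centres at both timepoints and pair them by rank.

    Raises if the two timepoints yield different minima counts (naming the
    counts); warns if ``expected_stripes`` is given and not matched.
    """
    x = np.asarray(x, dtype=float)
    m0, n0 = detect_stripe_minima(x, profile_t0, smooth_points, prominence_fraction)
    m1, n1 = detect_stripe_minima(x, profile_t1, smooth_points, prominence_fraction)
    if len(m0) != len(m1):
        raise ValueError(
            f"unequal stripe counts between timepoints: {len(m0)} at t0, {len(m1)} at t1"
        )
    if expected_stripes is not None and len(m0) != expected_stripes:
        warnings.warn(
            f"expected {expected_stripes} stripes, detected {len(m0)}", stacklevel=2
        )
    return StripeAnalysis(
        x=x,
        profile_t0=n0,
        profile_t1=n1,
        minima_t0=m0,
        minima_t1=m1,
        displacements=m1 - m0,
        smooth_points=smooth_points,
    )


def linescan_profile(image: np.ndarray, thickness_px: int = 100, axis: int = 0) -> np.ndarray:
    """Mean over a midline band of the given thickness, emulating a thick
    linescan perpendicular to the bleach stripes."""
    img = np.asarray(image, dtype=float)
    mid = img.shape[axis] // 2
    lo = max(0, mid - thickness_px // 2)
    hi = min(img.shape[axis], mid + thickness_px // 2)
    sl = [slice(None)] * img.ndim
    sl[axis] = slice(lo, hi)
    return img[tuple(sl)].mean(axis=axis)
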