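"""Windowed normalized cross-correlation PIV with spatiotemporal interpolation.

A source window centred at each grid node in frame ``t`` is matched against
a larger search window in frame ``t+1`` by zero-mean normalized
cross-correlation (the correlation coefficient, so the validity threshold
lives in [0, 1]); the correlation peak, refined to sub-pixel precision by a
three-point Gaussian fit per axis, gives the displacement at that node.
The raw field is then smoothed by a truncated-Gaussian weighted mean over
valid vectors in space and time.

Three named parameter presets cover the imaging modalities used for the
tissue-flow measurements:

=================  ========  ========  ======  ==========
preset             source    search    grid    threshold
=================  ========  ========  ======  ==========
confocal_whole     9 um      16 um     5 um    0.5
confocal_hires     2 um      4 um      1 um    0.3
mosaic             5 um      10 um     3 um    0.5
=================  ========  ========  ======  ==========
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import match_template

from .containers import DisplacementFieldSeries, ImageStack


@dataclass(frozen=True)
class PIVParams:
    """Window geometry (in um) and the peak-correlation validity threshold."""

    source_size: float
    search_size: float
    grid_size: float
    corr_threshold: float
    modality_label: str = ""

    def __post_init__(self) -> None:
        if not (self.search_size > self.source_size > 0):
            raise ValueError("require search_size > source_size > 0")
        if self.grid_size <= 0:
            raise ValueError("grid_size must be > 0")
        if not (0.0 <= self.corr_threshold <= 1.0):
            raise ValueError("corr_threshold must be in [0, 1]")


@dataclass(frozen=True)
class InterpolationKernel:
    """Truncated-Gaussian smoothing kernel.

    ``spatial_size``/``spatial_sigma`` are in um; the temporal pair is in
    frames when ``temporal_unit == 'frames'`` and in minutes otherwise
    (converted with the field's frame interval at application time).
    Kernel *size* is the full truncation width.
    """

    spatial_size: float
    spatial_sigma: float
    temporal_size: float
    temporal_sigma: float
    temporal_unit: str = "min"

    def __post_init__(self) -> None:
        if not (self.spatial_size >= self.spatial_sigma > 0):
            raise ValueError("require spatial_size >= spatial_sigma > 0")
        if not (self.temporal_size >= self.temporal_sigma > 0):
            raise ValueError("require temporal_size >= temporal_sigma > 0")
        if self.temporal_unit not in ("min", "frames"):
            raise ValueError("temporal_unit must be 'min' or 'frames'")


PIV_PRESETS: dict[str, tuple[PIVParams, InterpolationKernel]] = {
    "confocal_whole": (
        PIVParams(9.0, 16.0, 5.0, 0.5, "confocal_whole"),
        InterpolationKernel(50.0, 10.0, 90.0, 40.0, "min"),
    ),
    "confocal_hires": (
        PIVParams(2.0, 4.0, 1.0, 0.3, "confocal_hires"),
        InterpolationKernel(10.0, 2.0, 5.0, 2.0, "frames"),
    ),
    "mosaic": (
        PIVParams(5.0, 10.0, 3.0, 0.5, "mosaic"),
        InterpolationKernel(50.0, 10.0, 90.0, 40.0, "min"),
    ),
}


def get_preset(name: str) -> tuple[PIVParams, InterpolationKernel]:
    """Look up a named (PIVParams, InterpolationKernel) preset."""
    try:
        return PIV_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown PIV preset {name!r}; available: {sorted(PIV_PRESETS)}"
        ) from None


def _odd_px(size_um: float, pixel_size: float) -> int:
    """Convert a window size in um to the nearest odd pixel count (>= 3)."""
    n = int(round(size_um / pixel_size))
    if n % 2 == 0:
        n += 1
    return max(n, 3)


def _gaussian_subpixel(cm1: float, c0: float, cp1: float) -> float:
    """Three-point Gaussian peak interpolation; ties break toward zero offset."""
    if not (c0 >= cm1 and c0 >= cp1):
        return 0.0
    if cm1 <= 0 or c0 <= 0 or cp1 <= 0:
        # fall back to a parabolic fit when logs are undefined
        denom = cm1 - 2 * c0 + cp1
        return 0.0 if denom == 0 else float(np.clip(0.5 * (cm1 - cp1) / denom, -1, 1))
    lm1, l0, lp1 = np.log(cm1), np.log(c0), np.log(cp1)
    denom = lm1 - 2 * l0 + lp1
    if denom == 0:
        return 0.0
    return float(np.clip(0.5 * (lm1 - lp1) / denom, -1, 1))


def compute_piv(
    stack: ImageStack,
    params: PIVParams,
    roi_mask: np.ndarray | None = None,
) -> DisplacementFieldSeries:
    """Windowed ZNCC PIV between consecutive frames of ``stack``.

    Grid nodes are spaced ``grid_size`` um apart at positions where the
    search window fits inside the image. Vectors with peak correlation
    below ``corr_threshold``, with a zero-variance source window, or whose
    node falls outside ``roi_mask`` (a (H, W) boolean array) are flagged
    invalid. Returned displacements are in um per frame pair.
    """
    if stack.n_frames < 2:
        raise ValueError("PIV needs at least two frames")
    px = stack.pixel_size
    src_px = _odd_px(params.source_size, px)
    srch_px = _odd_px(params.search_size, px)
    if srch_px <= src_px:
        srch_px = src_px + 2
    H, W = stack.frame_shape
    if srch_px > min(H, W):
        raise ValueError(
            f"search window ({srch_px} px) larger than image ({H}x{W} px)"
        )
    half_src = src_px // 2
    half_srch = srch_px // 2
    margin = half_srch  # node must allow the search window to fit

    grid_step_px = max(1, int(round(params.grid_size / px)))
    nodes_x = np.arange(margin, W - margin, grid_step_px)
    nodes_y = np.arange(margin, H - margin, grid_step_px)
    if len(nodes_x) == 0 or len(nodes_y) == 0:
        raise ValueError("image too small for the requested window sizes")

    T = stack.n_frames - 1
    ny, nx = len(nodes_y), len(nodes_x)
    u = np.zeros((T, ny, nx))
    v = np.zeros((T, ny, nx))
    corr = np.zeros((T, ny, nx))
    valid = np.zeros((T, ny, nx), dtype=bool)
    data = np.asarray(stack.data, dtype=float)

    for t in range(T):
        a, b = data[t], data[t + 1]
        for j, cy in enumerate(nodes_y):
            for i, cx in enumerate(nodes_x):
                if roi_mask is not None and not roi_mask[cy, cx]:
                    continue
                src = a[cy - half_src : cy + half_src + 1, cx - half_src : cx + half_src + 1]
                if src.std() == 0:
                    continue  # featureless window: invalid, not NaN
                srch = b[
                    cy - half_srch : cy + half_srch + 1,
                    cx - half_srch : cx + half_srch + 1,
                ]
                if srch.std() == 0:
                    continue
                cc = match_template(srch, src, pad_input=False)
                pk = np.unravel_index(np.argmax(cc), cc.shape)
                peak = float(cc[pk])
                if peak < params.corr_threshold:
                    continue
                # integer displacement: peak index relative to the centred match
                center = half_srch - half_src
                dy = pk[0] - center
                dx = pk[1] - center
                # 3-point sub-pixel refinement per axis; an exact match
                # (peak correlation 1) needs no refinement, and fitting one
                # would only add model bias
                sy, sx = 0.0, 0.0
                if peak < 1.0 - 1e-9:
                    if 0 < pk[0] < cc.shape[0] - 1:
                        sy = _gaussian_subpixel(
                            cc[pk[0] - 1, pk[1]], peak, cc[pk[0] + 1, pk[1]]
                        )
                    if 0 < pk[1] < cc.shape[1] - 1:
                        sx = _gaussian_subpixel(
                            cc[pk[0], pk[1] - 1], peak, cc[pk[0], pk[1] + 1]
                        )
                u[t, j, i] = (dx + sx) * px
                v[t, j, i] = (dy + sy) * px
                corr[t, j, i] = peak
                valid[t, j, i] = True

    return DisplacementFieldSeries(
        x=nodes_x * px,
        y=nodes_y * px,
        u=u,
        v=v,
        valid=valid,
        corr=corr,
        frame_interval=stack.frame_interval,
        interpolated=False,
    )


def _truncated_gaussian(half_width: int, sigma: float) -> np.ndarray:
    offs = np.arange(-half_width, half_width + 1, dtype=float)
    return np.exp(-0.5 * (offs / sigma) ** 2)


def interpolate_field_series(
    fields: DisplacementFieldSeries, kernel: InterpolationKernel
) -> DisplacementFieldSeries:
    """Truncated-Gaussian weighted mean over valid vectors in space and time.

    Each output vector is the weighted mean of the valid input vectors
    within the truncation window (kernel size = full truncation width);
    weights are normalized over contributing vectors only, so the result
    is a convex combination and nodes with no valid contributor stay
    invalid. Output keeps the input grid and frame count.
    """
    spacing = fields.grid_spacing
    if spacing <= 0:
        raise ValueError("field grid has no spacing information")
    if kernel.spatial_size < spacing:
        warnings.warn(
            "interpolation kernel smaller than grid spacing; "
            "effectively nearest-neighbour",
            stacklevel=2,
        )
    half_sp = max(1, int(round(kernel.spatial_size / 2.0 / spacing)))
    sigma_sp = kernel.spatial_sigma / spacing

    if kernel.temporal_unit == "frames":
        t_size_frames = kernel.temporal_size
        t_sigma_frames = kernel.temporal_sigma
    else:
        t_size_frames = kernel.temporal_size / fields.frame_interval
        t_sigma_frames = kernel.temporal_sigma / fields.frame_interval
    half_t = max(1, int(round(t_size_frames / 2.0)))
    sigma_t = max(t_sigma_frames, 1e-9)

    w_sp = _truncated_gaussian(half_sp, sigma_sp)
    w_t = _truncated_gaussian(half_t, sigma_t)

    m = fields.valid.astype(float)
    u0 = np.where(fields.valid, fields.u, 0.0)
    v0 = np.where(fields.valid, fields.v, 0.0)

    def smooth(arr: np.ndarray) -> np.ndarray:
        out = ndimage.correlate1d(arr, w_t, axis=0, mode="constant", cval=0.0)
        out = ndimage.correlate1d(out, w_sp, axis=1, mode="constant", cval=0.0)
        out = ndimage.correlate1d(out, w_sp, axis=2, mode="constant", cval=0.0)
        return out

    wsum = smooth(m)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(wsum > 0, smooth(u0) / wsum, 0.0)
        v = np.where(wsum > 0, smooth(v0) / wsum, 0.0)

    return DisplacementFieldSeries(
        x=fields.x,
        y=fields.y,
        u=u,
        v=v,
        valid=wsum > 0,
        corr=None,
        frame_interval=fields.frame_interval,
        interpolated=True,
    )
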