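"""Kymographs and flow-coherence statistics over displacement-field series.

Two coherence measures are provided. The *local alignment* coherence
samples 256 random reference vectors per frame from the raw
(non-interpolated) field and averages the norm of the cosine of the angle
between each reference and its neighbours within an 8 um radius — values
near 1 indicate locally coherent motion regardless of its global
direction. The *directional* coherence compares an 11x11 sample of the
interpolated field on a 3 um-spaced grid against the tail-to-head
reference axis using the signed cosine — values near 1 indicate motion in
the tail-to-head direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .containers import DisplacementFieldSeries


@dataclass
class Kymograph:
    """AP-position x time matrix of a per-frame field statistic.

    ``values[p, t]`` is the mean over valid vectors in the AP bin at
    ``positions[p]`` during frame ``t``; bins with no valid vector are NaN.
    Speeds are reported in um/min.
    """

    positions: np.ndarray  # um along the AP axis
    values: np.ndarray  # (n_positions, n_frames)
    mode: str

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class CoherenceSeries:
    """Per-frame coherence values with their smoothing metadata.

    The norm variant lives in [0, 1]; the signed variant in [-1, 1].
    Frames with no contributing vector are NaN.
    """

    values: np.ndarray  # (n_frames,)
    variant: str  # "norm" or "signed"
    smooth_frames: int = 1


def _walking_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges; NaN-aware."""
    if window <= 1:
        return x.copy()
    out = np.empty_like(x, dtype=float)
    half = window // 2
    n = len(x)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        seg = x[lo:hi]
        good = ~np.isnan(seg)
        out[i] = seg[good].mean() if good.any() else np.nan
    return out


def kymograph(fields: DisplacementFieldSeries, mode: str = "speed") -> Kymograph:
    """Average the field column-wise along the AP axis for each frame.

    ``mode='speed'`` averages |v| in um/min; ``mode='x_component'``
    averages the signed x-component in um/min.
    """
    if mode not in ("speed", "x_component"):
        raise ValueError("mode must be 'speed' or 'x_component'")
    if fields.n_frames == 0:
        raise ValueError("empty field series")
    if mode == "speed":
        quantity = np.hypot(fields.u, fields.v) / fields.frame_interval
    else:
        quantity = fields.u / fields.frame_interval
    quantity = np.where(fields.valid, quantity, np.nan)
    with np.errstate(invalid="ignore"):
        # mean over rows (y) -> (T, nx); transpose to (nx, T)
        counts = fields.valid.sum(axis=1)
        sums = np.nansum(quantity, axis=1)
        col = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return Kymograph(positions=fields.x.copy(), values=col.T, mode=mode)


def local_alignment_coherence(
    fields: DisplacementFieldSeries,
    n_samples: int = 256,
    radius_um: float = 8.0,
    smooth_frames: int = 5,
    seed: int = 0,
) -> CoherenceSeries:
    """Mean |cos(theta)| between sampled reference vectors and their neighbours.

    Per frame: ``n_samples`` reference locations are drawn uniformly from
    the valid non-zero vectors (without replacement when enough exist,
    with replacement otherwise); each reference is compared against every
    other valid non-zero vector within ``radius_um``, excluding itself;
    the per-reference means are averaged and the per-frame series smoothed
    with a centered walking average over ``smooth_frames`` frames.
    """
    if fields.interpolated:
        raise ValueError("local alignment coherence expects the raw, non-interpolated field")
    rng = np.random.default_rng(seed)
    xx, yy = np.meshgrid(fields.x, fields.y)
    pts_all = np.column_stack([xx.ravel(), yy.ravel()])

    values = np.full(fields.n_frames, np.nan)
    for t in range(fields.n_frames):
        uu = fields.u[t].ravel()
        vv = fields.v[t].ravel()
        ok = fields.valid[t].ravel() & (np.hypot(uu, vv) > 0)
        if ok.sum() < 2:
            continue
        pts = pts_all[ok]
        vecs = np.column_stack([uu[ok], vv[ok]])
        unit = vecs / np.linalg.norm(vecs, axis=1, keepdims=True)
        n_ok = len(pts)
        if n_ok >= n_samples:
            refs = rng.choice(n_ok, size=n_samples, replace=False)
        else:
            refs = rng.choice(n_ok, size=n_samples, replace=True)
        tree = cKDTree(pts)
        neighbor_lists = tree.query_ball_point(pts[refs], r=radius_um)
        per_ref = []
        for ref_idx, nbrs in zip(refs, neighbor_lists):
            nbrs = [n for n in nbrs if n != ref_idx]
            if not nbrs:
                continue  # contributes nothing
            cos = unit[nbrs] @ unit[ref_idx]
            per_ref.append(np.abs(cos).mean())
        if per_ref:
            values[t] = float(np.mean(per_ref))
    return CoherenceSeries(
        values=_walking_average(values, smooth_frames),
        variant="norm",
        smooth_frames=smooth_frames,
    )


def directional_coherence(
    fields: DisplacementFieldSeries,
    reference_axis: tuple[float, float] = (-1.0, 0.0),
    grid_shape: tuple[int, int] = (11, 11),
    grid_spacing_um: float = 3.0,
    roi_center: tuple[float, float] | None = None,
) -> CoherenceSeries:
    """Mean signed cos(theta) between sampled vectors and the reference axis.

    An ``11 x 11`` sampling grid with 3 um spacing, centred on
    ``roi_center`` (field centre by default), is interpolated bilinearly
    from the field; degenerate (zero or invalid) samples are excluded and
    an all-degenerate frame is NaN.
    """
    ref = np.asarray(reference_axis, dtype=float)
    nrm = np.linalg.norm(ref)
    if nrm == 0:
        raise ValueError("reference_axis must be non-zero")
    ref = ref / nrm
    if roi_center is None:
        roi_center = (
            float((fields.x[0] + fields.x[-1]) / 2),
            float((fields.y[0] + fields.y[-1]) / 2),
        )
    gy = (np.arange(grid_shape[0]) - (grid_shape[0] - 1) / 2) * grid_spacing_um
    gx = (np.arange(grid_shape[1]) - (grid_shape[1] - 1) / 2) * grid_spacing_um
    sample_x = np.clip(roi_center[0] + gx, fields.x[0], fields.x[-1])
    sample_y = np.clip(roi_center[1] + gy, fields.y[0], fields.y[-1])
    sx, sy = np.meshgrid(sample_x, sample_y)

    from scipy.interpolate import RegularGridInterpolator

    values = np.full(fields.n_frames, np.nan)
    for t in range(fields.n_frames):
        u = np.where(fields.valid[t], fields.u[t], np.nan)
        v = np.where(fields.valid[t], fields.v[t], np.nan)
        fi_u = RegularGridInterpolator((fields.y, fields.x), u, bounds_error=False)
        fi_v = RegularGridInterpolator((fields.y, fields.x), v, bounds_error=False)
        pts = np.column_stack([sy.ravel(), sx.ravel()])
        su = fi_u(pts)
        sv = fi_v(pts)
        mag = np.hypot(su, sv)
        ok = np.isfinite(mag) & (mag > 0)
        if not ok.any():
            continue
        cos = (su[ok] * ref[0] + sv[ok] * ref[1]) / mag[ok]
        values[t] = float(cos.mean())
    return CoherenceSeries(values=values, variant="signed", smooth_frames=1)
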