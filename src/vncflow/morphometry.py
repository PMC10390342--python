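"""Tissue morphometry: elliptical-cylinder geometry, ellipse-fit
eccentricity of cross-sections, and z-interpolation of sparse outline
annotations into a volume.

The tissue is idealized as an elliptical cylinder of length ``L`` whose
cross-section has width ``W`` and height ``H``:

    volume       = pi (W/2) (H/2) L
    surface area = perimeter(W/2, H/2) L + 2 pi (W/2) (H/2)

with the ellipse perimeter by Ramanujan's first approximation
``pi [3(a+b) - sqrt((3a+b)(a+3b))]`` (relative error < 1e-4 for the
aspect ratios that occur here). End caps are included in the surface area,
so area *changes* rather than absolute areas are the meaningful readout.

Cross-section eccentricity is ``e = c/a = sqrt(a^2 - b^2)/a``, the ratio
of the inter-focal distance of the fitted ellipse to its major-axis
length: 0 for a circle, approaching 1 for a line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.draw import polygon as draw_polygon
from skimage.measure import EllipseModel


@dataclass
class TissueDims:
    """Length, width, and height of the tissue in um at one timepoint."""

    L: float
    W: float
    H: float
    label: str = ""

    def __post_init__(self) -> None:
        if min(self.L, self.W, self.H) <= 0:
            raise ValueError("all dimensions must be positive")


@dataclass
class EllipseFit:
    center: tuple[float, float]
    a: float  # semi-major, um
    b: float  # semi-minor, um
    orientation: float  # radians, major axis vs x
    eccentricity: float
    residual_rms: float


def ellipse_perimeter(a: float, b: float) -> float:
    """Ramanujan's first approximation to the ellipse perimeter."""
    if a <= 0 or b <= 0:
        raise ValueError("semi-axes must be positive")
    return float(np.pi * (3 * (a + b) - np.sqrt((3 * a + b) * (a + 3 * b))))


def cylinder_geometry(dims: TissueDims) -> dict[str, float]:
    """Volume (um^3) and closed surface area (um^2) of the idealized tissue."""
    a, b = dims.W / 2.0, dims.H / 2.0
    volume = np.pi * a * b * dims.L
    area = ellipse_perimeter(a, b) * dims.L + 2 * np.pi * a * b
    return {"volume": float(volume), "surface_area": float(area)}


def fit_ellipse(points: np.ndarray) -> EllipseFit:
    """Direct algebraic least-squares ellipse fit of an outline.

    ``points`` is (n, 2) with n >= 6 non-collinear points. The outline is
    centred (centroid removed) before fitting for numerical conditioning;
    the reported centre is in the original frame.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 6:
        raise ValueError("need an (n >= 6, 2) point array")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    # collinearity check via the singular values of the centred cloud
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise ValueError("points are collinear; the e -> 1 limit is not fittable")
    if hasattr(EllipseModel, "from_estimate"):
        model = EllipseModel.from_estimate(centered)
        if not model:
            raise ValueError("ellipse fit failed")
        xc, yc = model.center
        a, b = model.axis_lengths
        theta = model.theta
    else:  # scikit-image < 0.26
        model = EllipseModel()
        if not model.estimate(centered):
            raise ValueError("ellipse fit failed")
        xc, yc, a, b, theta = model.params
    if a < b:
        a, b = b, a
        theta = theta + np.pi / 2
    theta = (theta + np.pi / 2) % np.pi - np.pi / 2  # wrap to (-pi/2, pi/2]
    ecc = float(np.sqrt(max(a**2 - b**2, 0.0)) / a)
    rms = float(np.sqrt(np.mean(model.residuals(centered) ** 2)))
    return EllipseFit(
        center=(float(xc + centroid[0]), float(yc + centroid[1])),
        a=float(a),
        b=float(b),
        orientation=float(theta),
        eccentricity=ecc,
        residual_rms=rms,
    )


def align_outline(points: np.ndarray, fit: EllipseFit | None = None) -> np.ndarray:
    """Centre an outline and rotate its major axis onto the horizontal axis."""
    pts = np.asarray(points, dtype=float)
    if fit is None:
        fit = fit_ellipse(pts)
    shifted = pts - np.asarray(fit.center)
    c, s = np.cos(-fit.orientation), np.sin(-fit.orientation)
    rot = np.array([[c, -s], [s, c]])
    return shifted @ rot.T


def _polygon_sdf(poly: np.ndarray, grid_shape: tuple[int, int], origin, px: float) -> np.ndarray:
    """Signed distance (positive inside) of a simple polygon on a raster grid."""
    rr = (poly[:, 1] - origin[1]) / px
    cc = (poly[:, 0] - origin[0]) / px
    mask = np.zeros(grid_shape, dtype=bool)
    r_idx, c_idx = draw_polygon(rr, cc, shape=grid_shape)
    mask[r_idx, c_idx] = True
    if not mask.any() or mask.all():
        raise ValueError("polygon does not rasterize inside the grid")
    d_out = ndimage.distance_transform_edt(~mask)
    d_in = ndimage.distance_transform_edt(mask)
    return (d_in - d_out) * px


def _check_simple(poly: np.ndarray) -> None:
    """Reject self-intersecting polygons (O(n^2) segment test)."""
    n = len(poly)
    segs = [(poly[i], poly[(i + 1) % n]) for i in range(n)]

    def cross2(u, v) -> float:
        return u[0] * v[1] - u[1] * v[0]

    def intersects(p1, p2, p3, p4) -> bool:
        d1 = cross2(p4 - p3, p1 - p3)
        d2 = cross2(p4 - p3, p2 - p3)
        d3 = cross2(p2 - p1, p3 - p1)
        d4 = cross2(p2 - p1, p4 - p1)
        return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))

    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue  # adjacent through the wrap-around
            if intersects(*segs[i], *segs[j]):
                raise ValueError("polygon is self-intersecting")


def interpolate_annotations_z(
    polygons: dict[float, np.ndarray],
    z_spacing: float = 1.0,
    raster_px: float = 0.25,
) -> dict[str, object]:
    """Shape-based interpolation of sparse polygon annotations along z.

    ``polygons`` maps annotated z positions (um) to (n, 2) outline arrays
    (um). Intermediate slices at ``z_spacing`` steps are obtained by
    linear interpolation of the polygons' signed-distance transforms;
    volume is the trapezoidal integral of slice areas over z. Returns the
    boolean slice masks, their z positions, and the volume in um^3.
    """
    if len(polygons) < 2:
        raise ValueError("need at least two annotated planes")
    zs = np.array(sorted(polygons))
    polys = [np.asarray(polygons[z], dtype=float) for z in zs]
    for poly in polys:
        if len(poly) < 3:
            raise ValueError("polygons need at least 3 vertices")
        _check_simple(poly)

    allpts = np.vstack(polys)
    lo = allpts.min(axis=0) - 4 * raster_px
    hi = allpts.max(axis=0) + 4 * raster_px
    ncols = int(np.ceil((hi[0] - lo[0]) / raster_px)) + 1
    nrows = int(np.ceil((hi[1] - lo[1]) / raster_px)) + 1
    shape = (nrows, ncols)
    sdfs = [_polygon_sdf(p, shape, lo, raster_px) for p in polys]

    slice_z = np.arange(zs[0], zs[-1] + z_spacing / 2, z_spacing)
    masks = []
    areas = []
    for z in slice_z:
        k = min(np.searchsorted(zs, z, side="right"), len(zs) - 1)
        z0, z1 = zs[k - 1], zs[k]
        w = 0.0 if z1 == z0 else (z - z0) / (z1 - z0)
        sdf = (1 - w) * sdfs[k - 1] + w * sdfs[k]
        mask = sdf > 0
        masks.append(mask)
        areas.append(mask.sum() * raster_px**2)
    volume = float(np.trapezoid(areas, slice_z))
    return {
        "slice_z": slice_z,
        "masks": np.stack(masks),
        "slice_areas": np.asarray(areas),
        "volume": volume,
    }
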