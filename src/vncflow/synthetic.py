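"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the statistical structure of the real measurements:
a speckled Col4 surface texture advected by a prescribed flow with a
tail-to-head speed gradient, glial cell tracks drifting with the tissue,
Hertzian force-indentation curves, elliptical tissue cross-sections,
photobleached stripe profiles, and a two-phase condensation time course
(isovolumetric phase 1, volume-losing phase 2) with exponential Col4
induction and a sigmoidal tail displacement.

All randomness is driven by explicit integer seeds; identical parameters
and seed give bit-identical outputs.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .containers import ForceCurve, ImageStack

logger = logging.getLogger(__name__)

FlowField = Callable[[np.ndarray, np.ndarray, float], tuple[np.ndarray, np.ndarray]]

FLOW_KINDS = ("uniform", "tail_to_head_gradient", "rotational", "zero")


@dataclass
class FlowSpec:
    """Prescribed tissue-surface flow, in um/min.

    ``axis`` is the unit tail-to-head direction (direction of motion);
    for ``tail_to_head_gradient`` the speed decays linearly from
    ``peak_speed`` at the tail end to zero over ``gradient_length``.
    """

    kind: str = "zero"
    peak_speed: float = 0.0  # um/min
    gradient_length: float = 100.0  # um
    axis: tuple[float, float] = (-1.0, 0.0)

    def __post_init__(self) -> None:
        if self.kind not in FLOW_KINDS:
            raise ValueError(f"unknown flow kind {self.kind!r}; one of {FLOW_KINDS}")
        if self.peak_speed < 0:
            raise ValueError("peak_speed must be >= 0")
        if self.gradient_length <= 0:
            raise ValueError("gradient_length must be > 0")
        ax = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(ax)
        if n == 0:
            raise ValueError("axis must be a non-zero 2-vector")
        self.axis = (float(ax[0] / n), float(ax[1] / n))


@dataclass
class SpeckleParams:
    """Rendering parameters for the speckle texture stack."""

    image_shape: tuple[int, int] = (128, 128)  # (H, W) px
    pixel_size: float = 0.5  # um/px
    frame_interval: float = 5.0  # min/frame
    n_frames: int = 6
    speckle_density: float = 0.05
    speckle_sigma: float = 1.0  # px
    noise_sd: float = 0.0  # fraction of mean intensity
    bleach_rate: float = 0.0  # 1/min
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.image_shape) <= 0 or self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("sizes must be positive")
        if not (0 < self.speckle_density < 1):
            raise ValueError("speckle_density must be in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def generate_flow_field(
    spec: FlowSpec, stack_geometry: tuple[float, float] | None = None
) -> FlowField:
    """Return an evaluable displacement-rate field ``f(x_um, y_um, t_min) -> (vx, vy)``.

    ``stack_geometry`` is the (width, height) of the imaged domain in um;
    it anchors the tail end for the gradient flow and the centre for the
    rotational flow. Speeds are in um/min.
    """
    ax = np.asarray(spec.axis, dtype=float)
    if stack_geometry is None:
        stack_geometry = (200.0, 200.0)
    w, h = stack_geometry
    corners = np.array([[0, 0], [w, 0], [0, h], [w, h]], dtype=float)
    # Tail is the domain end the flow points away from: minimal projection on axis.
    tail_proj = corners @ ax
    s_tail = float(tail_proj.min())
    cx, cy = w / 2.0, h / 2.0

    def f(x, y, t):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if spec.kind == "zero":
            z = np.zeros(np.broadcast(x, y).shape)
            return z, z.copy()
        if spec.kind == "uniform":
            shape = np.broadcast(x, y).shape
            return (
                np.full(shape, spec.peak_speed * ax[0]),
                np.full(shape, spec.peak_speed * ax[1]),
            )
        if spec.kind == "tail_to_head_gradient":
            d = x * ax[0] + y * ax[1] - s_tail  # distance travelled from tail end
            speed = spec.peak_speed * np.clip(1.0 - d / spec.gradient_length, 0.0, None)
            return speed * ax[0], speed * ax[1]
        # rotational: solid-body rotation about the domain centre, peak at the rim
        r_max = min(w, h) / 2.0
        omega = spec.peak_speed / r_max
        return -omega * (y - cy), omega * (x - cx)

    return f


def render_speckle_stack(
    flow: FlowField,
    params: SpeckleParams,
    piv_search_margin_px: float | None = None,
) -> ImageStack:
    """Advect a Gaussian-blob speckle texture by the integrated flow.

    Frame ``t+1`` is frame ``t`` warped by backward mapping with bilinear
    interpolation, multiplied by ``exp(-bleach_rate * dt)``; Gaussian read
    noise (clipped at zero) is added independently per output frame so that
    noise is not advected. For uniform integer-pixel shifts the bilinear
    sampling is exact, so phase correlation of consecutive frames recovers
    the imposed shift exactly.
    """
    rng = np.random.default_rng(params.seed)
    H, W = params.image_shape
    base = np.zeros((H, W))
    n_speckles = max(1, int(round(params.speckle_density * H * W)))
    idx = rng.choice(H * W, size=n_speckles, replace=False)
    base.ravel()[idx] = rng.uniform(0.5, 1.0, size=n_speckles)
    base = ndimage.gaussian_filter(base, params.speckle_sigma)
    base /= base.mean()

    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    x_um = xx * params.pixel_size
    y_um = yy * params.pixel_size

    frames = [base]
    clean = base
    dt = params.frame_interval
    max_disp_px = 0.0
    for t in range(params.n_frames - 1):
        vx, vy = flow(x_um, y_um, t * dt)
        dx_px = vx * dt / params.pixel_size
        dy_px = vy * dt / params.pixel_size
        max_disp_px = max(max_disp_px, float(np.hypot(dx_px, dy_px).max()))
        warped = ndimage.map_coordinates(
            clean, [yy - dy_px, xx - dx_px], order=1, mode="constant", cval=0.0
        )
        clean = warped * np.exp(-params.bleach_rate * dt)
        frames.append(clean)

    if piv_search_margin_px is not None and max_disp_px > piv_search_margin_px:
        warnings.warn(
            f"per-frame flow displacement {max_disp_px:.2f} px exceeds the "
            f"PIV search margin {piv_search_margin_px:.2f} px; vectors will clip",
            stacklevel=2,
        )

    data = np.stack(frames)
    if params.noise_sd > 0:
        noise = rng.normal(0.0, params.noise_sd * base.mean(), size=data.shape)
        data = np.clip(data + noise, 0.0, None)
    return ImageStack(
        data=data, pixel_size=params.pixel_size, frame_interval=params.frame_interval
    )


def generate_tracks(
    drift: FlowSpec,
    n_tracks: int = 100,
    n_frames: int = 20,
    frame_interval: float = 10.0,
    jitter_sd: float = 0.0,
    seed: int = 0,
    domain: tuple[float, float] = (200.0, 100.0),
) -> pd.DataFrame:
    """Cell tracks following the drift field plus isotropic Gaussian jitter.

    Returns a long-format table with columns
    ``track_id, frame, x_um, y_um`` and strictly increasing frames per track.
    ``jitter_sd`` is in um per step.
    """
    rng = np.random.default_rng(seed)
    flow = generate_flow_field(drift, stack_geometry=domain)
    pos = np.column_stack(
        [rng.uniform(0, domain[0], n_tracks), rng.uniform(0, domain[1], n_tracks)]
    )
    records = []
    for t in range(n_frames):
        for i in range(n_tracks):
            records.append((i, t, pos[i, 0], pos[i, 1]))
        vx, vy = flow(pos[:, 0], pos[:, 1], t * frame_interval)
        step = np.column_stack([vx, vy]) * frame_interval
        if jitter_sd > 0:
            step = step + rng.normal(0.0, jitter_sd, size=step.shape)
        pos = pos + step
    return pd.DataFrame(records, columns=["track_id", "frame", "x_um", "y_um"])


def generate_force_curve(
    E_true: float,
    contact_model,
    z_range: tuple[float, float, int] = (-500.0, 1500.0, 400),
    noise_sd: float = 0.0,
    seed: int = 0,
    contact_z: float = 0.0,
) -> ForceCurve:
    """Synthesize an approach curve obeying the spherical Hertz law.

    The pre-contact region is flat; past the contact point ``contact_z`` the
    deflection ``d`` solves ``k d = (4/3) (E / (1 - nu^2)) sqrt(R) delta^{3/2}``
    with indentation ``delta = (z - contact_z) - d``, i.e. the piezo travel is
    shared between indentation and cantilever bending. ``noise_sd`` is
    additive Gaussian force noise expressed as a fraction of the Hertz
    force at the contact model's target indentation depth (the force
    scale of the region the fit uses).
    """
    from .afm import hertz_force_coefficient  # avoid a cycle at import time

    z = np.linspace(z_range[0], z_range[1], z_range[2])
    k = contact_model.k  # N/m == nN/nm
    c = hertz_force_coefficient(E_true, contact_model)  # nN / nm^{3/2}
    d = np.zeros_like(z)
    post = z > contact_z
    travel = z[post] - contact_z  # nm
    # Newton iteration, vectorized; the map is smooth and monotone.
    dd = np.minimum(c * travel**1.5 / k, travel * 0.99)
    for _ in range(60):
        delta = np.clip(travel - dd, 0.0, None)
        fval = k * dd - c * delta**1.5
        fprime = k + 1.5 * c * np.sqrt(delta)
        dd = np.clip(dd - fval / fprime, 0.0, travel)
    d[post] = dd
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        f_ref = c * contact_model.target_depth**1.5
        d = d + rng.normal(0.0, noise_sd * f_ref / k, size=d.shape)
    return ForceCurve(z=z, deflection=d)


def generate_outline(
    a: float,
    b: float,
    n_points: int = 200,
    noise_sd: float = 0.0,
    seed: int = 0,
    center: tuple[float, float] = (0.0, 0.0),
    angle: float = 0.0,
) -> np.ndarray:
    """Points on the ellipse ``x = a cos t, y = b sin t`` plus radial noise.

    Returns an (n_points, 2) array in um. ``a >= b`` is enforced by swapping.
    ``angle`` rotates the major axis; ``noise_sd`` is the radial
    perturbation standard deviation in um.
    """
    if a <= 0 or b <= 0:
        raise ValueError("semi-axes must be positive")
    if a < b:
        a, b = b, a
    theta = np.linspace(0.0, 2 * np.pi, n_points, endpoint=False)
    pts = np.column_stack([a * np.cos(theta), b * np.sin(theta)])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        r = np.linalg.norm(pts, axis=1)
        radial = pts / r[:, None]
        pts = pts + radial * rng.normal(0.0, noise_sd, size=n_points)[:, None]
    ca, sa = np.cos(angle), np.sin(angle)
    rot = np.array([[ca, -sa], [sa, ca]])
    return pts @ rot.T + np.asarray(center)


@dataclass
class CondensationParams:
    """Two-phase condensation scenario parameters.

    Defaults describe a VNC-scale tissue: phase 1 is a 180 min
    isovolumetric shortening by ``phase1_shrink`` with compensating width
    and height growth; phase 2 shrinks all dimensions and loses volume.
    Intensity follows exponential induction until ``t_sat``; the tail
    displaces along a logistic ramp whose rate peaks inside phase 1.
    """

    L0: float = 200.0  # um
    W0: float = 40.0
    H0: float = 30.0
    t_end_phase1: float = 180.0  # min
    t_end_phase2: float = 720.0
    dt: float = 2.0  # native sampling, min
    phase1_shrink: float = 0.40  # fractional L loss in phase 1
    phase2_shrink: float = 0.15  # fractional isotropic dim loss in phase 2
    intensity_I0: float = 1.0
    intensity_rate: float = np.log(20.0) / 240.0  # 1/min
    intensity_t_sat: float = 300.0  # min
    tail_t_half: float = 170.0  # min, logistic midpoint (inside phase 1)
    tail_tau: float = 40.0  # min, logistic time constant
    intensity_noise_sd: float = 0.0  # fraction of instantaneous intensity
    displacement_noise_sd: float = 0.0  # um


@dataclass
class CondensationScene:
    """Ground-truth condensation time course."""

    times: np.ndarray  # min
    dims: np.ndarray  # (n, 3) -> (L, W, H) um
    col4_intensity: np.ndarray  # a.u.
    tail_displacement: np.ndarray  # um, 0 at t=0
    phase_boundaries: tuple[float, float]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "times_min": self.times.tolist(),
            "dims_um": self.dims.tolist(),
            "col4_intensity": self.col4_intensity.tolist(),
            "tail_displacement_um": self.tail_displacement.tolist(),
            "phase_boundaries_min": list(self.phase_boundaries),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "CondensationScene":
        d = json.loads(Path(path).read_text())
        return cls(
            times=np.asarray(d["times_min"]),
            dims=np.asarray(d["dims_um"]),
            col4_intensity=np.asarray(d["col4_intensity"]),
            tail_displacement=np.asarray(d["tail_displacement_um"]),
            phase_boundaries=tuple(d["phase_boundaries_min"]),
        )


def generate_condensation_scene(
    params: CondensationParams | None = None, seed: int = 0
) -> CondensationScene:
    """Build the two-phase scene; phase-1 volume is constant by construction.

    During phase 1, ``L(t) = L0 (1 - phase1_shrink * s(t))`` with a smooth
    ramp ``s``; ``W`` and ``H`` both scale by ``sqrt(L0 / L(t))`` so the
    elliptical-cylinder volume ``pi (W/2)(H/2) L`` is exactly conserved.
    During phase 2 all three dimensions shrink linearly, so volume drops.
    """
    p = params or CondensationParams()
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, p.t_end_phase2 + p.dt / 2, p.dt)
    t1 = p.t_end_phase1

    # smoothstep ramp for the phase-1 shortening
    s = np.clip(times / t1, 0.0, 1.0)
    ramp = 3 * s**2 - 2 * s**3
    L = p.L0 * (1.0 - p.phase1_shrink * ramp)
    scale = np.sqrt(p.L0 / L)
    W = p.W0 * scale
    H = p.H0 * scale

    in2 = times > t1
    if in2.any():
        shrink2 = 1.0 - p.phase2_shrink * (times[in2] - t1) / (p.t_end_phase2 - t1)
        L1 = p.L0 * (1.0 - p.phase1_shrink)
        grow1 = np.sqrt(p.L0 / L1)
        L[in2] = L1 * shrink2
        W[in2] = p.W0 * grow1 * shrink2
        H[in2] = p.H0 * grow1 * shrink2

    intensity = p.intensity_I0 * np.exp(p.intensity_rate * np.minimum(times, p.intensity_t_sat))
    if p.intensity_noise_sd > 0:
        intensity = intensity * (
            1.0 + rng.normal(0.0, p.intensity_noise_sd, size=intensity.shape)
        )

    d_max = p.L0 * p.phase1_shrink
    logistic = 1.0 / (1.0 + np.exp(-(times - p.tail_t_half) / p.tail_tau))
    logistic0 = 1.0 / (1.0 + np.exp(p.tail_t_half / p.tail_tau))
    disp = d_max * (logistic - logistic0) / (1.0 - logistic0)
    if p.displacement_noise_sd > 0:
        disp = disp + rng.normal(0.0, p.displacement_noise_sd, size=disp.shape)
        disp[0] = 0.0
        disp = np.maximum.accumulate(disp)  # keep monotone under noise

    return CondensationScene(
        times=times,
        dims=np.column_stack([L, W, H]),
        col4_intensity=intensity,
        tail_displacement=disp,
        phase_boundaries=(p.t_end_phase1, p.t_end_phase2),
    )


# Patterned-photobleaching protocol geometry: five ~20 um-wide stripes
# spaced ~50 um apart along the VNC midline.
PROTOCOL_STRIPE_CENTERS = (60.0, 110.0, 160.0, 210.0, 260.0)
PROTOCOL_STRIPE_WIDTH = 20.0  # um, FWHM
PROTOCOL_PROFILE_LENGTH = 320.0  # um


def generate_bleach_profile(
    length_um: float = PROTOCOL_PROFILE_LENGTH,
    stripe_centers: Sequence[float] = PROTOCOL_STRIPE_CENTERS,
    stripe_width: float = PROTOCOL_STRIPE_WIDTH,
    depth: float = 0.5,
    noise_sd: float = 0.0,
    shift_um: float | Sequence[float] = 0.0,
    seed: int = 0,
    sampling_um: float = 0.1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two baseline-normalized midline profiles with Gaussian bleach dips.

    Returns ``(x_um, profile_t0, profile_t1)``. The t1 pattern is the t0
    pattern displaced ``shift_um`` toward the head (toward smaller
    coordinate; a per-stripe sequence produces a graded shift).
    ``stripe_width`` is the dip FWHM; ``noise_sd`` is multiplicative.
    """
    x = np.arange(0.0, length_um, sampling_um)
    sigma = stripe_width / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    centers = np.asarray(stripe_centers, dtype=float)
    shifts = np.broadcast_to(np.asarray(shift_um, dtype=float), centers.shape)

    def profile(cs):
        prof = np.ones_like(x)
        for c in cs:
            prof -= depth * np.exp(-((x - c) ** 2) / (2 * sigma**2))
        return prof

    p0 = profile(centers)
    p1 = profile(centers - shifts)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        p0 = p0 * (1.0 + rng.normal(0.0, noise_sd, size=x.shape))
        p1 = p1 * (1.0 + rng.normal(0.0, noise_sd, size=x.shape))
    return x, p0, p1
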