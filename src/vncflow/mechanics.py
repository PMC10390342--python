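"""Core+shell mechanical model of tissue condensation.

The tissue is idealized as a soft, nearly incompressible elastic core
shaped as a capped elliptical cylinder (length L along x, width W along
y, height H along z, head cap at x = 0 held fixed — the attachment to the
brain) wrapped in a thin basement-membrane shell. The shell acts on the
core either as a uniform normal pressure or as an in-plane membrane
tension (isotropic, or anisotropic with the dominant component along the
tissue axis), optionally reduced by a scale factor inside a central
stripe. The core is solved as small-strain linear elasticity on a
tetrahedral mesh; membrane tension enters as the equivalent surface
traction of a constant prestress on each surface facet (the nodal forces
are the gradient of the membrane energy ``sigma : epsilon * area``, which
for an isotropic tension reduces to ``-sigma * dA/dx``). The claims this
model supports are sign and ordering patterns of the shape change, not
magnitudes, and in the linear regime those patterns are invariant to
uniformly rescaling the loads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import Delaunay

from .morphometry import fit_ellipse

LOAD_CASES = ("normal_pressure", "isotropic_tension", "anisotropic_tension")


@dataclass
class StripeSpec:
    """Axial band in which the shell tension is rescaled."""

    center: float  # um along the axis
    width: float  # um
    scale: float  # multiplies the tension inside the band, in [0, 1]

    def __post_init__(self) -> None:
        if not (0.0 <= self.scale <= 1.0):
            raise ValueError("stripe scale must be in [0, 1]")
        if self.width <= 0:
            raise ValueError("stripe width must be positive")


@dataclass
class ShellModel:
    """Geometry, materials, loads, and discretization of the core+shell model.

    Lengths in um, moduli and pressure in Pa, tensions in N/m. The default
    load magnitudes are free parameters chosen to keep strains in the
    small-strain regime.
    """

    L: float = 200.0
    W: float = 40.0
    H: float = 20.0
    E_core: float = 100.0  # Pa
    nu_core: float = 0.49
    shell_thickness: float = 0.2  # um, bookkeeping only: loads are N/m
    sigma_ax: float = 2e-5  # N/m
    sigma_circ: float = 2e-6  # N/m
    pressure: float = 5.0  # Pa
    stripe: StripeSpec | None = None
    n_theta: int = 16
    n_rings: int = 3
    n_axial: int = 21
    # filled by build()
    nodes: np.ndarray | None = field(default=None, repr=False)
    tets: np.ndarray | None = field(default=None, repr=False)
    surface_tris: np.ndarray | None = field(default=None, repr=False)
    surface_kind: np.ndarray | None = field(default=None, repr=False)
    fixed_nodes: np.ndarray | None = field(default=None, repr=False)
    _mid_ring: np.ndarray | None = field(default=None, repr=False)
    _tail_cap: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if min(self.L, self.W, self.H, self.E_core, self.shell_thickness) <= 0:
            raise ValueError("geometry and material parameters must be positive")
        if not (0.0 <= self.nu_core < 0.5):
            raise ValueError("nu_core must be in [0, 0.5)")

    @property
    def is_built(self) -> bool:
        return self.nodes is not None


@dataclass
class DeformationResult:
    """Signed shape changes of the deformed core (um)."""

    dL: float
    dW: float
    dH: float
    relative_volume_change: float
    tail_displacement: float  # um, positive = tail moved toward the head
    displacements: np.ndarray  # (n_nodes, 3), um
    eccentricity_mid: float
    eccentricity_mid_undeformed: float


def _ellipse_section_mesh(a: float, b: float, n_theta: int, n_rings: int):
    """2-D triangulation of an ellipse cross-section; returns points,
    triangles, and the ordered boundary ring indices."""
    pts = [(0.0, 0.0)]
    for k in range(1, n_rings + 1):
        r = k / n_rings
        th = np.arange(n_theta) * 2 * np.pi / n_theta
        for t in th:
            pts.append((r * a * np.cos(t), r * b * np.sin(t)))
    pts = np.asarray(pts)
    tri = Delaunay(pts)
    boundary = np.arange(1 + (n_rings - 1) * n_theta, 1 + n_rings * n_theta)
    return pts, tri.simplices.copy(), boundary


def build_model(model: ShellModel | None = None, **overrides) -> ShellModel:
    """Mesh the capped elliptical cylinder and attach the discretization.

    Prisms obtained by extruding the cross-section triangulation along
    the axis are split into tetrahedra through their centroid, with quad
    faces triangulated by a smallest-global-index diagonal rule so
    neighbouring prisms conform. Raises if the axial spacing is coarser
    than a requested stripe.
    """
    if model is None:
        model = ShellModel(**overrides)
    elif overrides:
        raise ValueError("pass either a model or keyword overrides, not both")
    a, b = model.W / 2.0, model.H / 2.0
    dx = model.L / (model.n_axial - 1)
    if model.stripe is not None and dx > model.stripe.width:
        raise ValueError(
            f"axial spacing {dx:.1f} um too coarse for a "
            f"{model.stripe.width:.1f} um stripe; refine n_axial"
        )
    pts2d, tris2d, boundary = _ellipse_section_mesh(
        a, b, model.n_theta, model.n_rings
    )
    n2d = len(pts2d)
    xs = np.linspace(0.0, model.L, model.n_axial)
    nodes = np.column_stack(
        [
            np.repeat(xs, n2d),
            np.tile(pts2d[:, 0], model.n_axial),
            np.tile(pts2d[:, 1], model.n_axial),
        ]
    )
    node_id = lambda s, i: s * n2d + i

    extra_nodes = []
    tets = []

    def add_tet(i, j, k, centroid_idx):
        tets.append((i, j, k, centroid_idx))

    def split_quad(i0, i1, j1, j0):
        """Triangulate quad (i0 -> i1 -> j1 -> j0) by the smallest-index rule."""
        ids = [i0, i1, j1, j0]
        m = int(np.argmin(ids))
        # diagonal from the smallest-index vertex
        a0, a1, a2, a3 = (ids[(m + s) % 4] for s in range(4))
        return [(a0, a1, a2), (a0, a2, a3)]

    next_id = len(nodes)
    for s in range(model.n_axial - 1):
        for t in tris2d:
            i0, i1, i2 = (node_id(s, v) for v in t)
            j0, j1, j2 = (node_id(s + 1, v) for v in t)
            centroid = nodes[[i0, i1, i2, j0, j1, j2]].mean(axis=0)
            extra_nodes.append(centroid)
            c = next_id
            next_id += 1
            add_tet(i0, i1, i2, c)  # bottom face
            add_tet(j0, j2, j1, c)  # top face
            for tri in split_quad(i0, i1, j1, j0):
                add_tet(*tri, c)
            for tri in split_quad(i1, i2, j2, j1):
                add_tet(*tri, c)
            for tri in split_quad(i2, i0, j0, j2):
                add_tet(*tri, c)

    nodes = np.vstack([nodes, np.asarray(extra_nodes)])
    tets = np.asarray(tets, dtype=int)
    # orient all tets to positive volume
    v = _tet_volumes(nodes, tets)
    flip = v < 0
    tets[flip] = tets[flip][:, [0, 2, 1, 3]]
    if (np.abs(_tet_volumes(nodes, tets)) < 1e-12).any():
        raise RuntimeError("mesh contains degenerate elements")

    # surface triangles: lateral quads + end caps
    surf = []
    kind = []  # 0 = lateral, 1 = head cap, 2 = tail cap
    nb = len(boundary)
    for s in range(model.n_axial - 1):
        for e in range(nb):
            p0 = node_id(s, boundary[e])
            p1 = node_id(s, boundary[(e + 1) % nb])
            q1 = node_id(s + 1, boundary[(e + 1) % nb])
            q0 = node_id(s + 1, boundary[e])
            for tri in split_quad(p0, p1, q1, q0):
                surf.append(tri)
                kind.append(0)
    for t in tris2d:
        surf.append(tuple(node_id(0, v) for v in t))
        kind.append(1)
        surf.append(tuple(node_id(model.n_axial - 1, v) for v in t))
        kind.append(2)
    surf = np.asarray(surf, dtype=int)
    kind = np.asarray(kind, dtype=int)
    # orient surface normals outward (away from the local axis point)
    p = nodes[surf]
    centers = p.mean(axis=1)
    normals = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    axis_pt = centers.copy()
    axis_pt[:, 1:] = 0.0
    axis_pt[kind == 1, 0] = 1.0  # head cap: interior reference just inside
    axis_pt[kind == 2, 0] = model.L - 1.0
    outward = centers - axis_pt
    flip = np.einsum("ij,ij->i", normals, outward) < 0
    surf[flip] = surf[flip][:, [0, 2, 1]]

    model.nodes = nodes
    model.tets = tets
    model.surface_tris = surf
    model.surface_kind = kind
    model.fixed_nodes = np.nonzero(nodes[:, 0] < 1e-9)[0]
    model._mid_ring = np.array(
        [node_id(model.n_axial // 2, i) for i in boundary]
    )
    model._tail_cap = np.array(
        [node_id(model.n_axial - 1, i) for i in range(n2d)]
    )
    return model


def _tet_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    p = nodes[tets]
    return np.einsum(
        "ij,ij->i",
        np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
        p[:, 3] - p[:, 0],
    ) / 6.0


def _assemble_stiffness(nodes_m: np.ndarray, tets: np.ndarray, E: float, nu: float):
    """Linear (constant-strain) tetrahedron stiffness, vectorized assembly."""
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.array(
        [
            [lam + 2 * mu, lam, lam, 0, 0, 0],
            [lam, lam + 2 * mu, lam, 0, 0, 0],
            [lam, lam, lam + 2 * mu, 0, 0, 0],
            [0, 0, 0, mu, 0, 0],
            [0, 0, 0, 0, mu, 0],
            [0, 0, 0, 0, 0, mu],
        ]
    )
    p = nodes_m[tets]  # (ne, 4, 3)
    ne = len(tets)
    ones = np.ones((ne, 4, 1))
    M = np.concatenate([ones, p], axis=2)  # (ne, 4, 4)
    vol = np.abs(np.linalg.det(M)) / 6.0
    Minv = np.linalg.inv(M)
    grads = Minv[:, 1:, :]  # (ne, 3, 4): d(phi_j)/d(x_i)
    B = np.zeros((ne, 6, 12))
    for j in range(4):
        gx, gy, gz = grads[:, 0, j], grads[:, 1, j], grads[:, 2, j]
        c = 3 * j
        B[:, 0, c] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c] = gy
        B[:, 3, c + 1] = gx
        B[:, 4, c + 1] = gz
        B[:, 4, c + 2] = gy
        B[:, 5, c] = gz
        B[:, 5, c + 2] = gx
    Ke = np.einsum("eki,kl,elj,e->eij", B, D, B, vol)  # (ne, 12, 12)
    dofs = (3 * tets[:, :, None] + np.arange(3)[None, None, :]).reshape(ne, 12)
    rows = np.repeat(dofs, 12, axis=1).ravel()
    cols = np.tile(dofs, (1, 12)).ravel()
    n_dof = 3 * len(nodes_m)
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(n_dof, n_dof)).tocsr()
    return K


def _tension_loads(model: ShellModel, sigma_ax: float, sigma_circ: float,
                   stripe: StripeSpec | None) -> np.ndarray:
    """Equivalent nodal forces of a constant membrane prestress (SI units)."""
    nodes_m = model.nodes * 1e-6
    f = np.zeros((len(nodes_m), 3))
    axial = np.array([1.0, 0.0, 0.0])
    for tri, kindv in zip(model.surface_tris, model.surface_kind):
        p = nodes_m[tri]
        e1, e2 = p[1] - p[0], p[2] - p[0]
        nvec = np.cross(e1, e2)
        area2 = np.linalg.norm(nvec)
        if area2 == 0:
            continue
        nhat = nvec / area2
        A = area2 / 2.0
        if kindv == 0:
            t1 = axial - (axial @ nhat) * nhat
            t1n = np.linalg.norm(t1)
            if t1n < 1e-12:
                continue
            t1 = t1 / t1n
            s_ax, s_circ = sigma_ax, sigma_circ
        else:
            # end caps carry the transverse (circumferential) tension
            t1 = e1 / np.linalg.norm(e1)
            t1 = t1 - (t1 @ nhat) * nhat
            t1 = t1 / np.linalg.norm(t1)
            s_ax = s_circ = sigma_circ
        t2 = np.cross(nhat, t1)
        if stripe is not None and kindv == 0:
            xc = (p[:, 0].mean()) / 1e-6  # back to um
            if abs(xc - stripe.center) <= stripe.width / 2.0:
                s_ax = s_ax * stripe.scale
                s_circ = s_circ * stripe.scale
        # local 2-D coordinates of the triangle
        q = np.column_stack([(p - p[0]) @ t1, (p - p[0]) @ t2])  # (3, 2)
        x1, y1 = q[0]
        x2, y2 = q[1]
        x3, y3 = q[2]
        bvec = np.array([y2 - y3, y3 - y1, y1 - y2])
        cvec = np.array([x3 - x2, x1 - x3, x2 - x1])
        # f_local = -A * B^T sigma ; B = 1/(2A) [...]
        sig = np.array([s_ax, s_circ, 0.0])
        for i in range(3):
            fx_loc = -(bvec[i] * sig[0] + cvec[i] * sig[2]) / 2.0
            fy_loc = -(cvec[i] * sig[1] + bvec[i] * sig[2]) / 2.0
            f[tri[i]] += fx_loc * t1 + fy_loc * t2
    return f


def _pressure_loads(model: ShellModel, P: float) -> np.ndarray:
    """Uniform inward normal pressure on the whole surface (SI units)."""
    nodes_m = model.nodes * 1e-6
    f = np.zeros((len(nodes_m), 3))
    for tri in model.surface_tris:
        p = nodes_m[tri]
        nvec = np.cross(p[1] - p[0], p[2] - p[0])  # outward, |n| = 2A
        contrib = -P * nvec / 6.0  # per node: -P * nhat * A / 3
        for i in range(3):
            f[tri[i]] += contrib
    return f


def simulate(model: ShellModel, load_case: str, load_scale: float = 1.0,
             use_stripe: bool = False) -> DeformationResult:
    """Static equilibrium of the core under the requested shell loading.

    ``load_case`` is one of ``normal_pressure``, ``isotropic_tension``
    (both tension components equal to ``sigma_ax``), or
    ``anisotropic_tension`` (``sigma_ax`` along the axis, ``sigma_circ``
    transverse). ``load_scale`` multiplies the load; ``use_stripe``
    activates the model's stripe, if any.
    """
    if load_case not in LOAD_CASES:
        raise ValueError(f"load_case must be one of {LOAD_CASES}")
    if not model.is_built:
        build_model(model)
    stripe = model.stripe if use_stripe else None
    if load_case == "normal_pressure":
        f = _pressure_loads(model, model.pressure * load_scale)
    elif load_case == "isotropic_tension":
        s = model.sigma_ax * load_scale
        f = _tension_loads(model, s, s, stripe)
    else:
        f = _tension_loads(
            model, model.sigma_ax * load_scale, model.sigma_circ * load_scale, stripe
        )

    nodes_m = model.nodes * 1e-6
    K = _assemble_stiffness(nodes_m, model.tets, model.E_core, model.nu_core)
    n_dof = 3 * len(nodes_m)
    fixed = np.zeros(n_dof, dtype=bool)
    fixed[3 * model.fixed_nodes[:, None] + np.arange(3)] = True
    free = ~fixed
    rhs = f.ravel()
    u = np.zeros(n_dof)
    Kff = K[free][:, free]
    u[free] = spla.spsolve(Kff.tocsc(), rhs[free])
    disp_um = u.reshape(-1, 3) * 1e6  # m -> um

    return _summarize(model, disp_um)


def _summarize(model: ShellModel, disp_um: np.ndarray) -> DeformationResult:
    nodes = model.nodes
    deformed = nodes + disp_um
    tail = model._tail_cap
    dL = float(disp_um[tail, 0].mean())
    ring = model._mid_ring
    y0, z0 = nodes[ring, 1], nodes[ring, 2]
    y1, z1 = deformed[ring, 1], deformed[ring, 2]
    dW = float((y1.max() - y1.min()) - (y0.max() - y0.min()))
    dH = float((z1.max() - z1.min()) - (z0.max() - z0.min()))
    v0 = _tet_volumes(nodes, model.tets).sum()
    v1 = _tet_volumes(deformed, model.tets).sum()
    ecc0 = fit_ellipse(np.column_stack([y0, z0])).eccentricity
    ecc1 = fit_ellipse(np.column_stack([y1, z1])).eccentricity
    return DeformationResult(
        dL=dL,
        dW=dW,
        dH=dH,
        relative_volume_change=float((v1 - v0) / v0),
        tail_displacement=-dL,
        displacements=disp_um,
        eccentricity_mid=float(ecc1),
        eccentricity_mid_undeformed=float(ecc0),
    )


def stripe_perturbation(
    model: ShellModel,
    base_load: str = "anisotropic_tension",
    scale: float | None = None,
) -> dict[str, DeformationResult]:
    """Run the base load with and without the stripe tension reduction.

    Returns {'base': ..., 'perturbed': ...}; with ``scale`` given, the
    model's stripe scale is overridden for the perturbed run.
    """
    if model.stripe is None:
        raise ValueError("model has no stripe configured")
    if not model.is_built:
        build_model(model)
    base = simulate(model, base_load, use_stripe=False)
    if scale is not None:
        original = model.stripe.scale
        model.stripe.scale = scale
        try:
            perturbed = simulate(model, base_load, use_stripe=True)
        finally:
            model.stripe.scale = original
    else:
        perturbed = simulate(model, base_load, use_stripe=True)
    return {"base": base, "perturbed": perturbed}


def export_vtk(model: ShellModel, disp_um: np.ndarray, path) -> None:
    """Write the mesh and displacement field as legacy-text VTK."""
    nodes = model.nodes
    lines = [
        "# vtk DataFile Version 3.0",
        "core+shell deformation",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {len(nodes)} float",
    ]
    lines += [f"{p[0]:.6g} {p[1]:.6g} {p[2]:.6g}" for p in nodes]
    tets = model.tets
    lines.append(f"CELLS {len(tets)} {5 * len(tets)}")
    lines += [f"4 {t[0]} {t[1]} {t[2]} {t[3]}" for t in tets]
    lines.append(f"CELL_TYPES {len(tets)}")
    lines += ["10"] * len(tets)
    lines.append(f"POINT_DATA {len(nodes)}")
    lines.append("VECTORS displacement float")
    lines += [f"{d[0]:.6g} {d[1]:.6g} {d[2]:.6g}" for d in disp_um]
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")
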