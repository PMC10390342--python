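"""AFM force-curve calibration and spherical-tip Hertz fitting.

An approach curve records piezo extension ``z`` and cantilever deflection
``d`` (both nm). Force is ``F = k d`` and indentation
``delta = (z - z_c) - d`` past the contact point ``z_c``. The effective
elastic modulus follows the Hertz law for a sphere on an elastic
half-space,

    F = (4/3) * (E / (1 - nu^2)) * sqrt(R) * delta^(3/2),

fitted over indentations up to the target depth (230 nm by default).
The contact point is estimated jointly with ``E``: for each candidate
contact sample, ``E`` follows from a linear least-squares fit of ``F``
against ``delta^(3/2)`` through the origin, and the candidate with the
smallest residual wins — more robust on soft samples than a separate
threshold detector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import ForceCurve


@dataclass(frozen=True)
class ContactModel:
    """Probe and fit parameters.

    ``R`` is the tip sphere radius in um (a 10 um bead gives 5), ``k``
    the cantilever spring constant in N/m, ``nu`` the sample Poisson
    ratio (0.5 = incompressible), ``target_depth`` the indentation depth
    in nm over which the Hertz law is fitted, and ``setpoint`` the
    maximum force in nN.
    """

    R: float = 5.0  # um
    k: float = 0.2  # N/m (= nN/nm)
    nu: float = 0.5
    target_depth: float = 230.0  # nm
    setpoint: float = 3.0  # nN

    def __post_init__(self) -> None:
        if min(self.R, self.k, self.target_depth, self.setpoint) <= 0:
            raise ValueError("all physical parameters must be positive")
        if not (0.0 <= self.nu <= 0.5):
            raise ValueError("nu must be in [0, 0.5]")


@dataclass
class HertzFit:
    contact_z: float  # nm on the piezo axis
    E_eff: float  # Pa
    residual_rms: float  # nN
    depth_range: tuple[float, float]  # nm


def hertz_force_coefficient(E: float, model: ContactModel) -> float:
    """Prefactor c with F[nN] = c * delta[nm]^(3/2).

    ``E`` in Pa, ``R`` in um: c = (4/3) E / (1 - nu^2) * sqrt(R) in SI,
    converted so that nm^(3/2) indentations give nN forces.
    """
    R_m = model.R * 1e-6
    c_si = (4.0 / 3.0) * E / (1.0 - model.nu**2) * np.sqrt(R_m)  # N / m^{3/2}
    # delta[nm]^{3/2} -> m^{3/2}: 1e-13.5 ; N -> nN: 1e9
    return float(c_si * 10 ** (-13.5) * 1e9)


def hertz_force(delta_nm: np.ndarray, E: float, model: ContactModel) -> np.ndarray:
    """Hertz force (nN) at indentation depths in nm."""
    d = np.clip(np.asarray(delta_nm, dtype=float), 0.0, None)
    return hertz_force_coefficient(E, model) * d**1.5


def force_indentation(
    curve: ForceCurve, model: ContactModel, contact_z: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Convert a raw curve to calibrated (indentation nm, force nN) samples.

    ``F = k * deflection`` and ``delta = (z - z_c) - deflection``; when
    ``contact_z`` is not supplied it is taken from :func:`fit_hertz`.
    Raises if no contact is detected (flat deflection) or the deflection
    saturates before the setpoint is reached.
    """
    d = curve.deflection
    f = model.k * d
    if np.allclose(d, d[0]):
        raise ValueError("no contact detected: deflection is flat")
    tail = d[-max(3, len(d) // 50):]
    if np.ptp(tail) < 1e-12 and f.max() < model.setpoint:
        raise ValueError("deflection saturates before reaching the setpoint")
    if contact_z is None:
        contact_z = fit_hertz_curve(curve, model).contact_z
    delta = (curve.z - contact_z) - d
    keep = curve.z >= contact_z
    return delta[keep], f[keep]


def _fit_at_contact(z, d, model: ContactModel, zc: float, sel: np.ndarray):
    """Linear LS of F on clip(delta, 0)^{3/2} through the origin for one
    candidate contact point, over a fixed sample window ``sel``.

    The window includes the flat pre-contact baseline (model force 0),
    which anchors the contact point; because the window is shared by all
    candidates, the absolute residual is a comparable score.
    """
    delta = (z - zc) - d
    f = model.k * d
    dsel = delta[sel]
    if dsel.max() < model.target_depth * 0.98:
        return None
    # score the contact point over the full window (baseline + entire rise) ...
    xb_all = np.clip(dsel, 0.0, None) ** 1.5
    yb_all = f[sel]
    sxx = float(xb_all @ xb_all)
    if sxx == 0 or (xb_all > 0).sum() < 4:
        return None
    c_all = float(xb_all @ yb_all) / sxx
    if c_all <= 0:
        return None
    score = float(np.sqrt(np.mean((yb_all - c_all * xb_all) ** 2)))
    # ... but report the modulus fitted over the target indentation depth only
    inside = dsel <= model.target_depth
    xb = np.clip(dsel[inside], 0.0, None) ** 1.5
    yb = yb_all[inside]
    sxx_in = float(xb @ xb)
    if sxx_in == 0 or (xb > 0).sum() < 4:
        return None
    c = float(xb @ yb) / sxx_in
    if c <= 0:
        return None
    rms = float(np.sqrt(np.mean((yb - c * xb) ** 2)))
    return c, rms, (0.0, float(dsel[inside].max())), score


def fit_hertz(
    samples_or_curve,
    model: ContactModel,
) -> HertzFit:
    """Hertz fit; accepts either a ForceCurve or calibrated (delta, F) samples.

    For a ForceCurve the contact point is estimated jointly with ``E``
    (grid over candidate contact samples, linearized fit at each). For
    pre-calibrated samples the contact point is taken as delta = 0.
    Raises if the curve never reaches the target indentation depth.
    """
    if isinstance(samples_or_curve, ForceCurve):
        return fit_hertz_curve(samples_or_curve, model)
    delta, f = samples_or_curve
    delta = np.asarray(delta, dtype=float)
    f = np.asarray(f, dtype=float)
    if delta.max() < model.target_depth:
        raise ValueError(
            f"curve reaches only {delta.max():.1f} nm of the "
            f"{model.target_depth:.1f} nm target depth"
        )
    sel = (delta > 0) & (delta <= model.target_depth)
    xb = delta[sel] ** 1.5
    c = float(xb @ f[sel]) / float(xb @ xb)
    E = _coefficient_to_modulus(c, model)
    rms = float(np.sqrt(np.mean((f[sel] - c * xb) ** 2)))
    return HertzFit(
        contact_z=0.0,
        E_eff=E,
        residual_rms=rms,
        depth_range=(float(delta[sel].min()), float(delta[sel].max())),
    )


def _coefficient_to_modulus(c_nn: float, model: ContactModel) -> float:
    c_unit = hertz_force_coefficient(1.0, model)
    return float(c_nn / c_unit)


def fit_hertz_curve(curve: ForceCurve, model: ContactModel) -> HertzFit:
    """Joint contact-point and modulus estimation on a raw approach curve."""
    z, d = curve.z, curve.deflection
    if len(z) < 10:
        raise ValueError("curve too short to fit")
    max_travel = (z - z[0]) - (d - d[0])
    if max_travel.max() < model.target_depth:
        raise ValueError(
            "curve never reaches the target indentation depth "
            f"({model.target_depth:.0f} nm)"
        )
    dz = float(np.median(np.diff(z)))
    f = model.k * d
    # rough contact: first sustained rise above the baseline noise floor
    n_base = max(5, len(z) // 5)
    base_mean = float(f[:n_base].mean())
    base_sd = float(f[:n_base].std())
    above = np.nonzero(f > base_mean + 5 * base_sd)[0]
    above = above[above >= 1] if len(above) else above
    idx_rough = int(above[0]) if len(above) else int(np.argmax(f > base_mean))
    z_rough = z[idx_rough]
    # fixed fit window: whole baseline plus the rise up to the target depth
    # (generous margin so every candidate contact can reach the target)
    z_end = z_rough + model.target_depth + 60 * base_sd / max(model.k, 1e-12) + 5 * dz
    sel = z <= z_end
    # candidate grid: samples in [z_rough - generous backtrack, z_rough + a few]
    backtrack = model.target_depth + 50 * dz
    cand = np.nonzero((z >= z_rough - backtrack) & (z <= z_rough + 3 * dz))[0]
    best = None
    for idx in cand:
        res = _fit_at_contact(z, d, model, z[idx], sel)
        if res is None:
            continue
        c, rms, depth_range, score = res
        if best is None or score < best[4]:
            best = (c, rms, depth_range, z[idx], score)
    if best is None:
        raise ValueError("Hertz fit failed: no feasible contact point")
    c, rms, depth_range, zc, score = best
    # continuous refinement of the contact point around the best sample
    from scipy.optimize import minimize_scalar

    def objective(zc_try: float) -> float:
        res = _fit_at_contact(z, d, model, zc_try, sel)
        return res[3] if res is not None else 1e30

    opt = minimize_scalar(
        objective, bounds=(zc - dz, zc + dz), method="bounded",
        options={"xatol": dz * 1e-4},
    )
    if np.isfinite(opt.fun) and opt.fun <= score:
        refined = _fit_at_contact(z, d, model, float(opt.x), sel)
        if refined is not None:
            c, rms, depth_range, score = refined
            zc = float(opt.x)
    if depth_range[1] < model.target_depth * 0.95:
        raise ValueError(
            f"fitted depth range reaches only {depth_range[1]:.1f} nm of the "
            f"{model.target_depth:.1f} nm target"
        )
    # non-monotonicity beyond the noise floor is suspicious on approach
    post = z >= zc
    f_post = model.k * d[post]
    if len(f_post) > 5:
        drops = np.diff(f_post)
        noise = np.std(drops) + 1e-12
        if (drops < -5 * noise).any():
            import warnings

            warnings.warn("non-monotone post-contact force beyond the noise floor",
                          stacklevel=2)
    return HertzFit(
        contact_z=float(zc),
        E_eff=_coefficient_to_modulus(c, model),
        residual_rms=rms,
        depth_range=depth_range,
    )
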