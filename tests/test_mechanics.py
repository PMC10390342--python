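"""Core+shell FE model: mesh validity, load-case sign patterns, stripe
perturbation, and conservation/symmetry properties.

The model's claims are sign and ordering patterns of the deformation, not
magnitudes, so tests check signs across load scales and mesh refinement
rather than absolute displacements.
"""

import numpy as np
import pytest

from vncflow.mechanics import (
    LOAD_CASES,
    ShellModel,
    StripeSpec,
    build_model,
    simulate,
    stripe_perturbation,
    _tet_volumes,
)


@pytest.fixture(scope="module")
def model():
    return build_model(
        ShellModel(stripe=StripeSpec(center=100.0, width=20.0, scale=0.2))
    )


@pytest.fixture(scope="module")
def results(model):
    return {case: simulate(model, case) for case in LOAD_CASES}


class TestMesh:
    def test_default_geometry_meshes_without_inverted_elements(self, model):
        vols = _tet_volumes(model.nodes, model.tets)
        assert (vols > 0).all()

    def test_mesh_volume_close_to_analytic(self, model):
        analytic = np.pi * (model.W / 2) * (model.H / 2) * model.L
        meshed = _tet_volumes(model.nodes, model.tets).sum()
        # the polygonal cross-section under-covers the ellipse slightly
        assert meshed == pytest.approx(analytic, rel=0.03)

    def test_stripe_too_narrow_for_mesh_rejected(self):
        with pytest.raises(ValueError, match="too coarse"):
            build_model(
                ShellModel(n_axial=5, stripe=StripeSpec(100.0, 20.0, 0.5))
            )

    def test_head_cap_fixed(self, model):
        assert (model.nodes[model.fixed_nodes, 0] < 1e-9).all()
        r = simulate(model, "anisotropic_tension")
        assert np.allclose(r.displacements[model.fixed_nodes], 0.0)


class TestLoadCases:
    def test_zero_load_zero_displacement(self, model):
        r = simulate(model, "normal_pressure", load_scale=0.0)
        assert np.allclose(r.displacements, 0.0)

    @pytest.mark.parametrize("scale", [0.3, 1.0, 3.0])
    def test_pressure_shrinks_length_and_width(self, model, scale):
        r = simulate(model, "normal_pressure", load_scale=scale)
        assert r.dL < 0 and r.dW < 0

    @pytest.mark.parametrize("scale", [0.3, 1.0, 3.0])
    def test_isotropic_tension_shrinks_and_rounds(self, model, scale):
        r = simulate(model, "isotropic_tension", load_scale=scale)
        assert r.dL < 0 and r.dW < 0
        assert r.eccentricity_mid < r.eccentricity_mid_undeformed

    @pytest.mark.parametrize("scale", [0.3, 1.0, 3.0])
    def test_anisotropic_tension_shortens_and_thickens(self, model, scale):
        r = simulate(model, "anisotropic_tension", load_scale=scale)
        assert r.dL < 0 and r.dW > 0 and r.dH > 0

    def test_tension_cases_conserve_volume(self, model):
        for case in ("isotropic_tension", "anisotropic_tension"):
            r = simulate(model, case)
            assert abs(r.relative_volume_change) < 0.02

    def test_linearity_in_small_load_regime(self, model):
        r1 = simulate(model, "isotropic_tension", load_scale=1.0)
        r2 = simulate(model, "isotropic_tension", load_scale=0.5)
        assert abs(2 * r2.dL - r1.dL) / abs(r1.dL) < 0.10

    def test_unknown_load_case_rejected(self, model):
        with pytest.raises(ValueError, match="load_case"):
            simulate(model, "torsion")

    def test_mirror_symmetry_about_sagittal_plane(self, model):
        """Loads symmetric in y produce a mirror-symmetric displacement field
        (up to the discretization asymmetry of the unstructured mesh)."""
        r = simulate(model, "isotropic_tension")
        nodes = model.nodes
        umax = np.abs(r.displacements).max()
        # match each node to its y-mirrored partner
        key = {tuple(np.round(p, 6)): i for i, p in enumerate(nodes)}
        errs = []
        for i, p in enumerate(nodes):
            j = key.get(tuple(np.round([p[0], -p[1], p[2]], 6)))
            if j is None:
                continue
            ui, uj = r.displacements[i], r.displacements[j]
            errs.append(
                max(abs(ui[0] - uj[0]), abs(ui[1] + uj[1]), abs(ui[2] - uj[2]))
            )
        assert len(errs) > 1000
        # the unstructured mesh breaks exact discrete symmetry; the violation
        # must stay a small fraction of the deformation and vanish on average
        assert np.mean(errs) < 0.05 * umax
        assert np.max(errs) < 0.15 * umax


class TestStripePerturbation:
    def test_scale_one_matches_base(self, model):
        res = stripe_perturbation(model, scale=1.0)
        assert res["perturbed"].tail_displacement == pytest.approx(
            res["base"].tail_displacement, rel=1e-9)

    def test_reduced_stripe_slows_tail(self, model):
        res = stripe_perturbation(model, scale=0.2)
        assert res["perturbed"].tail_displacement < res["base"].tail_displacement

    def test_tail_displacement_monotone_in_scale(self, model):
        tails = [
            stripe_perturbation(model, scale=s)["perturbed"].tail_displacement
            for s in (0.0, 0.25, 0.5, 0.75, 1.0)
        ]
        assert all(a <= b for a, b in zip(tails, tails[1:]))

    def test_model_without_stripe_rejected(self):
        m = build_model(ShellModel())
        with pytest.raises(ValueError, match="no stripe"):
            stripe_perturbation(m)


class TestConvergence:
    def test_refining_mesh_changes_length_response_little(self, model):
        fine = build_model(
            ShellModel(n_theta=32, n_rings=6, n_axial=41)
        )
        r_coarse = simulate(model, "anisotropic_tension")
        r_fine = simulate(fine, "anisotropic_tension")
        assert abs(r_fine.dL - r_coarse.dL) / abs(r_fine.dL) < 0.05
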