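"""Generators: ground-truth fidelity and determinism."""

import numpy as np
import pytest
from skimage.registration import phase_cross_correlation

import vncflow as vf
from vncflow.afm import ContactModel, hertz_force
from vncflow.morphometry import TissueDims, cylinder_geometry


class TestFlowField:
    def test_zero_flow_is_identically_zero(self):
        f = vf.generate_flow_field(vf.FlowSpec("zero"))
        vx, vy = f(12.3, 45.6, 7.0)
        assert vx == 0.0 and vy == 0.0

    def test_uniform_flow_matches_spec_everywhere(self):
        f = vf.generate_flow_field(
            vf.FlowSpec("uniform", peak_speed=2.0, axis=(-1, 0))
        )
        x = np.array([0.0, 50.0, 199.0])
        vx, vy = f(x, x / 2, 0.0)
        assert np.allclose(vx, -2.0) and np.allclose(vy, 0.0)

    def test_gradient_speed_ramps_linearly_from_tail(self):
        # tail at x = 200 for axis (-1, 0): 50 um from the tail -> half speed
        f = vf.generate_flow_field(
            vf.FlowSpec("tail_to_head_gradient", peak_speed=2.0,
                        gradient_length=100.0, axis=(-1, 0)),
            stack_geometry=(200.0, 100.0),
        )
        vx, vy = f(150.0, 50.0, 0.0)
        assert np.hypot(vx, vy) == pytest.approx(1.0)
        # beyond the gradient length the speed clamps at zero
        vx, vy = f(50.0, 50.0, 0.0)
        assert np.hypot(vx, vy) == 0.0

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown flow kind"):
            vf.FlowSpec("sideways")

    def test_axis_is_normalized(self):
        spec = vf.FlowSpec("uniform", peak_speed=1.0, axis=(3, 4))
        assert np.hypot(*spec.axis) == pytest.approx(1.0)


class TestSpeckleStack:
    def test_zero_flow_no_noise_gives_identical_frames(self):
        f = vf.generate_flow_field(vf.FlowSpec("zero"))
        stack = vf.render_speckle_stack(
            f, vf.SpeckleParams(image_shape=(64, 64), n_frames=4, seed=0)
        )
        for t in range(1, 4):
            assert np.array_equal(stack.data[0], stack.data[t])

    def test_uniform_shift_recovered_by_phase_correlation(self):
        # 3 px/frame toward -x at 0.5 um/px, 5 min/frame
        spec = vf.FlowSpec("uniform", peak_speed=3 * 0.5 / 5.0, axis=(-1, 0))
        f = vf.generate_flow_field(spec, (64, 64))
        stack = vf.render_speckle_stack(
            f, vf.SpeckleParams(image_shape=(128, 128), n_frames=3, seed=1)
        )
        shift, _, _ = phase_cross_correlation(stack.data[0], stack.data[1])
        assert tuple(shift) == (0.0, 3.0)

    def test_same_seed_bit_identical(self):
        f = vf.generate_flow_field(vf.FlowSpec("zero"))
        p = vf.SpeckleParams(image_shape=(48, 48), n_frames=3, noise_sd=0.1, seed=5)
        s1 = vf.render_speckle_stack(f, p)
        s2 = vf.render_speckle_stack(f, p)
        assert np.array_equal(s1.data, s2.data)

    def test_bleaching_decays_exponentially(self):
        f = vf.generate_flow_field(vf.FlowSpec("zero"))
        p = vf.SpeckleParams(image_shape=(48, 48), n_frames=3,
                             bleach_rate=0.01, frame_interval=5.0, seed=2)
        s = vf.render_speckle_stack(f, p)
        ratio = s.data[1].sum() / s.data[0].sum()
        assert ratio == pytest.approx(np.exp(-0.01 * 5.0), rel=1e-6)

    def test_excessive_flow_warns(self):
        spec = vf.FlowSpec("uniform", peak_speed=10 * 0.5 / 5.0, axis=(-1, 0))
        f = vf.generate_flow_field(spec, (32, 32))
        with pytest.warns(UserWarning, match="search margin"):
            vf.render_speckle_stack(
                f,
                vf.SpeckleParams(image_shape=(64, 64), n_frames=2, seed=0),
                piv_search_margin_px=3.5,
            )


class TestTracks:
    def test_table_shape_and_monotone_frames(self):
        df = vf.generate_tracks(vf.FlowSpec("zero"), n_tracks=100, n_frames=20,
                                jitter_sd=1.0, seed=0)
        assert len(df) == 2000
        for _, grp in df.groupby("track_id"):
            assert grp["frame"].is_monotonic_increasing

    def test_pure_drift_runs_along_axis(self):
        df = vf.generate_tracks(
            vf.FlowSpec("uniform", peak_speed=0.1, axis=(1, 0)),
            n_tracks=10, n_frames=5, frame_interval=10.0, jitter_sd=0.0, seed=1,
        )
        for _, grp in df.groupby("track_id"):
            dx = grp["x_um"].iloc[-1] - grp["x_um"].iloc[0]
            dy = grp["y_um"].iloc[-1] - grp["y_um"].iloc[0]
            assert dx == pytest.approx(4.0)  # 0.1 um/min * 10 min * 4 steps
            assert dy == pytest.approx(0.0)

    def test_random_walk_mean_displacement_near_zero(self):
        n_tracks, n_frames, jitter = 200, 20, 1.0
        df = vf.generate_tracks(vf.FlowSpec("zero"), n_tracks=n_tracks,
                                n_frames=n_frames, jitter_sd=jitter, seed=3)
        nets = []
        for _, grp in df.groupby("track_id"):
            nets.append(
                [grp["x_um"].iloc[-1] - grp["x_um"].iloc[0],
                 grp["y_um"].iloc[-1] - grp["y_um"].iloc[0]]
            )
        mean_net = np.linalg.norm(np.mean(nets, axis=0))
        bound = 3 * jitter * np.sqrt(n_frames) / np.sqrt(n_tracks)
        assert mean_net < bound


class TestForceCurveGenerator:
    def test_noiseless_curve_satisfies_hertz_law(self):
        m = ContactModel()
        c = vf.generate_force_curve(1000.0, m, noise_sd=0.0)
        post = c.z > 0
        delta = c.z[post] - c.deflection[post]
        f = m.k * c.deflection[post]
        assert np.allclose(f, hertz_force(delta, 1000.0, m), atol=1e-9)

    def test_zero_indentation_zero_force(self):
        m = ContactModel()
        c = vf.generate_force_curve(1000.0, m, noise_sd=0.0)
        assert np.all(c.deflection[c.z <= 0] == 0.0)

    def test_force_linear_in_modulus(self):
        m = ContactModel()
        c1 = vf.generate_force_curve(500.0, m, noise_sd=0.0)
        c2 = vf.generate_force_curve(1000.0, m, noise_sd=0.0)
        # compare at equal indentation: interpolate F(delta)
        def f_of_delta(c):
            post = c.z > 0
            return (c.z[post] - c.deflection[post]), m.k * c.deflection[post]
        d1, f1 = f_of_delta(c1)
        d2, f2 = f_of_delta(c2)
        grid = np.linspace(50, 200, 10)
        # interpolation onto a common indentation grid bounds the comparison
        assert np.allclose(
            2 * np.interp(grid, d1, f1), np.interp(grid, d2, f2), rtol=1e-3
        )


class TestOutline:
    def test_circle_points(self):
        pts = vf.generate_outline(10.0, 10.0, 100)
        assert np.allclose(np.linalg.norm(pts, axis=1), 10.0)

    def test_axes_swap_keeps_major_first(self):
        pts = vf.generate_outline(3.0, 5.0, 100)
        assert np.abs(pts[:, 0]).max() == pytest.approx(5.0)

    def test_seeded_noise_deterministic(self):
        a = vf.generate_outline(5, 3, 50, noise_sd=0.1, seed=9)
        b = vf.generate_outline(5, 3, 50, noise_sd=0.1, seed=9)
        assert np.array_equal(a, b)


class TestCondensationScene:
    def test_phase1_volume_conserved(self):
        scene = vf.generate_condensation_scene()
        in1 = scene.times <= scene.phase_boundaries[0]
        vols = [
            cylinder_geometry(TissueDims(*d))["volume"] for d in scene.dims[in1]
        ]
        assert np.ptp(vols) / vols[0] < 1e-6

    def test_phase2_volume_decreases(self):
        scene = vf.generate_condensation_scene()
        in2 = scene.times > scene.phase_boundaries[0]
        vols = np.array(
            [cylinder_geometry(TissueDims(*d))["volume"] for d in scene.dims[in2]]
        )
        assert np.all(np.diff(vols) < 0)

    def test_surface_area_decreases_in_phase1(self):
        scene = vf.generate_condensation_scene()
        i1 = int(np.searchsorted(scene.times, scene.phase_boundaries[0]))
        area0 = cylinder_geometry(TissueDims(*scene.dims[0]))["surface_area"]
        area1 = cylinder_geometry(TissueDims(*scene.dims[i1]))["surface_area"]
        assert area1 < area0
        # the isovolumetric shortening produces a double-digit relative drop
        assert 0.10 < (area0 - area1) / area0 < 0.20

    def test_intensity_is_exponential_before_saturation(self):
        scene = vf.generate_condensation_scene()
        p = vf.CondensationParams()
        sel = scene.times < p.intensity_t_sat - 10
        I = scene.col4_intensity[sel]
        ratios = I[5:] / I[:-5]
        assert np.allclose(ratios, np.exp(p.intensity_rate * 5 * p.dt), rtol=1e-9)

    def test_tail_displacement_monotone_and_zero_at_start(self):
        scene = vf.generate_condensation_scene(seed=4)
        assert scene.tail_displacement[0] == 0.0
        assert np.all(np.diff(scene.tail_displacement) >= 0)


class TestBleachProfile:
    def test_flat_without_stripes(self):
        x, p0, p1 = vf.generate_bleach_profile(stripe_centers=())
        assert np.allclose(p0, 1.0) and np.allclose(p1, 1.0)

    def test_single_dip_shifts_headward(self):
        x, p0, p1 = vf.generate_bleach_profile(
            length_um=200.0, stripe_centers=(100.0,), shift_um=5.0
        )
        assert x[np.argmin(p0)] == pytest.approx(100.0, abs=0.11)
        assert x[np.argmin(p1)] == pytest.approx(95.0, abs=0.11)

    def test_protocol_defaults_have_five_stripes(self):
        x, p0, _ = vf.generate_bleach_profile()
        from scipy.signal import find_peaks

        pk, _ = find_peaks(-p0, prominence=0.1)
        assert len(pk) == 5
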