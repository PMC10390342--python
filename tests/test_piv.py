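"""PIV engine: oracle equivalence on synthetic speckle, validity rules,
and interpolation properties."""

import numpy as np
import pytest

import vncflow as vf
from vncflow.containers import ImageStack
from vncflow.piv import PIV_PRESETS, InterpolationKernel, PIVParams, get_preset
from tests.conftest import make_field


def shifted_stack(shift_px, pixel_size, n_frames=3, image_px=128, seed=1,
                  frame_interval=5.0):
    """Noise-free speckle stack advected by a uniform integer-pixel shift."""
    speed = abs(shift_px) * pixel_size / frame_interval
    axis = (-1.0, 0.0) if shift_px < 0 else (1.0, 0.0)
    spec = vf.FlowSpec("uniform", peak_speed=speed, axis=axis)
    flow = vf.generate_flow_field(spec, (image_px * pixel_size,) * 2)
    return vf.render_speckle_stack(
        flow,
        vf.SpeckleParams(
            image_shape=(image_px, image_px), pixel_size=pixel_size,
            frame_interval=frame_interval, n_frames=n_frames, seed=seed,
        ),
    )


class TestParams:
    def test_presets_match_reported_values(self):
        p, k = get_preset("confocal_whole")
        assert (p.source_size, p.search_size, p.grid_size, p.corr_threshold) == (
            9.0, 16.0, 5.0, 0.5)
        assert (k.spatial_size, k.spatial_sigma) == (50.0, 10.0)
        assert (k.temporal_size, k.temporal_sigma, k.temporal_unit) == (
            90.0, 40.0, "min")
        p, k = get_preset("confocal_hires")
        assert (p.source_size, p.search_size, p.grid_size, p.corr_threshold) == (
            2.0, 4.0, 1.0, 0.3)
        assert (k.spatial_size, k.spatial_sigma, k.temporal_size,
                k.temporal_sigma, k.temporal_unit) == (10.0, 2.0, 5.0, 2.0, "frames")
        p, _ = get_preset("mosaic")
        assert (p.source_size, p.search_size, p.grid_size, p.corr_threshold) == (
            5.0, 10.0, 3.0, 0.5)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            PIVParams(source_size=10, search_size=5, grid_size=3, corr_threshold=0.5)
        with pytest.raises(ValueError):
            PIVParams(source_size=5, search_size=10, grid_size=3, corr_threshold=1.5)
        with pytest.raises(KeyError, match="unknown PIV preset"):
            get_preset("widefield")


class TestComputePIV:
    def test_identical_frames_give_zero_displacement(self):
        stack = shifted_stack(0, pixel_size=0.5)
        fields = vf.compute_piv(stack, get_preset("mosaic")[0])
        assert fields.valid.all()
        assert np.abs(fields.u / 0.5).max() < 0.05  # px
        assert np.abs(fields.v / 0.5).max() < 0.05

    @pytest.mark.parametrize("preset", sorted(PIV_PRESETS))
    def test_uniform_shift_recovered_within_rms_budget(self, preset):
        params, _ = get_preset(preset)
        px = 0.5
        shift = -3 if preset != "confocal_hires" else -2  # within search margin
        stack = shifted_stack(shift, pixel_size=px, image_px=96)
        fields = vf.compute_piv(stack, params)
        assert fields.valid.mean() > 0.8
        u_px = fields.u[fields.valid] / px
        v_px = fields.v[fields.valid] / px
        assert np.sqrt(np.mean((u_px - shift) ** 2)) <= 0.2
        assert np.sqrt(np.mean(v_px**2)) <= 0.2

    def test_validity_fraction_monotone_in_threshold(self):
        stack = shifted_stack(-2, pixel_size=0.5, image_px=96)
        noisy = ImageStack(
            data=np.clip(
                stack.data
                + np.random.default_rng(0).normal(0, 0.3, stack.data.shape),
                0, None),
            pixel_size=0.5, frame_interval=5.0,
        )
        fracs = []
        for thr in (0.1, 0.3, 0.5, 0.7, 0.9):
            params = PIVParams(5.0, 10.0, 3.0, thr)
            fracs.append(vf.compute_piv(noisy, params).valid.mean())
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_constant_window_is_invalid_not_nan(self):
        data = np.ones((2, 64, 64))
        data[:, 40:50, 40:50] += np.random.default_rng(1).random((2, 10, 10))
        stack = ImageStack(data=data, pixel_size=0.5, frame_interval=5.0)
        fields = vf.compute_piv(stack, PIVParams(3.0, 6.0, 3.0, 0.5))
        assert not fields.valid.all()
        assert np.isfinite(fields.u).all()

    def test_window_larger_than_image_rejected(self):
        stack = shifted_stack(0, pixel_size=0.5, image_px=16)
        with pytest.raises(ValueError, match="larger than image"):
            vf.compute_piv(stack, PIVParams(9.0, 16.0, 5.0, 0.5))

    def test_roi_mask_invalidates_outside(self):
        stack = shifted_stack(-2, pixel_size=0.5, image_px=96)
        mask = np.zeros(stack.frame_shape, dtype=bool)
        mask[:, :48] = True
        fields = vf.compute_piv(stack, get_preset("mosaic")[0], roi_mask=mask)
        xx = np.meshgrid(fields.x, fields.y)[0]
        outside = xx / 0.5 >= 48
        assert not fields.valid[:, outside].any()

    def test_rotation_consistency(self):
        """Rotating the stack by 90 deg rotates the recovered field by 90 deg."""
        px = 0.5
        stack = shifted_stack(-3, pixel_size=px, image_px=96)
        params = get_preset("mosaic")[0]
        f0 = vf.compute_piv(stack, params)
        rot = ImageStack(
            data=np.rot90(stack.data, k=1, axes=(1, 2)).copy(),
            pixel_size=px, frame_interval=5.0,
        )
        f1 = vf.compute_piv(rot, params)
        # a -x displacement becomes a +y displacement under CCW rotation
        # (rows of the rotated image run along the original +x axis reversed)
        assert np.median(f0.u[f0.valid]) == pytest.approx(-1.5, abs=0.1)
        assert np.median(f1.v[f1.valid]) == pytest.approx(
            -np.median(f0.u[f0.valid]), abs=0.1)
        assert np.abs(np.median(f1.u[f1.valid])) < 0.1


class TestInterpolation:
    def test_uniform_field_unchanged(self):
        field = make_field(u=1.2, v=-0.7)
        kernel = InterpolationKernel(50.0, 10.0, 90.0, 40.0, "min")
        out = vf.interpolate_field_series(field, kernel)
        assert np.allclose(out.u[out.valid], 1.2)
        assert np.allclose(out.v[out.valid], -0.7)

    def test_single_valid_vector_propagates_alone(self):
        field = make_field(u=0.0, v=0.0, n_frames=1, nx=9, ny=9)
        field.valid[:] = False
        field.valid[0, 4, 4] = True
        field.u[0, 4, 4] = 2.5
        field.v[0, 4, 4] = -1.0
        kernel = InterpolationKernel(30.0, 10.0, 3.0, 1.0, "frames")
        out = vf.interpolate_field_series(field, kernel)
        assert out.valid[0, 4, 4]
        got = out.u[0][out.valid[0]]
        assert np.allclose(got, 2.5)
        assert np.allclose(out.v[0][out.valid[0]], -1.0)
        # nodes beyond the truncation window (size 30 um = +-3 grid steps
        # per axis) stay invalid
        assert not out.valid[0, 0, 0]

    def test_convex_combination_bounds(self):
        rng = np.random.default_rng(2)
        field = make_field(n_frames=4, nx=9, ny=9)
        field.u[:] = rng.normal(0, 1, field.u.shape)
        field.v[:] = rng.normal(0, 1, field.v.shape)
        field.valid[:] = rng.random(field.u.shape) > 0.3
        kernel = InterpolationKernel(20.0, 5.0, 3.0, 1.0, "frames")
        out = vf.interpolate_field_series(field, kernel)
        assert out.u[out.valid].max() <= field.u[field.valid].max() + 1e-12
        assert out.u[out.valid].min() >= field.u[field.valid].min() - 1e-12

    def test_small_kernel_warns(self):
        field = make_field()
        with pytest.warns(UserWarning, match="nearest-neighbour"):
            vf.interpolate_field_series(
                field, InterpolationKernel(2.0, 1.0, 3.0, 1.0, "frames")
            )
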