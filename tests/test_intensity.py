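"""Intensity time courses, AP profiles, tail traces, and the
intensity-condensation correlation."""

import numpy as np
import pandas as pd
import pytest

import vncflow as vf
from vncflow.containers import ImageStack
from vncflow.intensity import (
    CondensationTrace,
    IntensityTrace,
    ap_profile,
    intensity_rate_correlation,
    intensity_timecourse,
    moving_average,
    tail_displacement,
)


class TestTimecourse:
    def test_constant_stack_gives_constant_trace(self):
        stack = ImageStack(np.full((20, 8, 8), 3.5), 0.5, 2.0)
        trace = intensity_timecourse(stack)
        assert np.allclose(trace.intensity, 3.5)
        assert trace.smooth_window == 10

    def test_exponential_trace_close_to_analytic_away_from_edges(self):
        k = 0.01
        t = np.arange(60) * 2.0
        data = np.exp(k * t)[:, None, None] * np.ones((60, 4, 4))
        stack = ImageStack(data, 0.5, 2.0)
        trace = intensity_timecourse(stack, window=10)
        inner = slice(10, 50)
        assert np.allclose(
            trace.intensity[inner], np.exp(k * t)[inner], rtol=0.01
        )


class TestAPProfile:
    def test_uniform_image_flat_profile(self):
        x, prof = ap_profile(np.full((40, 100), 2.0), pixel_size=1.0)
        assert np.allclose(prof, 2.0)

    def test_gradient_recovered_despite_bright_puncta(self):
        rng = np.random.default_rng(0)
        w = 400
        base = np.linspace(2.0, 1.0, w)[None, :] * np.ones((60, w))
        img = base.copy()
        # bright intracellular puncta at 10x background
        ii = rng.integers(0, 60, 200)
        jj = rng.integers(0, w, 200)
        img[ii, jj] = 20.0
        x, prof = ap_profile(img, pixel_size=1.0, window_um=20.0)
        inner = slice(30, w - 30)
        slope_fit = np.polyfit(x[inner], prof[inner], 1)[0]
        slope_true = (1.0 - 2.0) / (w - 1)
        assert slope_fit == pytest.approx(slope_true, rel=0.05)

    def test_scale_invariance_of_discard_rule(self):
        rng = np.random.default_rng(1)
        img = rng.random((30, 80)) + 0.5
        x0, p0 = ap_profile(img, pixel_size=1.0, window_um=5.0)
        x1, p1 = ap_profile(img * 37.0, pixel_size=1.0, window_um=5.0)
        assert np.allclose(p1, 37.0 * p0)

    def test_all_discarded_raises(self):
        img = np.zeros((10, 10))
        img[0, 0] = 1.0
        with pytest.raises(ValueError, match="discarded"):
            ap_profile(img, pixel_size=1.0, discard_fraction=-0.1)

    def test_quantile_mode_available(self):
        rng = np.random.default_rng(2)
        img = rng.random((30, 80))
        x, prof = ap_profile(img, pixel_size=1.0, discard_mode="quantile")
        assert np.isfinite(prof).all()


class TestTailDisplacement:
    def test_static_tail_zero(self):
        pts = pd.DataFrame({"frame": range(10), "x": 5.0, "y": 7.0})
        trace = tail_displacement(pts)
        assert np.allclose(trace.displacement, 0.0)

    def test_constant_speed_slope(self):
        t = np.arange(30)
        pts = pd.DataFrame({"frame": t, "x": 0.5 * 2.0 * t, "y": 0.0})
        trace = tail_displacement(pts, frame_interval=2.0)
        slope = np.polyfit(trace.times, trace.displacement, 1)[0]
        assert slope == pytest.approx(0.5)
        assert np.allclose(trace.rate, 0.5)

    def test_translation_invariance(self):
        t = np.arange(20)
        pts = pd.DataFrame({"frame": t, "x": t * 1.0, "y": t * 0.5})
        shifted = pts.assign(x=pts["x"] + 100, y=pts["y"] - 50)
        a = tail_displacement(pts).displacement
        b = tail_displacement(shifted).displacement
        assert np.allclose(a, b)

    def test_ap_projection_signed(self):
        t = np.arange(10)
        pts = pd.DataFrame({"frame": t, "x": -1.0 * t, "y": 0.0})
        trace = tail_displacement(pts, projection="ap_axis", axis=(1, 0))
        assert trace.displacement[-1] == pytest.approx(-9.0)


class TestCorrelation:
    def test_proportional_series_give_r_one(self):
        t = np.arange(50) * 2.0
        intensity = 1.0 + 0.1 * t
        trace = IntensityTrace(t, intensity, intensity, 1)
        cond = CondensationTrace(t, np.cumsum(intensity) * 2.0, intensity)
        out = intensity_rate_correlation(trace, cond, smooth_window=1)
        assert out["pearson_r"] == pytest.approx(1.0)

    def test_default_scene_correlates_in_phase1(self):
        scene = vf.generate_condensation_scene(
            vf.CondensationParams(intensity_noise_sd=0.05,
                                  displacement_noise_sd=0.5),
            seed=0,
        )
        trace = IntensityTrace(
            scene.times, moving_average(scene.col4_intensity, 10),
            scene.col4_intensity, 10,
        )
        cond = CondensationTrace(
            scene.times, scene.tail_displacement,
            np.gradient(scene.tail_displacement, scene.times),
        )
        out = intensity_rate_correlation(
            trace, cond, t_range=(0.0, scene.phase_boundaries[0])
        )
        assert out["pearson_r"] > 0.9

    def test_independent_noise_gives_low_r(self):
        t = np.arange(90) * 2.0
        rs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            trace = IntensityTrace(t, rng.normal(size=90), None, 1)
            cond = CondensationTrace(t, None, rng.normal(size=90))
            out = intensity_rate_correlation(trace, cond, smooth_window=1)
            rs.append(abs(out["pearson_r"]))
        assert np.quantile(rs, 0.95) < 0.3

    def test_zero_variance_flagged(self):
        t = np.arange(30) * 2.0
        trace = IntensityTrace(t, np.ones(30), None, 1)
        cond = CondensationTrace(t, None, np.arange(30.0))
        out = intensity_rate_correlation(trace, cond, smooth_window=1)
        assert out["zero_variance"]
        assert np.isnan(out["pearson_r"])
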