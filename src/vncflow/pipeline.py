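"""Run orchestration: configuration, stage execution, and manifests.

A run is described by a small YAML/dict config (stage list, input paths,
modality preset, calibration, seeds, output directory). Stages execute in
dependency order — simulate -> piv -> interpolate -> stats/kymo, then the
independent tracks / shape / intensity / bleach / afm / mech stages — and
the manifest records package version, parameters, seeds, and a SHA-256
hash of every output file, so reruns with identical seeds can be checked
for bit-identical deterministic outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import afm as afm_mod
from . import flowstats, intensity, mechanics, morphometry, photobleach, synthetic, tracks as tracks_mod
from .containers import ForceCurve, ImageStack
from .piv import PIV_PRESETS, compute_piv, get_preset, interpolate_field_series

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "piv",
    "stats",
    "tracks",
    "shape",
    "intensity",
    "bleach",
    "afm",
    "mech",
)


def default_config() -> dict:
    """A self-contained synthetic demo configuration."""
    return {
        "stages": list(STAGES),
        "out_dir": "vncflow_run",
        "seed": 0,
        "preset": "mosaic",
        "pixel_size_um": 0.5,
        "frame_interval_min": 5.0,
        "simulate": {
            "flow": {"kind": "tail_to_head_gradient", "peak_speed": 1.0,
                     "gradient_length": 150.0, "axis": [-1.0, 0.0]},
            "image_shape": [96, 96],
            "n_frames": 5,
            "n_tracks": 40,
            "track_frames": 61,  # 600 min at 10 min/frame: covers both phase windows
            "afm_modulus_pa": 800.0,
            "outline_axes_um": [20.0, 15.0],
            "bleach_shift_um": 5.0,
        },
    }


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError("run config must be a mapping")
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict | str | Path) -> dict:
    """Execute the configured stages and return (and write) the manifest."""
    if not isinstance(config, dict):
        config = load_config(config)
    preset_name = config.get("preset", "mosaic")
    if preset_name not in PIV_PRESETS:
        raise ValueError(
            f"unknown preset {preset_name!r}; available: {sorted(PIV_PRESETS)}"
        )
    stages = config.get("stages", list(STAGES))
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out_dir = Path(config.get("out_dir", "vncflow_run"))
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    px = float(config.get("pixel_size_um", 0.5))
    dt = float(config.get("frame_interval_min", 5.0))
    sim = config.get("simulate", default_config()["simulate"])

    manifest: dict = {
        "package_version": __version__,
        "config": config,
        "seed": seed,
        "stages": {},
    }

    state: dict = {}

    def record(stage: str, outputs: list[Path], params: dict | None = None) -> None:
        manifest["stages"][stage] = {
            "outputs": {str(p.relative_to(out_dir)): _sha256(p) for p in outputs},
            "params": params or {},
            "completed_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        logger.info("stage %s: %d outputs", stage, len(outputs))

    if "simulate" in stages:
        spec = synthetic.FlowSpec(**sim["flow"])
        shape = tuple(sim.get("image_shape", [96, 96]))
        geom = (shape[1] * px, shape[0] * px)
        flow = synthetic.generate_flow_field(spec, geom)
        stack = synthetic.render_speckle_stack(
            flow,
            synthetic.SpeckleParams(
                image_shape=shape, pixel_size=px, frame_interval=dt,
                n_frames=int(sim.get("n_frames", 5)), seed=seed,
            ),
        )
        stack_path = out_dir / "stack.tif"
        stack.save_tiff(stack_path)
        state["stack"] = stack

        track_df = synthetic.generate_tracks(
            spec, n_tracks=int(sim.get("n_tracks", 40)),
            n_frames=int(sim.get("track_frames", 20)),
            frame_interval=10.0, jitter_sd=0.5, seed=seed, domain=geom,
        )
        tracks_path = out_dir / "tracks.csv"
        track_df.to_csv(tracks_path, index=False)

        curve = synthetic.generate_force_curve(
            float(sim.get("afm_modulus_pa", 800.0)), afm_mod.ContactModel(),
            noise_sd=0.02, seed=seed,
        )
        curve_path = out_dir / "force_curve.csv"
        curve.to_dataframe().to_csv(curve_path, index=False)

        a_ax, b_ax = sim.get("outline_axes_um", [20.0, 15.0])
        outline = synthetic.generate_outline(a_ax, b_ax, noise_sd=0.05 * a_ax, seed=seed)
        outline_path = out_dir / "outline.csv"
        pd.DataFrame(outline, columns=["x_um", "y_um"]).to_csv(outline_path, index=False)

        scene = synthetic.generate_condensation_scene(seed=seed)
        scene_path = out_dir / "scene.json"
        scene.to_json(scene_path)
        state["scene"] = scene

        x, p0, p1 = synthetic.generate_bleach_profile(
            shift_um=float(sim.get("bleach_shift_um", 5.0)), noise_sd=0.05, seed=seed
        )
        bleach_path = out_dir / "bleach_profiles.csv"
        pd.DataFrame({"x_um": x, "t0": p0, "t1": p1}).to_csv(bleach_path, index=False)
        record("simulate", [stack_path, tracks_path, curve_path, outline_path,
                            scene_path, bleach_path], {"flow": sim["flow"]})

    if "piv" in stages:
        if "stack" not in state:
            stack_file = out_dir / "stack.tif"
            if not stack_file.exists():
                raise RuntimeError("piv stage requires the simulate stage output 'stack.tif'")
            state["stack"] = ImageStack.from_tiff(stack_file, px, dt)
        params, kernel = get_preset(preset_name)
        fields = compute_piv(state["stack"], params)
        smoothed = interpolate_field_series(fields, kernel)
        state["fields"], state["smoothed"] = fields, smoothed
        piv_paths = fields.save_csv(out_dir / "piv", prefix="raw")
        piv_paths += smoothed.save_csv(out_dir / "piv", prefix="interp")
        record("piv", piv_paths, {"preset": preset_name})

    if "stats" in stages:
        if "fields" not in state:
            raise RuntimeError("stats stage requires the piv stage to have run")
        kymo = flowstats.kymograph(state["smoothed"], mode="speed")
        kymo_path = out_dir / "kymograph.csv"
        pd.DataFrame(kymo.values, index=kymo.positions).to_csv(kymo_path)
        coh = flowstats.local_alignment_coherence(state["fields"], seed=seed)
        dcoh = flowstats.directional_coherence(state["smoothed"])
        coh_path = out_dir / "coherence.csv"
        pd.DataFrame(
            {"frame": np.arange(len(coh.values)),
             "local_alignment": coh.values,
             "directional": dcoh.values}
        ).to_csv(coh_path, index=False)
        record("stats", [kymo_path, coh_path])

    if "tracks" in stages:
        tracks_file = out_dir / "tracks.csv"
        if not tracks_file.exists():
            raise RuntimeError("tracks stage requires the simulate stage output 'tracks.csv'")
        df = tracks_mod.load_tracks(tracks_file)
        sets = tracks_mod.filter_and_window_tracks(df)
        rows = []
        for (region, window), sub in sets.items():
            summ = tracks_mod.track_directionality(sub)
            rows.append(
                {"region": region, "window_start_min": window[0],
                 "window_end_min": window[1], "n_tracks": summ.n_tracks,
                 "mean_average_velocity_um_min": summ.mean_average_velocity,
                 "mean_resultant_length": summ.mean_resultant_length}
            )
        tracks_out = out_dir / "track_summary.csv"
        pd.DataFrame(rows).to_csv(tracks_out, index=False)
        record("tracks", [tracks_out])

    if "shape" in stages:
        outline_file = out_dir / "outline.csv"
        if not outline_file.exists():
            raise RuntimeError("shape stage requires the simulate stage output 'outline.csv'")
        outline = pd.read_csv(outline_file)[["x_um", "y_um"]].to_numpy()
        fit = morphometry.fit_ellipse(outline)
        scene = state.get("scene") or synthetic.CondensationScene.from_json(out_dir / "scene.json")
        rows = []
        for label, idx in (("start", 0), ("end_phase1", None), ("end_phase2", -1)):
            if idx is None:
                idx = int(np.searchsorted(scene.times, scene.phase_boundaries[0]))
            L, W, H = scene.dims[idx]
            geo = morphometry.cylinder_geometry(morphometry.TissueDims(L, W, H, label))
            rows.append({"timepoint": label, "L_um": L, "W_um": W, "H_um": H, **geo})
        shape_out = out_dir / "shape_metrics.csv"
        df = pd.DataFrame(rows)
        df["outline_eccentricity"] = fit.eccentricity
        df.to_csv(shape_out, index=False)
        record("shape", [shape_out])

    if "intensity" in stages:
        scene = state.get("scene") or synthetic.CondensationScene.from_json(out_dir / "scene.json")
        trace = intensity.IntensityTrace(
            times=scene.times,
            intensity=intensity.moving_average(scene.col4_intensity, 10),
            raw=scene.col4_intensity, smooth_window=10,
        )
        cond = intensity.CondensationTrace(
            times=scene.times, displacement=scene.tail_displacement,
            rate=np.gradient(scene.tail_displacement, scene.times),
        )
        corr = intensity.intensity_rate_correlation(
            trace, cond, t_range=(0.0, scene.phase_boundaries[0])
        )
        out = out_dir / "intensity_rate.csv"
        pd.DataFrame(
            {"time_min": corr["times"], "intensity": corr["intensity"],
             "rate_um_min": corr["rate"]}
        ).to_csv(out, index=False)
        record("intensity", [out], {"pearson_r": corr["pearson_r"]})

    if "bleach" in stages:
        bleach_file = out_dir / "bleach_profiles.csv"
        if not bleach_file.exists():
            raise RuntimeError("bleach stage requires the simulate stage output 'bleach_profiles.csv'")
        df = pd.read_csv(bleach_file)
        res = photobleach.stripe_analysis(
            df["x_um"].to_numpy(), df["t0"].to_numpy(), df["t1"].to_numpy(),
            expected_stripes=5,
        )
        out = out_dir / "stripe_displacements.csv"
        res.to_dataframe().to_csv(out, index=False)
        record("bleach", [out])

    if "afm" in stages:
        curve_file = out_dir / "force_curve.csv"
        if not curve_file.exists():
            raise RuntimeError("afm stage requires the simulate stage output 'force_curve.csv'")
        curve = ForceCurve.from_csv(curve_file)
        model = afm_mod.ContactModel()
        fit = afm_mod.fit_hertz_curve(curve, model)
        out = out_dir / "afm_fits.csv"
        pd.DataFrame(
            [{"curve_id": 0, "contact_nm": fit.contact_z, "E_pa": fit.E_eff,
              "rms_nN": fit.residual_rms}]
        ).to_csv(out, index=False)
        record("afm", [out])

    if "mech" in stages:
        mech_cfg = config.get("mech", {})
        model = mechanics.build_model(
            mechanics.ShellModel(
                stripe=mechanics.StripeSpec(center=100.0, width=20.0, scale=0.2),
                **mech_cfg,
            )
        )
        rows = []
        for case in mechanics.LOAD_CASES:
            r = mechanics.simulate(model, case)
            rows.append({"load_case": case, "dL_um": r.dL, "dW_um": r.dW,
                         "dH_um": r.dH, "tail_displacement_um": r.tail_displacement,
                         "rel_volume_change": r.relative_volume_change,
                         "ecc_mid": r.eccentricity_mid})
        stripe_res = mechanics.stripe_perturbation(model)
        rows.append({"load_case": "anisotropic_tension+stripe",
                     "dL_um": stripe_res["perturbed"].dL,
                     "dW_um": stripe_res["perturbed"].dW,
                     "dH_um": stripe_res["perturbed"].dH,
                     "tail_displacement_um": stripe_res["perturbed"].tail_displacement,
                     "rel_volume_change": stripe_res["perturbed"].relative_volume_change,
                     "ecc_mid": stripe_res["perturbed"].eccentricity_mid})
        out = out_dir / "mech_summary.csv"
        pd.DataFrame(rows).to_csv(out, index=False)
        record("mech", [out])

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
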