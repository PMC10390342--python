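"""Correlate Col4 induction with the rate of tissue condensation.

Generates the default condensation scene with measurement noise, builds
the smoothed intensity trace (10-frame moving average at 2-min sampling)
and the tail-displacement trace, and reports the Pearson correlation of
intensity with condensation rate over the fast phase.
"""

import numpy as np

import vncflow as vf
from vncflow.intensity import (
    CondensationTrace, IntensityTrace, intensity_rate_correlation,
    moving_average,
)

scene = vf.generate_condensation_scene(
    vf.CondensationParams(intensity_noise_sd=0.05, displacement_noise_sd=0.5),
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

print(f"samples in phase 1        : {len(out['times'])} (2-min resolution)")
print(f"intensity fold change     : "
      f"{out['intensity'][-1] / out['intensity'][0]:.1f}x")
print(f"peak condensation rate    : {out['rate'].max():.2f} um/min")
print(f"Pearson r (phase 1)       : {out['pearson_r']:.3f}")
print()
print("The strong positive correlation mirrors the coupling between")
print("exponential Col4 assembly and the accelerating motion of the tissue")
print("tail; it is a statistical association, not a causal claim.")
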