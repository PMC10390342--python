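"""Fit an elastic modulus to a synthetic AFM force curve.

Generates an approach curve for a 1 kPa sample probed with a 10 um
spherical bead on a 0.2 N/m cantilever, adds 5% force noise, and fits
the spherical Hertz model over the first 230 nm of indentation with the
contact point estimated jointly.
"""

import numpy as np

import vncflow as vf

model = vf.ContactModel()  # R = 5 um, k = 0.2 N/m, nu = 0.5, depth 230 nm
E_TRUE = 1000.0  # Pa

curve = vf.generate_force_curve(E_TRUE, model, noise_sd=0.05, seed=0)
fit = vf.fit_hertz_curve(curve, model)

print(f"probe: {2 * model.R:.0f} um bead, k = {model.k} N/m, "
      f"fit depth {model.target_depth:.0f} nm")
print(f"true modulus      : {E_TRUE:8.1f} Pa")
print(f"fitted modulus    : {fit.E_eff:8.1f} Pa")
print(f"contact point     : {fit.contact_z:8.1f} nm (true 0)")
print(f"fit residual      : {fit.residual_rms:8.4f} nN rms")

E_hat = [
    vf.fit_hertz_curve(
        vf.generate_force_curve(E_TRUE, model, noise_sd=0.05, seed=s), model
    ).E_eff
    for s in range(25)
]
print(f"25-curve ensemble : {np.mean(E_hat):8.1f} +/- {np.std(E_hat):.1f} Pa")
print("The effective modulus is recovered without bias despite the noise;")
print("a stiffening tissue would shift this distribution upward.")
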