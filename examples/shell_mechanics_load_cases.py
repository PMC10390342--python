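"""Which shell loading reproduces the observed tissue shape change?

Solves the core+shell model (soft elastic core in a capped elliptical
cylinder, head end fixed, thin surface shell) under three load cases and
prints the resulting shape changes. The observed phase-1 change is
length down, width and height up at constant volume — only the
anisotropic (axially dominant) surface tension produces that pattern.
"""

import vncflow as vf
from vncflow.mechanics import LOAD_CASES, StripeSpec

model = vf.build_model(
    vf.ShellModel(stripe=StripeSpec(center=100.0, width=20.0, scale=0.2))
)
print(f"geometry L={model.L:.0f} x W={model.W:.0f} x H={model.H:.0f} um, "
      f"E_core={model.E_core:.0f} Pa, nu={model.nu_core}")
print()
print("load case            dL(um)   dW(um)   dH(um)  dV/V     ecc(mid)")
for case in LOAD_CASES:
    r = vf.simulate(model, case)
    print(f"{case:20s} {r.dL:+7.2f} {r.dW:+8.2f} {r.dH:+8.2f} "
          f"{r.relative_volume_change:+7.4f}  "
          f"{r.eccentricity_mid_undeformed:.3f} -> {r.eccentricity_mid:.3f}")

print()
res = vf.stripe_perturbation(model, scale=0.2)
print("Reducing surface tension to 20% inside a 20 um central stripe:")
print(f"  tail displacement {res['base'].tail_displacement:.2f} um -> "
      f"{res['perturbed'].tail_displacement:.2f} um")
print("A local cut in the shell slows the distant tail: the surface acts as")
print("one mechanically connected network.")
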