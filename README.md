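# vncflow

Quantification and modeling toolkit for studying how extracellular-matrix
(ECM) assembly reshapes the *Drosophila* embryonic ventral nerve cord
(VNC) during condensation — the sudden shortening of the nerve cord that
coincides with the exponential assembly of collagen IV (Col4) on its
surface. The package is written for developmental biophysicists who need
to turn time-lapse microscopy, cell tracks, AFM force curves, and
cross-section outlines into the quantities that test a surface-tension
account of tissue morphogenesis:

- **PIV** (`vncflow.piv`): windowed zero-mean normalized cross-correlation
  between consecutive frames, with sub-pixel Gaussian peak refinement and
  truncated-Gaussian spatiotemporal smoothing. Ships the three presets
  used for whole-tissue confocal (source 9 µm / search 16 µm / grid 5 µm /
  threshold 0.5), high-resolution confocal (2 / 4 / 1 / 0.3) and
  light-sheet (5 / 10 / 3 / 0.5) acquisitions.
- **Flow statistics** (`vncflow.flowstats`): speed and x-component
  kymographs along the anterior–posterior (AP) axis; *local alignment
  coherence* — the mean |cos θ| between 256 sampled reference vectors and
  their neighbours within 8 µm (1 = locally coherent motion, 2/π ≈ 0.64
  for random orientations); *directional coherence* — the mean signed
  cos θ against the tail-to-head axis on an 11×11, 3 µm-spaced sample of
  the smoothed field.
- **Track analysis** (`vncflow.tracks`): filtering (> 10 frames), phase
  windows (0–3 h and 7–10 h), head/tail split, start-to-end angles with
  polar histograms (0 = head-to-tail axis), and mean average velocity.
- **Morphometry** (`vncflow.morphometry`): the tissue idealized as an
  elliptical cylinder — volume π·(W/2)·(H/2)·L and closed surface area
  with Ramanujan's perimeter approximation; direct algebraic ellipse fits
  of cross-section outlines with eccentricity e = √(a²−b²)/a; shape-based
  z-interpolation of sparse polygon annotations into volumes.
- **Intensity dynamics** (`vncflow.intensity`): induction time courses
  (10-frame moving average at 2-min sampling), AP-axis surface profiles
  with the bright-puncta discard rule (70% of maximum) and a 200 µm
  walking average, tail-displacement traces, and the intensity ×
  condensation-rate Pearson correlation.
- **Photobleach stripe tracking** (`vncflow.photobleach`): normalized
  midline profiles, 150-point smoothing, automatic minima detection, and
  rank-paired per-stripe displacements (negative = head-ward).
- **AFM** (`vncflow.afm`): force-curve calibration (F = k·d,
  δ = z-travel − deflection) and a spherical-tip Hertz fit
  F = (4/3)·E/(1−ν²)·√R·δ^(3/2) over a 230 nm target depth with the
  contact point estimated jointly with E.
- **Shell mechanics** (`vncflow.mechanics`): a two-material finite
  element model — a soft, nearly incompressible elastic core shaped as a
  capped elliptical cylinder, fixed at the head, loaded by a thin surface
  shell exerting normal pressure, isotropic tension, or axially biased
  anisotropic tension, optionally weakened in a central stripe.
- **Synthetic data** (`vncflow.synthetic`): seeded generators for every
  input — advected speckle stacks, drifting tracks, Hertzian force
  curves, noisy elliptical outlines, bleach-stripe profiles, and a
  two-phase condensation scene (isovolumetric phase 1, volume loss in
  phase 2) with known ground truth.
- **Pipeline** (`vncflow.pipeline`, CLI `vncflow`): stage orchestration
  with YAML configs and SHA-256 output manifests for reproducible runs.

## Worked example

`examples/shell_mechanics_load_cases.py` asks which shell loading can
explain the observed phase-1 shape change (length down, width and height
up, volume constant):

```
geometry L=200 x W=40 x H=20 um, E_core=100 Pa, nu=0.49

load case            dL(um)   dW(um)   dH(um)  dV/V     ecc(mid)
normal_pressure        -0.22    -0.04    -0.02 -0.0030  0.866 -> 0.866
isotropic_tension      -2.85    -0.19    +0.38 -0.0016  0.866 -> 0.859
anisotropic_tension    -5.62    +0.53    +0.32 -0.0014  0.866 -> 0.865

Reducing surface tension to 20% inside a 20 um central stripe:
  tail displacement 5.62 um -> 5.15 um
```

Uniform pressure shortens the tissue but also constricts it; isotropic
tension shortens, narrows, and rounds the cross-section; only the
anisotropic, axially dominant tension reproduces the observed pattern
(ΔL < 0, ΔW > 0, ΔH > 0 at near-constant volume). A local tension cut
slows the distant tail — the surface behaves as one connected network.

Each other capability has its own narrative script under `examples/`
(PIV flow recovery, coherence statistics, track directionality,
condensation morphometry — including the ~15% phase-1 surface-area drop
implied by isovolumetric shortening — AFM fitting, photobleach stripes,
and the intensity–condensation correlation).

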