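# pwcoh — unsupervised coherence-loss beamforming for single plane-wave ultrasound

Single plane-wave imaging (SPWI) fires one unfocused transmit per frame
and reaches kilohertz frame rates, but the images are degraded by
multipath **reverberation clutter** — ghost echoes at wrong depths that
correlate spatially much like real tissue. `pwcoh` implements an
unsupervised route to suppressing that clutter: a U-Net-style enhancer is
trained on complex beamformed I/Q frames with a **physics-gated coherence
loss**, no labels and no compounded "ground truth" required.

The idea: between a transmit steered by θ and an unsteered one, an echo
at depth z is displaced axially by `2z(sec θ − 1)`. A 50%
fractional-bandwidth pulse spans about two wavelengths, so once that
displacement exceeds `2λ` the clutter in the two frames is statistically
independent while tissue — anchored to fixed anatomy — stays coherent.
Evaluated at the effective maximum depth `z_FOV = W/(2 tan θ_max)` this
gives a decorrelation angle `θ_dec = arccos(z_FOV/(z_FOV + λ))` and a
minimum reference-to-target index separation
`N_excl = max(1, round(θ_dec/Δθ)·2)`. The training loss

    L = −(1/|T_i|) Σ_{t∈T_i} Re⟨f(P_i), P_t*⟩ / √(⟨f(P_i),f(P_i)*⟩⟨P_t,P_t*⟩),
    T_i = { j : |j−i| ≥ N_excl, j ≠ i }

rewards correlation of the enhanced frame only with frames whose clutter
has decorrelated, so minimizing it keeps tissue and removes ghosts.

The package is for ultrasound-imaging researchers who want a testable,
CPU-only reference implementation: a delay-and-sum front-end (dynamic
receive focusing, F-number 2, λ/3 grid), the frame-selection calculus,
the coherence/MSE losses with analytic gradients, a numpy U-Net with
hand-derived backpropagation (no deep-learning framework dependency),
CNR/gCNR metrics, and a plane-wave channel-data simulator with speckle,
anechoic inclusions, and comb-model reverberation. Everything hangs off
two objects: `PlaneWaveEnhancer` (built from data) and the
`PlaneWaveEnhancerResults` its `fit()` returns.

## Worked example

Frame selection for a 75-angle ±18° sequence on a 128-element, 0.3 mm
pitch, 5 MHz array (the `pwcoh select-frames` CLI prints the same):

```python
from pwcoh import AngleSequence, ProbeConfig, selection_for_acquisition

probe = ProbeConfig(n_elements=128, pitch=0.3e-3, f0=5e6, c=1540.0, fs=20e6)
sel = selection_for_acquisition(probe, AngleSequence.symmetric(18.0, 75))
print(f"z_FOV     = {sel.z_fov*1e3:.3f} mm")
print(f"theta_dec = {sel.theta_dec:.4f} deg")
print(f"N_excl    = {sel.n_excl}")
```

```
z_FOV     = 59.092 mm
theta_dec = 5.8373 deg
N_excl    = 24
```

i.e. the aperture stops overlapping beyond 59 mm; at that depth a 5.84°
steer displaces clutter by 2λ; with Δθ = 36°/74 that is 12 index steps,
doubled to cover both sides of the reference. At ±8° the same calculus
gives N_excl = 36 — narrower spans need more exclusion.

End-to-end on synthetic data (simulate → beamform → train → evaluate; a
few minutes on one CPU at the desk scale used in the test suite):

```python
from pwcoh import (BeamformConfig, PixelGrid, PlaneWaveEnhancer, ProbeConfig,
                   AngleSequence, Inclusion, ReverbLayer, SceneConfig,
                   beamform_all, load_acquisition, make_corpus)
from pwcoh.training import TrainConfig
from pwcoh.network import NetworkSpec

probe = ProbeConfig(n_elements=64, pitch=0.3e-3, f0=5e6, c=1540.0, fs=20e6)
angles = AngleSequence.symmetric(18.0, 15)
scene = SceneConfig(
    inclusions=(Inclusion(center=(0.0, 10e-3), radius=2.5e-3),),
    reverb_layers=(ReverbLayer(depth=6e-3, reflection_coefficient=0.7, max_order=2),),
)
paths = make_corpus(4, probe, angles, scene, (-8e-3, 8e-3, 2e-3, 20e-3),
                    "corpus/", seed=123)
grid = PixelGrid.lambda_third(probe, z0=6e-3, nz=128, nx=128)
frame_sets = [beamform_all(load_acquisition(p), BeamformConfig(grid=grid))
              for p in paths]

cfg = TrainConfig(total_steps=2000, cycle_steps=2000, patch=128, val_pad=128,
                  network=NetworkSpec(channel_widths=(8, 16, 32, 64, 128)))
model = PlaneWaveEnhancer(frame_sets[:3], [probe] * 3, config=cfg)
results = model.fit(seed=0)
print(results.summary())
```

This configuration printed:

```
Plane-wave coherence enhancer — fit summary
===============================================
loss mode:          optimized
steps run:          2000
network parameters: 540154
final train loss:   -0.3889
best val loss:      -0.2762
per-dataset frame selection:
  dataset 0: z_FOV =   29.55 mm, theta_dec =  8.237 deg, N_excl = 6
  dataset 1: z_FOV =   29.55 mm, theta_dec =  8.237 deg, N_excl = 6
  dataset 2: z_FOV =   29.55 mm, theta_dec =  8.237 deg, N_excl = 6
```

A train loss of −0.39 means the enhanced frame correlates at ≈ 0.39 on
average with its decorrelated target frames. Evaluating on the held-out
fourth acquisition (ROI sidecars are written next to each simulated
container):

```python
import yaml
from pwcoh.metrics import roi_from_geometry

roi_spec = yaml.safe_load(open("corpus/acq_003_roi.yaml"))
rois = roi_from_geometry(roi_spec["target"], roi_spec["background"], grid)
print(results.evaluate(frame_sets[3], rois))
```

```
cnr_das_1pw     -5.275198
gcnr_das_1pw     0.273612
cnr_enhanced    -1.659947
gcnr_enhanced    0.409807
```

The raw single-plane-wave image is dominated by reverberation ghosts
inside the anechoic inclusion (CNR −5.3 dB); the enhancer recovers
+3.6 dB of contrast and raises gCNR from 0.27 to 0.41 because the ghosts
decorrelate across the selected frame pairs while the surrounding speckle
does not.

A `pwcoh` CLI wraps the same stages (`simulate`, `beamform`,
`select-frames`, `train` via `run`, `enhance`, `evaluate`); see
`pwcoh --help`.

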