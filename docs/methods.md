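# Methods

## Problem and model

Single plane-wave imaging (SPWI) reconstructs a frame from one unfocused
transmit, reaching kilohertz frame rates at the cost of strong clutter —
in particular multipath reverberation, which appears as ghost structures
at incorrect depths and is hard to remove because it is spatially
correlated much like tissue.

The package trains an image-to-image enhancer f(·) on complex beamformed
I/Q frames without any labels. For a steered-frame stack {P_1 … P_k} the
training signal is the *coherence loss*

    L = −(1/|T_i|) Σ_{t ∈ T_i}  Re⟨f(P_i), P_t*⟩ / √(⟨f(P_i), f(P_i)*⟩ ⟨P_t, P_t*⟩),

the negative mean normalized cross-correlation between the enhanced
reference frame and a set of target frames T_i. Tissue echoes originate
at fixed anatomical positions and stay coherent across steering angles;
reverberation ghosts shift axially with the steering angle and
decorrelate. Maximizing gated cross-frame correlation therefore preserves
tissue and suppresses clutter.

The gate is physical. Between a transmit steered by θ and an unsteered
one, an echo at depth z is displaced axially by 2z(sec θ − 1). A
broadband pulse with 50% fractional bandwidth has a speckle cell of about
two carrier cycles, so echoes become statistically independent once the
displacement exceeds 2λ. Evaluated at the effective maximum imaging depth

    z_FOV = W / (2 tan θ_max)          (W = aperture width)

this gives the maximum decorrelation angle

    θ_dec = arccos( z_FOV / (z_FOV + λ) )

and the minimum index separation between reference and target frames

    N_excl = max(1, round(θ_dec / Δθ) · 2),      Δθ = span / (k − 1).

Targets are then T_i = { j : |j − i| ≥ N_excl, j ≠ i }. For a 75-angle,
38.4 mm-aperture configuration at λ = 0.308 mm this yields N_excl = 36 at
±8° and 24 at ±18° — wider spans decorrelate faster per index step.

Assumptions inherited from the geometry: ideal plane wavefronts,
homogeneous sound speed, straight-ray propagation. Sound-speed
heterogeneity of real tissue (±5% or so) perturbs the displacement
proportionally but stays within the 2λ margin; the criterion is
deliberately conservative (the ×2 in N_excl covers both sides of the
reference, so admitted pairs are separated by at least ≈ 2·θ_dec).

### Interpretation choices

* **Eq. operator precedence.** `round(θ_dec/Δθ)·2` is used (guaranteeing
  an even count); the alternative `round((θ_dec/Δθ)·2)` reproduces the
  same 36/24 reference counts and is covered by a regression check in the
  acceptance suite.
* **Pair distance under center removal.** During training the 0° frame is
  held out; distances are measured after removing it and re-indexing the
  remaining frames contiguously. Validation uses the center frame as
  reference in the original indexing.
* **Complex correlation → real scalar.** The real part of the normalized
  inner product is used (a sign-flipped frame scores −1, preserving
  phase opposition); the magnitude reduction is available as
  `mode="magnitude"` for ablations.
* **Normalization scope.** One max-abs scalar per frame *set*, not per
  frame, so relative inter-frame amplitudes — which the loss depends
  on — are preserved.

## Front-end

Delay-and-sum with dynamic receive focusing at F-number 2 on a λ/3 pixel
grid: receive aperture half-width z/(2F), rectangular apodization, linear
interpolation in time with explicit exp(i2πf0 τ) phase rotation for
demodulated data, out-of-window samples contribute zero. RF is
demodulated to baseband I/Q by Hilbert transform and exp(−i2πf0 t) mixing,
no decimation. The transmit-delay reference (wavefront crosses the
aperture center at t = 0, plus a (W/2)|sin θ|/c non-negativity offset) and
the rectangular apodization are conventions chosen here; the simulator
uses the identical convention so simulated targets reconstruct at their
true positions (verified to within one λ/3 cell in the tests).

## Network and optimization

A five-level encoder–decoder (U-Net-style) maps (2, H, W) I/Q channels to
an enhanced frame of the same shape: per level two 3×3 convolutions with
LeakyReLU (negative slope 0.2), 2×2 max pooling between levels, nearest-
neighbor ×2 upsampling + 3×3 convolution with skip concatenation on the
way up (a 2×2 transposed-convolution variant sits behind a flag), a 1×1
head with tanh. Kaiming-normal initialization; no normalization layers.
Full-scale channel widths are (32, 64, 128, 256, 512).

Because no autodiff framework is a dependency, forward *and* backward
passes are implemented directly in numpy (convolutions as nine shifted
channel-mixing matmuls); the loss gradients with respect to the
prediction are analytic. All gradients are validated against central
finite differences in the test suite (relative agreement ~1e−6 at float64).

Training follows the reference recipe: AdamW (decoupled weight decay
1e−2), batch size 1, cosine learning-rate cycle from 1e−4 to 1e−7
restarting every 20,000 steps, 40,000 steps total, 256×256 random crops
(one shared window across reference and targets per draw), validation on
the zero-padded (1024×1024, never resized) held-out 0° frame every 500
steps, best-validation checkpointing. "Cycling" is realized as cosine
annealing with warm restarts; a triangular variant sits behind a flag.
Each step draws one acquisition uniformly, then one non-center reference
uniformly. Every random draw descends from the single configured seed, so
runs are bit-reproducible.

## Synthetic data

The simulator generates what the method needs statistically, not a
full-wave solution:

* point scatterers at 40/mm² (several per resolution cell at the
  default F-number-2 beamforming → fully developed, Rayleigh-envelope
  speckle), i.i.d. standard-normal
  amplitudes, uniform placement with Poisson counts;
* anechoic disk inclusions (echogenicity multiplier, 0 removes
  scatterers) standing in for rod/vessel targets;
* reverberation as a comb model: echoes bounce between the transducer
  face and a reflecting layer at depth d with reflectivity r, so every
  echo gains order-m replicas delayed by 2md/c and scaled by r^m. A
  scatterer at depth z grows ghosts near apparent depth z + md at 0°
  that migrate axially with steering angle —
  exactly the angle-decorrelating behavior the selection criterion
  exploits (asserted directly in the tests: clutter patch correlation
  falls with angular separation while same-depth speckle stays coherent);
* additive white Gaussian channel noise at 40 dB SNR.

Omitted on purpose: frequency-dependent attenuation (the selection
criterion neglects it too), element directivity, elevation effects,
aberration. Consequently, passing tests demonstrate the mechanism —
physics-gated coherence training suppresses angle-decorrelating clutter —
not clinical performance on heterogeneous tissue.

### Desk-scale study conditions

Tests and the worked example run a scaled-down configuration chosen once:
64-element, 0.3 mm pitch, 5 MHz array (W = 19.2 mm, λ = 0.308 mm),
15 plane waves spanning ±18° (N_excl = 6), 128×128 λ/3 grid from 6 mm
depth, scene 16 × 18 mm. The clutter phantom emulation places a
reflecting layer at 6 mm with r = 0.7, M = 2 above an anechoic inclusion
(radius 2.5 mm) centered at 10 mm, so first-order ghosts of the shallow
speckle land *inside* the target — reproducing the severe in-target
reverberation regime of a vessel-like phantom (single-PW CNR near or
below 0 dB, compounding a few dB better). The layer depth matters: a
layer whose first-order ghosts miss the inclusion leaves the single-PW
baseline nearly clutter-free inside the target and the enhancement has
nothing to remove there.
Desk-scale training uses the same recipe at 2,000 steps (one cosine
cycle), 128×128 patches, and channel widths (8, 16, 32, 64, 128) — the
full five-level architecture at a quarter of the full-scale width, which
the training-benefit check shows is enough capacity to raise held-out
contrast within that step budget. The full-scale widths remain the
package defaults.

## Metrics

CNR in dB, 20·log10(|μ_i − μ_o| / √((σ_i² + σ_o²)/2)), and gCNR,
1 − Σ_bins min(h_i, h_o) with 256 shared-support bins, both computed on
the linear envelope (log-domain variants behind a flag). gCNR is exactly
scale-invariant (bin edges are recomputed) and invariant to monotone
intensity maps up to binning tolerance. ROIs are rasterized disks,
annuli, or rectangles in meters; disjointness is enforced.

## Numerical choices and degeneracies

* Correlation denominators get ε = 1e−12 only when an argument has zero
  energy (with a warning; both-zero returns 0), keeping exact ±1 for the
  clean cases.
* Zero mean difference in CNR returns −∞ with a warning; empty ROIs are
  rejected.
* An empty target set raises (training skips the draw with a log;
  a selection that empties *every* reference warns at construction).
* Max-pool ties resolve to the first occurrence; crop offsets are uniform
  over valid positions; float32 is the training dtype, float64 the
  gradient-checking dtype.

## Known limitations

The comb reverberation model has no multiple-scattering phase diversity;
clutter suppression numbers on it do not transfer quantitatively to
tissue. Desk-scale training runs (minutes on one CPU) demonstrate trend
and ordering, not converged image quality; full-scale runs (40,000
steps, wide networks, large multi-configuration corpora) are what the
defaults describe but are not exercised by the suite. Curved and phased
arrays are unsupported (the FOV geometry assumes a linear array).
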