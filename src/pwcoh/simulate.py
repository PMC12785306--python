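"""Synthetic linear-array plane-wave channel data with reverberation clutter.

The simulator emulates the statistical structure the coherence-loss method
relies on, at desk-scale cost:

* **speckle** — sub-resolution point scatterers placed uniformly at a
  configurable density with i.i.d. standard-normal amplitudes, giving
  fully developed (Rayleigh-envelope) speckle that stays coherent across
  steering angles;
* **anechoic inclusions** — disks whose scatterers are attenuated by an
  echogenicity multiplier (0 removes them entirely), standing in for the
  silicone-rod / vessel-lumen targets used in contrast evaluation;
* **multipath reverberation** — a comb model: every recorded echo
  bounces between the transducer face and a reflecting layer at depth
  ``d``, gaining order-``m`` replicas delayed by ``2·m·d/c`` and scaled
  by ``r^m``. A scatterer at depth ``z`` grows ghosts at apparent depth
  ``z + m·d`` at normal incidence that shift axially with steering
  angle, reproducing the angle-decorrelating clutter the frame-selection
  criterion targets — without a full multiple-scattering wave solver.

Physics follows the same idealizations as the selection calculus: ideal
plane wavefronts, homogeneous sound speed, straight rays, no attenuation
or element directivity. Echo waveforms are Gaussian-modulated sinusoids
(default 50% fractional bandwidth, so one speckle spans ≈ two carrier
cycles). The transmit-delay convention matches the DAS beamformer exactly,
so simulated targets reconstruct at their true positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import yaml
from scipy.signal import gausspulse

from .acquisition import AngleSequence, ProbeConfig, PWAcquisition
from .das import transmit_delay
from .io import save_acquisition

__all__ = [
    "Pulse",
    "Inclusion",
    "ReverbLayer",
    "SceneConfig",
    "Scene",
    "make_scene",
    "simulate_channel_data",
    "add_reverberation",
    "make_corpus",
]


@dataclass(frozen=True)
class Pulse:
    """Gaussian-envelope excitation pulse."""

    f0: float
    fractional_bandwidth: float = 0.5

    def waveform(self, t):
        """Evaluate the pulse at times ``t`` (seconds, zero-centered)."""
        return gausspulse(np.asarray(t), fc=self.f0, bw=self.fractional_bandwidth, bwr=-6)

    def cutoff(self) -> float:
        """Half-width (s) beyond which the envelope is below −60 dB."""
        return float(
            gausspulse("cutoff", fc=self.f0, bw=self.fractional_bandwidth, bwr=-6, tpr=-60)
        )


@dataclass(frozen=True)
class Inclusion:
    """Disk with modified echogenicity (0 = anechoic)."""

    center: tuple[float, float]  # (x, z) meters
    radius: float
    echogenicity: float = 0.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("inclusion radius must be positive")
        if self.echogenicity < 0:
            raise ValueError("echogenicity must be >= 0")


@dataclass(frozen=True)
class ReverbLayer:
    """Reflecting layer for the comb reverberation model."""

    depth: float
    reflection_coefficient: float
    max_order: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.reflection_coefficient < 1.0:
            raise ValueError("reflection coefficient must lie in (0, 1)")
        if self.max_order < 1:
            raise ValueError("max_order must be >= 1")
        if self.depth <= 0:
            raise ValueError("layer depth must be positive")


@dataclass(frozen=True)
class SceneConfig:
    """Study conditions for one synthetic acquisition.

    ``speckle_density`` is in scatterers per mm² (default 40, several per
    resolution cell at the default F-number-2 beamforming, enough for fully
    developed Rayleigh speckle); ``noise_snr_db``
    sets additive white Gaussian noise relative to the RF signal RMS
    (default 40 dB — channel noise well below speckle level).
    """

    speckle_density: float = 40.0  # scatterers / mm^2
    inclusions: tuple[Inclusion, ...] = ()
    reverb_layers: tuple[ReverbLayer, ...] = ()
    noise_snr_db: float = 40.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.speckle_density <= 0:
            raise ValueError("speckle_density must be positive")


@dataclass(frozen=True)
class Scene:
    """Realized scatterer field: positions (x, z) in meters and amplitudes."""

    positions: np.ndarray  # (n, 2)
    amplitudes: np.ndarray  # (n,)
    extent: tuple[float, float, float, float]  # (x0, x1, z0, z1)


def make_scene(cfg: SceneConfig, extent: tuple[float, float, float, float]) -> Scene:
    """Draw the scatterer field for ``extent`` = (x0, x1, z0, z1) meters.

    The count is Poisson with mean density × area; positions are uniform;
    amplitudes i.i.d. standard normal. Scatterers inside an inclusion have
    their amplitude multiplied by its echogenicity (0 ⇒ removed).
    """
    x0, x1, z0, z1 = extent
    area_mm2 = (x1 - x0) * (z1 - z0) * 1e6
    if area_mm2 <= 0:
        raise ValueError("extent must have positive area")
    rng = np.random.default_rng(cfg.rng_seed)
    n = int(rng.poisson(cfg.speckle_density * area_mm2))
    xs = rng.uniform(x0, x1, size=n)
    zs = rng.uniform(z0, z1, size=n)
    amps = rng.standard_normal(n)
    for inc in cfg.inclusions:
        inside = (xs - inc.center[0]) ** 2 + (zs - inc.center[1]) ** 2 <= inc.radius**2
        amps = np.where(inside, amps * inc.echogenicity, amps)
    keep = amps != 0.0
    return Scene(
        positions=np.column_stack([xs[keep], zs[keep]]),
        amplitudes=amps[keep],
        extent=extent,
    )


def simulate_channel_data(
    scene: Scene,
    probe: ProbeConfig,
    angles: AngleSequence,
    pulse: Pulse | None = None,
    t0: float = 0.0,
    n_samples: int | None = None,
    noise_snr_db: float | None = None,
    rng: np.random.Generator | int | None = None,
) -> PWAcquisition:
    """Superpose scatterer echoes into per-angle RF channel data.

    Arrival time at element ``e`` for a scatterer at (x, z) and steering
    angle θ is the plane-wave transmit delay (aperture-center reference,
    non-negativity offset — identical to the DAS convention) plus the
    return distance ``sqrt((x−x_e)² + z²)/c``. Echo amplitude is the
    scatterer amplitude (linear superposition, no attenuation); the
    waveform is the Gaussian-modulated sinusoid of ``pulse``.
    """
    pulse = pulse or Pulse(f0=probe.f0, fractional_bandwidth=probe.fractional_bandwidth)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    ex = probe.element_positions
    xs = scene.positions[:, 0] if len(scene.positions) else np.empty(0)
    zs = scene.positions[:, 1] if len(scene.positions) else np.empty(0)

    half = pulse.cutoff()
    L = int(np.ceil(half * probe.fs))
    offsets = np.arange(-L, L + 1)

    if n_samples is None:
        _, _, _, z1 = scene.extent
        t_end = (z1 + np.sqrt(z1**2 + (probe.aperture_width) ** 2)) / probe.c
        t_end += (probe.aperture_width / 2.0) * np.sin(np.deg2rad(angles.span)) / probe.c
        n_samples = int(np.ceil((t_end - t0) * probe.fs)) + 2 * L + 2

    k = len(angles)
    data = np.zeros((k, n_samples, probe.n_elements))
    truncated = False
    if len(xs):
        dist_rx = np.sqrt(zs[:, None] ** 2 + (xs[:, None] - ex[None, :]) ** 2)  # (n, E)
        for a, angle in enumerate(angles.angles):
            t_tx = transmit_delay(xs, zs, float(angle), probe)  # (n,)
            arrival = t_tx[:, None] + dist_rx / probe.c  # (n, E)
            base = np.round((arrival - t0) * probe.fs).astype(np.intp)  # (n, E)
            idx = base[:, :, None] + offsets[None, None, :]  # (n, E, 2L+1)
            t_off = t0 + idx / probe.fs - arrival[:, :, None]
            vals = scene.amplitudes[:, None, None] * pulse.waveform(t_off)
            elem = np.broadcast_to(
                np.arange(probe.n_elements)[None, :, None], idx.shape
            )
            valid = (idx >= 0) & (idx < n_samples)
            flat = idx[valid] * probe.n_elements + elem[valid]
            plane = np.bincount(flat, weights=vals[valid], minlength=n_samples * probe.n_elements)
            data[a] = plane.reshape(n_samples, probe.n_elements)
            truncated |= bool(np.any((base < 0) | (base >= n_samples)))
    if truncated:
        warnings.warn(
            "part of the scene falls outside the recorded time window; echoes truncated",
            stacklevel=2,
        )

    snr = noise_snr_db
    if snr is not None:
        signal_rms = float(np.sqrt(np.mean(data**2)))
        ref = signal_rms if signal_rms > 0 else 1.0
        sigma = ref * 10.0 ** (-snr / 20.0)
        data = data + rng.normal(0.0, sigma, size=data.shape)

    return PWAcquisition(probe=probe, angles=angles, channel_data=data, data_kind="rf", t0=t0)


def add_reverberation(acq: PWAcquisition, layers: tuple[ReverbLayer, ...]) -> PWAcquisition:
    """Apply the comb reverberation model to recorded RF data.

    Each echo bounces back and forth between the transducer face and a
    reflecting layer at depth ``d``, so for every order ``m = 1…M`` the
    recorded traces are added back delayed by ``2·m·d/c`` and scaled by
    ``r^m``. In the beamformed image a scatterer at depth ``z`` gains
    ghosts near apparent depth ``z + m·d`` at 0° that migrate axially
    with steering angle — the decorrelation the frame selection exploits.
    """
    data = acq.channel_data.copy()
    for layer in layers:
        for m in range(1, layer.max_order + 1):
            shift = int(round(2.0 * m * layer.depth * acq.probe.fs / acq.probe.c))
            if shift >= data.shape[1]:
                break
            scale = layer.reflection_coefficient**m
            data[:, shift:, :] += scale * acq.channel_data[:, : data.shape[1] - shift, :]
    return PWAcquisition(
        probe=acq.probe, angles=acq.angles, channel_data=data, data_kind=acq.data_kind, t0=acq.t0
    )


def make_corpus(
    n_acquisitions: int,
    probe: ProbeConfig,
    angles: AngleSequence,
    template: SceneConfig,
    extent: tuple[float, float, float, float],
    out_dir,
    seed: int = 0,
    radius_jitter: float = 0.2,
) -> list[Path]:
    """Generate ``n_acquisitions`` varied containers plus ROI sidecars.

    Each acquisition re-seeds the scene, jitters the inclusion centers
    laterally (±1 mm) and radii (±``radius_jitter`` relative), simulates
    channel data, applies the template's reverberation layers, and writes
    ``acq_###.h5`` together with ``acq_###_roi.yaml`` whose target disk
    lies inside the (first) anechoic inclusion and whose background
    annulus surrounds it at the same depth.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(seed)
    paths: list[Path] = []
    for i in range(n_acquisitions):
        sub = int(master.integers(0, 2**31 - 1))
        rng = np.random.default_rng(sub)
        inclusions = []
        for inc in template.inclusions:
            dx = float(rng.uniform(-1e-3, 1e-3))
            scale = float(rng.uniform(1.0 - radius_jitter, 1.0 + radius_jitter))
            inclusions.append(replace(inc, center=(inc.center[0] + dx, inc.center[1]),
                                      radius=inc.radius * scale))
        cfg = replace(template, inclusions=tuple(inclusions), rng_seed=sub)
        scene = make_scene(cfg, extent)
        acq = simulate_channel_data(
            scene, probe, angles, noise_snr_db=cfg.noise_snr_db, rng=rng
        )
        acq = add_reverberation(acq, cfg.reverb_layers)
        path = out_dir / f"acq_{i:03d}.h5"
        save_acquisition(acq, path)
        if inclusions:
            inc = inclusions[0]
            roi = {
                "target": {
                    "shape": "disk",
                    "center": [float(inc.center[0]), float(inc.center[1])],
                    "radius": float(inc.radius * 0.6),
                },
                "background": {
                    "shape": "annulus",
                    "center": [float(inc.center[0]), float(inc.center[1])],
                    "r_inner": float(inc.radius * 1.3),
                    "r_outer": float(inc.radius * 1.9),
                },
            }
            with open(out_dir / f"acq_{i:03d}_roi.yaml", "w") as fh:
                yaml.safe_dump(roi, fh)
        paths.append(path)
    return paths
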