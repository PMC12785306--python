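"""Delay-and-sum beamforming of plane-wave channel data.

Per-angle complex I/Q images are reconstructed with dynamic receive
focusing: for each pixel the receive aperture half-width is
``z / (2 · f_number)``, elements outside it are excluded (rectangular
apodization), and each contributing trace is sampled at the two-way delay
with linear interpolation in time plus an explicit ``exp(i 2π f0 τ)``
phase rotation appropriate for demodulated data.

Transmit-delay convention: the plane wavefront crosses the aperture center
at t = 0 and a constant offset ``(W/2)·|sin θ| / c`` keeps delays
non-negative over the whole aperture. Samples requested beyond the recorded
window contribute zero (never clamped), so the image bottom is unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .acquisition import AngleSequence, FrameSet, PixelGrid, ProbeConfig, PWAcquisition

__all__ = [
    "BeamformConfig",
    "transmit_delay",
    "receive_delay",
    "rf_to_iq",
    "dynamic_aperture_mask",
    "das_beamform_frame",
    "beamform_all",
    "coherent_compound",
]


@dataclass(frozen=True)
class BeamformConfig:
    """Delay-and-sum settings (defaults follow the package's λ/3, F=2 policy)."""

    grid: PixelGrid
    f_number: float = 2.0
    interpolation: str = "linear"
    apodization: str = "rect"

    def __post_init__(self) -> None:
        if self.f_number <= 0:
            raise ValueError("f_number must be positive")
        if self.interpolation != "linear":
            raise ValueError("only linear time interpolation is supported")
        if self.apodization != "rect":
            raise ValueError("only rectangular apodization is supported")


def transmit_delay(x, z, angle_deg: float, probe: ProbeConfig):
    """One-way plane-wave arrival time at pixel ``(x, z)`` in seconds.

    ``(z cos θ + x sin θ + (W/2)|sin θ|) / c`` — the projection of the pixel
    onto the propagation direction, offset so the delay is non-negative
    across the aperture.
    """
    if not -90.0 < angle_deg < 90.0:
        raise ValueError(f"steering angle must lie strictly within ±90°, got {angle_deg}")
    th = np.deg2rad(angle_deg)
    offset = (probe.aperture_width / 2.0) * abs(np.sin(th))
    return (np.asarray(z) * np.cos(th) + np.asarray(x) * np.sin(th) + offset) / probe.c


def receive_delay(x, z, element_x, c: float):
    """Return-path time from pixel ``(x, z)`` to an element at ``element_x``."""
    return np.sqrt(np.asarray(z) ** 2 + (np.asarray(x) - np.asarray(element_x)) ** 2) / c


def rf_to_iq(acq: PWAcquisition) -> PWAcquisition:
    """Demodulate real RF traces to complex baseband I/Q.

    Analytic signal (Hilbert transform along the time axis) multiplied by
    ``exp(−i 2π f0 t)``; no decimation, so the time axis is unchanged.
    Passes I/Q input through untouched.
    """
    if acq.data_kind == "iq":
        return acq
    analytic = hilbert(acq.channel_data, axis=1)
    t = acq.sample_times[None, :, None]
    iq = analytic * np.exp(-2j * np.pi * acq.probe.f0 * t)
    return PWAcquisition(
        probe=acq.probe, angles=acq.angles, channel_data=iq, data_kind="iq", t0=acq.t0
    )


def dynamic_aperture_mask(z, x, element_x, f_number: float):
    """Boolean mask of elements inside the depth-proportional receive aperture.

    Half-width is ``z / (2 · f_number)``, so the element count grows
    linearly with depth (slope ``1/(2·f_number)`` per side in pitch units)
    until the physical aperture is exhausted.
    """
    half = np.asarray(z) / (2.0 * f_number)
    return np.abs(np.asarray(x) - np.asarray(element_x)) <= half


def das_beamform_frame(acq: PWAcquisition, angle_index: int, cfg: BeamformConfig) -> np.ndarray:
    """Beamform one steering angle onto ``cfg.grid``; returns a complex image."""
    iq = rf_to_iq(acq)
    probe = iq.probe
    grid = cfg.grid
    data = iq.channel_data[angle_index]  # (n_samples, n_elements)
    n_samples = data.shape[0]
    angle = float(iq.angles.angles[angle_index])

    Z = grid.z[:, None]  # (nz, 1)
    X = grid.x[None, :]  # (1, nx)
    t_tx = transmit_delay(X, Z, angle, probe)  # (nz, nx)

    image = np.zeros(grid.shape, dtype=np.complex128)
    two_pi_f0 = 2.0 * np.pi * probe.f0
    for e, ex in enumerate(probe.element_positions):
        tau = t_tx + receive_delay(X, Z, ex, probe.c)
        s = (tau - iq.t0) * probe.fs
        i0 = np.floor(s).astype(np.intp)
        frac = s - i0
        valid = (i0 >= 0) & (i0 < n_samples - 1)
        valid &= dynamic_aperture_mask(Z, X, ex, cfg.f_number)
        i0c = np.clip(i0, 0, n_samples - 2)
        trace = data[:, e]
        sample = (1.0 - frac) * trace[i0c] + frac * trace[i0c + 1]
        sample *= np.exp(1j * two_pi_f0 * tau)
        image += np.where(valid, sample, 0.0)
    return image


def beamform_all(acq: PWAcquisition, cfg: BeamformConfig) -> FrameSet:
    """Beamform every steering angle onto the shared grid, ordered as the angles."""
    iq = rf_to_iq(acq)
    frames = np.stack(
        [das_beamform_frame(iq, i, cfg) for i in range(len(iq.angles))]
    )
    return FrameSet(frames=frames, grid=cfg.grid, angles=iq.angles)


def coherent_compound(frame_set: FrameSet) -> np.ndarray:
    """Phase-preserving mean across the steered frames (complex sum / k)."""
    if len(frame_set) < 1:
        raise ValueError("cannot compound an empty frame set")
    return frame_set.frames.mean(axis=0)
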