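"""Decorrelation-based angle-pair selection for the coherence loss.

A clutter echo produced by multipath reverberation shifts axially by
``2z(sec θ − 1)`` between a steered and an unsteered transmit. Once this
displacement exceeds the spatial extent of the acoustic pulse — about two
wavelengths for a 50% fractional-bandwidth pulse — the clutter becomes
statistically independent between the two frames while tissue speckle,
which originates at a fixed anatomical location, stays coherent. The
calculus here turns that condition into concrete frame pairs:

* ``z_fov``      — effective maximum imaging depth ``W / (2 tan θ_max)``;
* ``theta_dec``  — smallest angular separation achieving ≥ nλ axial
                   displacement at ``z_fov``: ``arccos(z/(z + nλ/2))``;
* ``n_excl``     — minimum index separation between reference and target
                   frames, ``max(1, round(θ_dec/Δθ) · 2)``;
* ``select_target_frames`` — the admissible target set
                   ``{j : |j − i| ≥ N_excl, j ≠ i}``.

Assumptions: ideal plane wavefronts, homogeneous sound speed, straight-ray
propagation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .acquisition import AngleSequence, ProbeConfig

__all__ = [
    "FrameSelection",
    "axial_displacement",
    "z_fov",
    "theta_dec",
    "n_excl",
    "select_target_frames",
    "selection_for_acquisition",
]

_THETA_MAX_FLOOR_DEG = 0.1


def axial_displacement(z: float, theta_deg: float) -> float:
    """Axial path-length difference ``2z(sec θ − 1)`` in meters.

    Round trip to depth ``z`` is ``2z sec θ`` when steered by θ and ``2z``
    at normal incidence; the difference is the displacement a clutter echo
    undergoes between the two frames. Zero at θ = 0, strictly increasing
    in both arguments.
    """
    if not 0.0 <= theta_deg < 90.0:
        raise ValueError(f"theta must lie in [0°, 90°), got {theta_deg}")
    if z < 0:
        raise ValueError("depth must be non-negative")
    return 2.0 * z * (1.0 / math.cos(math.radians(theta_deg)) - 1.0)


def z_fov(probe: ProbeConfig, theta_max_deg: float, floor_deg: float = _THETA_MAX_FLOOR_DEG) -> float:
    """Effective maximum imaging depth ``W / (2 tan θ_max)`` in meters.

    Beyond this depth the steered plane waves no longer overlap across the
    full span, so it bounds the region where the decorrelation condition
    must hold. Diverges as θ_max → 0, hence the configurable floor.
    """
    if theta_max_deg >= 90.0:
        raise ValueError("theta_max must be below 90°")
    if theta_max_deg < floor_deg:
        raise ValueError(
            f"theta_max = {theta_max_deg}° is below the {floor_deg}° floor; z_FOV diverges"
        )
    return probe.aperture_width / (2.0 * math.tan(math.radians(theta_max_deg)))


def theta_dec(z_fov_m: float, wavelength: float, n_pulse_cycles: float = 2.0) -> float:
    """Maximum decorrelation angle in degrees.

    The angle at which the axial displacement at depth ``z_fov`` equals the
    pulse length ``nλ``: solving ``2z(sec θ − 1) = nλ`` gives
    ``θ = arccos(z / (z + nλ/2))``. With the default two-cycle pulse this
    is ``arccos(z_FOV / (z_FOV + λ))``. Decreasing in ``z_fov``,
    increasing in ``wavelength``.
    """
    if z_fov_m <= 0 or wavelength <= 0 or n_pulse_cycles <= 0:
        raise ValueError("z_fov, wavelength and n_pulse_cycles must be positive")
    return math.degrees(math.acos(z_fov_m / (z_fov_m + n_pulse_cycles * wavelength / 2.0)))


def n_excl(theta_dec_deg: float, delta_theta_deg: float) -> int:
    """Minimum excluded-frame count ``max(1, round(θ_dec/Δθ) · 2)``.

    ``θ_dec/Δθ`` converts the decorrelation angle into frame-index units;
    the factor 2 covers both sides of the reference frame, so the count is
    even whenever the rounded ratio is at least 1. Non-increasing in Δθ.
    """
    if theta_dec_deg <= 0 or delta_theta_deg <= 0:
        raise ValueError("theta_dec and delta_theta must be positive")
    return max(1, round(theta_dec_deg / delta_theta_deg) * 2)


def select_target_frames(
    reference_index: int,
    n_excl_frames: int,
    k: int,
    excluded: frozenset[int] | set[int] = frozenset(),
) -> set[int]:
    """Target-frame indices ``{j : |j − i| ≥ N_excl, j ≠ i, j ∉ excluded}``.

    Index distance is measured in angle-index space after removing the
    ``excluded`` frames (e.g. the held-out 0° frame) and re-indexing the
    remainder contiguously; the returned set contains original indices.
    """
    if not 0 <= reference_index < k:
        raise ValueError(f"reference index {reference_index} outside [0, {k})")
    if n_excl_frames < 1:
        raise ValueError("n_excl must be >= 1")
    if reference_index in excluded:
        raise ValueError(f"reference frame {reference_index} is in the excluded set")
    kept = [j for j in range(k) if j not in excluded]
    pos = {j: p for p, j in enumerate(kept)}
    i_pos = pos[reference_index]
    return {j for j in kept if j != reference_index and abs(pos[j] - i_pos) >= n_excl_frames}


@dataclass(frozen=True)
class FrameSelection:
    """Materialized selection for one acquisition.

    ``valid_targets`` maps each admissible training reference (original
    angle index, center frame excluded) to its target set;
    ``validation_targets`` is the target set for the center (0°) reference
    in the original, un-removed indexing.
    """

    z_fov: float
    theta_dec: float
    n_excl: int
    valid_targets: dict[int, set[int]]
    validation_targets: set[int]
    n_pulse_cycles: float = 2.0
    center_index: int = 0

    def __post_init__(self) -> None:
        if self.n_excl < 1:
            raise ValueError("n_excl must be >= 1")
        if not 0.0 < self.theta_dec < 90.0:
            raise ValueError("theta_dec must lie in (0°, 90°)")
        for i, targets in self.valid_targets.items():
            if i in targets:
                raise ValueError("a target set may not contain its reference")


def selection_for_acquisition(
    probe: ProbeConfig,
    angles: AngleSequence,
    n_pulse_cycles: float = 2.0,
) -> FrameSelection:
    """Compose the full calculus for one probe/angle configuration.

    z_FOV from the aperture and half-span, θ_dec from z_FOV and λ, N_excl
    from θ_dec and Δθ, then the target sets: training references are all
    non-center frames (distances computed with the center frame removed
    and the remainder re-indexed), validation uses the center frame as
    reference in the original indexing.
    """
    k = len(angles)
    zf = z_fov(probe, angles.span)
    td = theta_dec(zf, probe.wavelength, n_pulse_cycles)
    ne = n_excl(td, angles.step)
    center = angles.center_index
    excluded = frozenset({center})
    valid: dict[int, set[int]] = {
        i: select_target_frames(i, ne, k, excluded) for i in range(k) if i != center
    }
    validation = select_target_frames(center, ne, k)
    if all(len(t) == 0 for t in valid.values()):
        warnings.warn(
            f"N_excl = {ne} leaves no valid target frames for any reference "
            f"(k = {k}); widen the span or add angles",
            stacklevel=2,
        )
    return FrameSelection(
        z_fov=zf,
        theta_dec=td,
        n_excl=ne,
        valid_targets=valid,
        validation_targets=validation,
        n_pulse_cycles=n_pulse_cycles,
        center_index=center,
    )
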