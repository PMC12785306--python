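"""Domain types and preprocessing primitives for plane-wave acquisitions.

The objects here describe a linear-array plane-wave experiment end to end:
the transducer (:class:`ProbeConfig`), the transmit steering schedule
(:class:`AngleSequence`), the raw per-angle channel data
(:class:`PWAcquisition`), the beamformed per-angle complex I/Q images on a
shared pixel grid (:class:`FrameSet`), and the grid itself
(:class:`PixelGrid`).

Preprocessing follows the convention used throughout the package: one
global max-absolute-value normalization per frame set (so relative
inter-frame amplitudes — which the coherence loss depends on — are
preserved), shared-window random cropping for training patches, and exact
zero-padding (never resampling) for full-frame inference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ProbeConfig",
    "AngleSequence",
    "PWAcquisition",
    "PixelGrid",
    "FrameSet",
    "Placement",
    "maxabs_normalize",
    "random_crop",
    "zero_pad",
    "unpad",
]


@dataclass(frozen=True)
class ProbeConfig:
    """Linear-array transducer and acquisition physics.

    Parameters
    ----------
    n_elements : int
        Number of array elements.
    pitch : float
        Element center-to-center spacing in meters.
    f0 : float
        Transmit center frequency in Hz.
    c : float
        Assumed speed of sound in m/s (homogeneous-medium model).
    fs : float
        Channel-data sampling rate in Hz.
    fractional_bandwidth : float
        Pulse -6 dB bandwidth divided by ``f0`` (default 0.5; at 50%
        fractional bandwidth one speckle cell spans about two carrier
        cycles, the scale the frame-selection calculus is built on).
    """

    n_elements: int
    pitch: float
    f0: float
    c: float
    fs: float
    fractional_bandwidth: float = 0.5

    def __post_init__(self) -> None:
        for name in ("n_elements", "pitch", "f0", "c", "fs", "fractional_bandwidth"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"ProbeConfig.{name} must be strictly positive, got {value!r}")

    @property
    def wavelength(self) -> float:
        """Acoustic wavelength λ = c / f0 in meters."""
        return self.c / self.f0

    @property
    def aperture_width(self) -> float:
        """Full aperture width W = n_elements × pitch in meters."""
        return self.n_elements * self.pitch

    @property
    def element_positions(self) -> np.ndarray:
        """Lateral element coordinates in meters, centered on the array."""
        idx = np.arange(self.n_elements, dtype=float)
        return (idx - (self.n_elements - 1) / 2.0) * self.pitch


@dataclass(frozen=True)
class AngleSequence:
    """Ordered plane-wave steering schedule in degrees, ascending."""

    angles: np.ndarray

    def __post_init__(self) -> None:
        angles = np.asarray(self.angles, dtype=float)
        object.__setattr__(self, "angles", angles)
        if angles.ndim != 1 or angles.size < 2:
            raise ValueError("AngleSequence needs at least two angles")
        if not np.all(np.diff(angles) > 0):
            raise ValueError("angles must be strictly increasing")

    @classmethod
    def symmetric(cls, span_deg: float, k: int) -> "AngleSequence":
        """Build ``k`` equally spaced angles spanning ±``span_deg``."""
        if span_deg <= 0 or k < 2:
            raise ValueError("span must be positive and k >= 2")
        return cls(np.linspace(-span_deg, span_deg, k))

    def __len__(self) -> int:
        return int(self.angles.size)

    @property
    def span(self) -> float:
        """Half-span θ_max in degrees (max |angle|)."""
        return float(np.max(np.abs(self.angles)))

    @property
    def step(self) -> float:
        """Angular step Δθ = total span / (k − 1) in degrees."""
        return float((self.angles[-1] - self.angles[0]) / (len(self) - 1))

    @property
    def center_index(self) -> int:
        """Index of the angle closest to 0° (the held-out validation frame)."""
        return int(np.argmin(np.abs(self.angles)))


@dataclass
class PWAcquisition:
    """Per-angle raw channel data for one plane-wave acquisition.

    ``channel_data`` has shape ``(k, n_samples, n_elements)`` and holds real
    RF traces (``data_kind='rf'``) or complex baseband I/Q
    (``data_kind='iq'``). ``t0`` is the arrival time of the first recorded
    sample, common to all angles.
    """

    probe: ProbeConfig
    angles: AngleSequence
    channel_data: np.ndarray
    data_kind: str = "rf"
    t0: float = 0.0

    def __post_init__(self) -> None:
        data = np.asarray(self.channel_data)
        if data.ndim != 3:
            raise ValueError("channel_data must be (k, n_samples, n_elements)")
        if data.shape[0] != len(self.angles):
            raise ValueError(
                f"one channel-data plane per angle required: got {data.shape[0]} planes "
                f"for {len(self.angles)} angles"
            )
        if data.shape[2] != self.probe.n_elements:
            raise ValueError(
                f"channel_data has {data.shape[2]} element columns, probe has "
                f"{self.probe.n_elements} elements"
            )
        if self.data_kind not in ("rf", "iq"):
            raise ValueError("data_kind must be 'rf' or 'iq'")
        if self.data_kind == "rf" and np.iscomplexobj(data):
            raise ValueError("rf data must be real-valued")
        if self.data_kind == "iq" and not np.iscomplexobj(data):
            raise ValueError("iq data must be complex-valued")
        if not np.isfinite(self.t0):
            raise ValueError("t0 must be finite")
        self.channel_data = data

    @property
    def n_samples(self) -> int:
        return int(self.channel_data.shape[1])

    @property
    def sample_times(self) -> np.ndarray:
        """Time axis of the recorded traces in seconds."""
        return self.t0 + np.arange(self.n_samples) / self.probe.fs


@dataclass(frozen=True)
class PixelGrid:
    """Regular imaging grid: depth ``z0 + i·dz``, lateral ``x0 + j·dx``.

    Depth increases with row index; ``x`` is centered on the array when
    built by :meth:`lambda_third`. All positions in meters.
    """

    z0: float
    dz: float
    dx: float
    nz: int
    nx: int
    x0: float | None = None

    def __post_init__(self) -> None:
        if self.nz < 1 or self.nx < 1:
            raise ValueError("nz and nx must be >= 1")
        if self.dz <= 0 or self.dx <= 0:
            raise ValueError("dz and dx must be positive")
        if self.x0 is None:
            object.__setattr__(self, "x0", -self.dx * (self.nx - 1) / 2.0)

    @classmethod
    def lambda_third(cls, probe: ProbeConfig, z0: float, nz: int, nx: int) -> "PixelGrid":
        """Default λ/3-spaced grid laterally centered on the aperture."""
        d = probe.wavelength / 3.0
        return cls(z0=z0, dz=d, dx=d, nz=nz, nx=nx)

    @property
    def z(self) -> np.ndarray:
        return self.z0 + np.arange(self.nz) * self.dz

    @property
    def x(self) -> np.ndarray:
        return self.x0 + np.arange(self.nx) * self.dx

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nz, self.nx)


@dataclass
class FrameSet:
    """Stack of k complex beamformed I/Q images on a shared grid."""

    frames: np.ndarray
    grid: PixelGrid
    angles: AngleSequence
    normalization_scale: float = 1.0

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim != 3:
            raise ValueError("frames must be (k, nz, nx)")
        if frames.shape[0] != len(self.angles):
            raise ValueError("one frame per angle required")
        if frames.shape[1:] != self.grid.shape:
            raise ValueError(f"frame shape {frames.shape[1:]} != grid shape {self.grid.shape}")
        if not np.iscomplexobj(frames):
            frames = frames.astype(np.complex128)
        if not np.all(np.isfinite(frames.view(float))):
            raise ValueError("frames must be finite")
        self.frames = frames

    def __len__(self) -> int:
        return int(self.frames.shape[0])

    @property
    def center_index(self) -> int:
        return self.angles.center_index


def maxabs_normalize(frame_set: FrameSet) -> FrameSet:
    """Scale a frame set by its single global maximum modulus.

    One scalar per frame *set*, not per frame: relative amplitudes between
    the steered frames carry physical information the coherence loss uses,
    so only the overall level is standardized. The applied scale is
    recorded in ``normalization_scale``; the output maximum modulus is 1.
    """
    s = float(np.max(np.abs(frame_set.frames)))
    if s == 0.0:
        raise ValueError("cannot normalize an all-zero frame set (undefined scale)")
    return FrameSet(
        frames=frame_set.frames / s,
        grid=frame_set.grid,
        angles=frame_set.angles,
        normalization_scale=s,
    )


def random_crop(
    frame_set: FrameSet,
    size: tuple[int, int] = (256, 256),
    rng: np.random.Generator | int | None = None,
) -> FrameSet:
    """Crop one shared window of ``size`` pixels from every frame.

    The top-left offset is drawn uniformly over all valid positions; the
    *same* window is applied to all k frames so inter-frame coherence is
    evaluated at identical spatial locations. Deterministic for a given
    ``rng`` state.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    ph, pw = size
    nz, nx = frame_set.grid.shape
    if nz < ph or nx < pw:
        raise ValueError(f"image {nz}x{nx} smaller than crop {ph}x{pw}")
    top = int(rng.integers(0, nz - ph + 1))
    left = int(rng.integers(0, nx - pw + 1))
    grid = frame_set.grid
    new_grid = PixelGrid(
        z0=grid.z0 + top * grid.dz,
        dz=grid.dz,
        dx=grid.dx,
        nz=ph,
        nx=pw,
        x0=grid.x0 + left * grid.dx,
    )
    return FrameSet(
        frames=frame_set.frames[:, top : top + ph, left : left + pw].copy(),
        grid=new_grid,
        angles=frame_set.angles,
        normalization_scale=frame_set.normalization_scale,
    )


@dataclass(frozen=True)
class Placement:
    """Record of where an image sits inside a zero-padded canvas."""

    top: int
    left: int
    nz: int
    nx: int


def zero_pad(frame: np.ndarray, target: tuple[int, int] = (1024, 1024)) -> tuple[np.ndarray, Placement]:
    """Embed ``frame`` top-left in a zero canvas of ``target`` shape.

    Padding (never resampling) preserves the native pixel spacing and the
    phase content of I/Q data exactly; the returned :class:`Placement`
    allows bit-exact recovery via :func:`unpad`.
    """
    frame = np.asarray(frame)
    nz, nx = frame.shape
    tz, tx = target
    if nz > tz or nx > tx:
        raise ValueError(f"frame {nz}x{nx} exceeds pad target {tz}x{tx}; refusing to downsample")
    out = np.zeros((tz, tx), dtype=frame.dtype if np.iscomplexobj(frame) else np.complex128)
    out[:nz, :nx] = frame
    return out, Placement(top=0, left=0, nz=nz, nx=nx)


def unpad(padded: np.ndarray, placement: Placement) -> np.ndarray:
    """Exact inverse of :func:`zero_pad`."""
    p = placement
    return padded[p.top : p.top + p.nz, p.left : p.left + p.nx].copy()
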