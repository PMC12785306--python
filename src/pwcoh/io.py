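"""Self-describing HDF5 containers for acquisitions and frame sets.

Layout (schema ``pwcoh-acquisition``):

* root attributes: schema, schema_version, data_kind, t0, probe fields
  (``n_elements``, ``pitch``, ``f0``, ``c``, ``fs``,
  ``fractional_bandwidth``) and the steering ``angles_deg`` array;
* group ``/channel_data`` with one dataset per angle, ``angle_000`` …;
  complex I/Q stored as separate ``<name>_real`` / ``<name>_imag`` planes
  so the files stay language-neutral.

Frame sets use the analogous ``pwcoh-frameset`` schema with the pixel-grid
geometry in the root attributes. Loading a container that lacks a required
attribute raises :class:`ContainerFormatError` naming the missing field.

A converter for generic ``(samples, elements, angles)`` arrays plus a JSON
sidecar is provided as :func:`acquisition_from_arrays`.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .acquisition import AngleSequence, FrameSet, PixelGrid, ProbeConfig, PWAcquisition

__all__ = [
    "ContainerFormatError",
    "save_acquisition",
    "load_acquisition",
    "save_frameset",
    "load_frameset",
    "acquisition_from_arrays",
]

SCHEMA_VERSION = "1.1"
_PROBE_ATTRS = ("n_elements", "pitch", "f0", "c", "fs", "fractional_bandwidth")


class ContainerFormatError(ValueError):
    """Raised when a container is missing a required field or is malformed."""


def _require(attrs, name: str, path):
    if name not in attrs:
        raise ContainerFormatError(f"container {path} is missing required attribute '{name}'")
    return attrs[name]


def _write_complex(group: h5py.Group, name: str, data: np.ndarray) -> None:
    if np.iscomplexobj(data):
        group.create_dataset(f"{name}_real", data=np.ascontiguousarray(data.real))
        group.create_dataset(f"{name}_imag", data=np.ascontiguousarray(data.imag))
    else:
        group.create_dataset(name, data=np.ascontiguousarray(data))


def _read_maybe_complex(group: h5py.Group, name: str, path) -> np.ndarray:
    if name in group:
        return np.asarray(group[name])
    if f"{name}_real" in group and f"{name}_imag" in group:
        return np.asarray(group[f"{name}_real"]) + 1j * np.asarray(group[f"{name}_imag"])
    raise ContainerFormatError(f"container {path} is missing dataset '{name}'")


def save_acquisition(acq: PWAcquisition, path) -> Path:
    """Write an acquisition container; returns the path written."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["schema"] = "pwcoh-acquisition"
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["data_kind"] = acq.data_kind
        f.attrs["t0"] = float(acq.t0)
        f.attrs["angles_deg"] = acq.angles.angles
        f.attrs["units"] = "SI: meters, seconds, Hz; angles in degrees"
        for name in _PROBE_ATTRS:
            f.attrs[name] = getattr(acq.probe, name)
        g = f.create_group("channel_data")
        for i in range(len(acq.angles)):
            _write_complex(g, f"angle_{i:03d}", acq.channel_data[i])
    return path


def load_acquisition(path) -> PWAcquisition:
    """Read an acquisition container written by :func:`save_acquisition`."""
    path = Path(path)
    try:
        f = h5py.File(path, "r")
    except OSError as exc:  # pragma: no cover - h5py's message varies
        raise ContainerFormatError(f"cannot open {path} as HDF5: {exc}") from exc
    with f:
        probe = ProbeConfig(
            n_elements=int(_require(f.attrs, "n_elements", path)),
            pitch=float(_require(f.attrs, "pitch", path)),
            f0=float(_require(f.attrs, "f0", path)),
            c=float(_require(f.attrs, "c", path)),
            fs=float(_require(f.attrs, "fs", path)),
            fractional_bandwidth=float(_require(f.attrs, "fractional_bandwidth", path)),
        )
        angles = AngleSequence(np.asarray(_require(f.attrs, "angles_deg", path), dtype=float))
        data_kind = str(_require(f.attrs, "data_kind", path))
        t0 = float(_require(f.attrs, "t0", path))
        if "channel_data" not in f:
            raise ContainerFormatError(f"container {path} is missing group 'channel_data'")
        g = f["channel_data"]
        planes = [_read_maybe_complex(g, f"angle_{i:03d}", path) for i in range(len(angles))]
    return PWAcquisition(
        probe=probe,
        angles=angles,
        channel_data=np.stack(planes),
        data_kind=data_kind,
        t0=t0,
    )


def save_frameset(frame_set: FrameSet, path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["schema"] = "pwcoh-frameset"
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["angles_deg"] = frame_set.angles.angles
        f.attrs["normalization_scale"] = float(frame_set.normalization_scale)
        for name in ("z0", "dz", "dx", "x0"):
            f.attrs[name] = float(getattr(frame_set.grid, name))
        _write_complex(f, "frames", frame_set.frames)
    return path


def load_frameset(path) -> FrameSet:
    path = Path(path)
    with h5py.File(path, "r") as f:
        angles = AngleSequence(np.asarray(_require(f.attrs, "angles_deg", path), dtype=float))
        frames = _read_maybe_complex(f, "frames", path)
        grid = PixelGrid(
            z0=float(_require(f.attrs, "z0", path)),
            dz=float(_require(f.attrs, "dz", path)),
            dx=float(_require(f.attrs, "dx", path)),
            nz=int(frames.shape[1]),
            nx=int(frames.shape[2]),
            x0=float(_require(f.attrs, "x0", path)),
        )
        scale = float(_require(f.attrs, "normalization_scale", path))
    return FrameSet(frames=frames, grid=grid, angles=angles, normalization_scale=scale)


def acquisition_from_arrays(
    data: np.ndarray, meta: dict, data_kind: str = "rf", t0: float = 0.0
) -> PWAcquisition:
    """Convert a generic ``(samples, elements, angles)`` array + metadata dict.

    ``meta`` must supply the probe fields (``n_elements``, ``pitch``,
    ``f0``, ``c``, ``fs``, optionally ``fractional_bandwidth``) and
    ``angles_deg``. This is the documented bridge from external exports
    (e.g. research-platform dumps or public-challenge matrices) into the
    native container; vendor file parsing itself is out of scope.
    """
    data = np.asarray(data)
    if data.ndim != 3:
        raise ValueError("expected (samples, elements, angles)")
    probe = ProbeConfig(
        n_elements=int(meta["n_elements"]),
        pitch=float(meta["pitch"]),
        f0=float(meta["f0"]),
        c=float(meta["c"]),
        fs=float(meta["fs"]),
        fractional_bandwidth=float(meta.get("fractional_bandwidth", 0.5)),
    )
    angles = AngleSequence(np.asarray(meta["angles_deg"], dtype=float))
    return PWAcquisition(
        probe=probe,
        angles=angles,
        channel_data=np.moveaxis(data, 2, 0),
        data_kind=data_kind,
        t0=t0,
    )
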