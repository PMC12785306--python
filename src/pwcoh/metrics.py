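"""Envelope detection and contrast metrics (CNR, gCNR) with ROI handling.

Both metrics are computed on the linear envelope (pixelwise modulus of the
complex I/Q image), not on log-compressed display data; a log-domain
variant is available behind the ``domain`` flag. CNR compares background
(μ_i, σ_i) against the anechoic target (μ_o, σ_o):

    CNR[dB] = 20·log10( |μ_i − μ_o| / sqrt((σ_i² + σ_o²)/2) )

while gCNR measures the overlap of the two intensity distributions with
shared-support histograms (256 bins by default):

    gCNR = 1 − Σ_bins min(h_i, h_o)   ∈ [0, 1],

0 for identical distributions, 1 for disjoint supports — independent of
the distributions' form and exactly invariant to global rescaling (the
bin edges are recomputed from the pooled data).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .acquisition import PixelGrid

__all__ = [
    "ROIPair",
    "envelope",
    "log_compress",
    "cnr",
    "gcnr",
    "disk_mask",
    "annulus_mask",
    "rect_mask",
    "roi_from_geometry",
]


@dataclass(frozen=True)
class ROIPair:
    """Disjoint background and target (anechoic) pixel masks on one grid."""

    background_mask: np.ndarray
    target_mask: np.ndarray

    def __post_init__(self) -> None:
        bg = np.asarray(self.background_mask, dtype=bool)
        tg = np.asarray(self.target_mask, dtype=bool)
        if bg.shape != tg.shape:
            raise ValueError("masks must share a shape")
        if not bg.any() or not tg.any():
            raise ValueError("both ROIs must be nonempty")
        if np.any(bg & tg):
            raise ValueError("background and target ROIs overlap")
        object.__setattr__(self, "background_mask", bg)
        object.__setattr__(self, "target_mask", tg)


def envelope(frame: np.ndarray) -> np.ndarray:
    """Pixelwise modulus of a complex I/Q image (linear envelope, ≥ 0)."""
    return np.abs(np.asarray(frame))


def log_compress(env: np.ndarray, floor_db: float = -60.0) -> np.ndarray:
    """20·log10(env / max) display image, clipped at ``floor_db`` — rendering only."""
    env = np.asarray(env, dtype=float)
    peak = env.max()
    if peak <= 0:
        raise ValueError("cannot log-compress an all-zero envelope")
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(env / peak)
    return np.maximum(db, floor_db)


def _roi_values(image: np.ndarray, rois: ROIPair, domain: str) -> tuple[np.ndarray, np.ndarray]:
    image = np.asarray(image, dtype=float)
    if image.shape != rois.background_mask.shape:
        raise ValueError("image and ROI masks must share a shape")
    if domain == "log":
        image = log_compress(image)
    elif domain != "linear":
        raise ValueError("domain must be 'linear' or 'log'")
    return image[rois.background_mask], image[rois.target_mask]


def cnr(image: np.ndarray, rois: ROIPair, domain: str = "linear") -> float:
    """Contrast-to-noise ratio in dB between background and target ROIs."""
    bg, tg = _roi_values(image, rois, domain)
    mu_i, mu_o = bg.mean(), tg.mean()
    sd = np.sqrt((bg.var(ddof=0) + tg.var(ddof=0)) / 2.0)
    diff = abs(mu_i - mu_o)
    if diff == 0.0:
        warnings.warn("zero mean difference between ROIs; CNR is -inf", stacklevel=2)
        return -np.inf
    if sd == 0.0:
        return np.inf
    return float(20.0 * np.log10(diff / sd))


def gcnr(image: np.ndarray, rois: ROIPair, n_bins: int = 256, domain: str = "linear") -> float:
    """Generalized CNR: one minus the histogram overlap of the two ROIs."""
    bg, tg = _roi_values(image, rois, domain)
    lo = min(bg.min(), tg.min())
    hi = max(bg.max(), tg.max())
    if lo == hi:  # all samples identical: complete overlap
        return 0.0
    edges = np.linspace(lo, hi, n_bins + 1)
    h_i, _ = np.histogram(bg, bins=edges)
    h_o, _ = np.histogram(tg, bins=edges)
    overlap = np.minimum(h_i / bg.size, h_o / tg.size).sum()
    return float(1.0 - overlap)


def disk_mask(grid: PixelGrid, center: tuple[float, float], radius: float) -> np.ndarray:
    """Rasterized disk; ``center`` is (x, z) in meters."""
    cx, cz = center
    X, Z = np.meshgrid(grid.x, grid.z)
    return (X - cx) ** 2 + (Z - cz) ** 2 <= radius**2


def annulus_mask(
    grid: PixelGrid, center: tuple[float, float], r_inner: float, r_outer: float
) -> np.ndarray:
    if r_outer <= r_inner:
        raise ValueError("r_outer must exceed r_inner")
    cx, cz = center
    X, Z = np.meshgrid(grid.x, grid.z)
    r2 = (X - cx) ** 2 + (Z - cz) ** 2
    return (r2 >= r_inner**2) & (r2 <= r_outer**2)


def rect_mask(
    grid: PixelGrid, x_range: tuple[float, float], z_range: tuple[float, float]
) -> np.ndarray:
    X, Z = np.meshgrid(grid.x, grid.z)
    return (X >= x_range[0]) & (X <= x_range[1]) & (Z >= z_range[0]) & (Z <= z_range[1])


_SHAPES = {"disk", "annulus", "rect"}


def _mask_from_spec(spec: dict, grid: PixelGrid) -> np.ndarray:
    kind = spec.get("shape")
    if kind not in _SHAPES:
        raise ValueError(f"ROI shape must be one of {sorted(_SHAPES)}, got {kind!r}")
    if kind == "disk":
        mask = disk_mask(grid, tuple(spec["center"]), float(spec["radius"]))
    elif kind == "annulus":
        mask = annulus_mask(
            grid, tuple(spec["center"]), float(spec["r_inner"]), float(spec["r_outer"])
        )
    else:
        mask = rect_mask(grid, tuple(spec["x_range"]), tuple(spec["z_range"]))
    if not mask.any():
        raise ValueError(f"ROI {spec} lies outside the image bounds")
    return mask


def roi_from_geometry(target_spec: dict, background_spec: dict, grid: PixelGrid) -> ROIPair:
    """Rasterize target/background geometry specs into an :class:`ROIPair`.

    Specs are dicts with a ``shape`` key (``disk``, ``annulus`` or
    ``rect``) and the corresponding geometry in meters — the schema used
    by the ROI YAML sidecars. Overlapping masks raise.
    """
    return ROIPair(
        background_mask=_mask_from_spec(background_spec, grid),
        target_mask=_mask_from_spec(target_spec, grid),
    )
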