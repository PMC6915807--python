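"""Group proportional body maps and Gaussian spatial smoothing.

A proportional map holds, per pixel, the fraction of subjects whose concern
mask covers that pixel.  Smoothing uses an isotropic Gaussian kernel
parameterized by its full width at half maximum (FWHM); the standard
relation sigma = FWHM / (2 * sqrt(2 * ln 2)) applies.  Reflective boundary
handling avoids artificial darkening at the silhouette edges, and the
kernel is truncated at 4 sigma (mass error < 1e-4).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["ProportionalMap", "fwhm_to_sigma", "proportional_map", "smooth_map",
           "smooth_grid", "map_to_png", "map_to_csv"]

_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...


@dataclass
class ProportionalMap:
    """Per-pixel proportion of subjects reporting a concern; n subjects aggregated."""

    grid: np.ndarray  # (H, W) float in [0, 1]
    n: int

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.grid.min() < -1e-12 or self.grid.max() > 1 + 1e-12:
            raise ValueError("proportion values must lie in [0, 1]")


def fwhm_to_sigma(fwhm: float) -> float:
    """Gaussian sigma for a given full width at half maximum."""
    if fwhm <= 0:
        raise ValueError(f"fwhm must be > 0, got {fwhm}")
    return float(fwhm) / _FWHM_FACTOR


def proportional_map(masks) -> ProportionalMap:
    """Arithmetic mean of binary subject masks: grid[p] = count(p) / n."""
    masks = list(masks)
    if not masks:
        raise ValueError("need >= 1 mask")
    shape = masks[0].shape
    for m in masks[1:]:
        if m.shape != shape:
            raise ValueError(f"mask dims mismatch: {m.shape} vs {shape}")
    stack = np.stack([np.asarray(m, dtype=np.float64) for m in masks])
    return ProportionalMap(grid=stack.mean(axis=0), n=len(masks))


def smooth_grid(grid: np.ndarray, fwhm_px: float) -> np.ndarray:
    """Gaussian-smooth a raster (reflective boundary, 4-sigma truncation)."""
    sigma = fwhm_to_sigma(fwhm_px)
    return ndimage.gaussian_filter(
        np.asarray(grid, dtype=float), sigma=sigma, mode="reflect", truncate=4.0
    )


def smooth_map(pmap: ProportionalMap, fwhm_px: float) -> ProportionalMap:
    """Smooth a proportional map; output clipped to [0, 1] against round-off."""
    out = np.clip(smooth_grid(pmap.grid, fwhm_px), 0.0, 1.0)
    return ProportionalMap(grid=out, n=pmap.n)


def map_to_png(grid: np.ndarray, path) -> None:
    """Write a [0, 1] raster as 8-bit grayscale PNG (value = round(255 * v))."""
    from PIL import Image

    arr = np.clip(np.asarray(grid, dtype=float), 0.0, 1.0)
    img = Image.fromarray(np.round(arr * 255).astype(np.uint8), mode="L")
    img.save(path)


def map_to_csv(grid: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(grid, dtype=float), delimiter=",", fmt="%.10g")
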