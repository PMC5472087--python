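"""Planar dose scoring and isodose-diameter analysis.

Emulates a radiochromic film placed normal to the z axis at a distance
``plane_offset`` from a point Y-90 source, with the magnetic field lying in
the film plane along x.  Film response is taken as proportional to the
energy deposited in a thin slab, so "dose" maps are in MeV per pixel; the
analysis compares geometric isodose diameters, which are independent of
absolute normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .transport import HitCloud, TransportConfig, run_simulation

__all__ = [
    "DoseMap2D",
    "IsodoseDiameters",
    "DEFAULT_ISODOSE_LEVELS",
    "bin_hits_to_plane",
    "score_dose_plane",
    "extract_isodose_diameters",
    "percent_change",
]

#: Six isodose levels (fractions of the maximum), innermost to outermost.
DEFAULT_ISODOSE_LEVELS = (0.9, 0.75, 0.6, 0.45, 0.3, 0.15)


@dataclass
class DoseMap2D:
    """Planar dose grid: deposited energy (MeV) per pixel.

    ``grid[iy, ix]`` covers pixel centres at ``(ix - (nx-1)/2) * pixel_size``
    in x and likewise in y; both dimensions are odd so the source projection
    is a pixel centre.  ``B_in_plane_axis`` records the in-plane field axis.
    """

    grid: np.ndarray
    pixel_size: float = 0.1
    plane_offset: float = 0.0
    B_in_plane_axis: str = "x"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise ValueError("grid must be 2D")
        if any(n % 2 == 0 for n in self.grid.shape):
            raise ValueError("grid dimensions must be odd")
        if np.any(self.grid < 0):
            raise ValueError("grid values must be non-negative")

    def x_coords(self) -> np.ndarray:
        nx = self.grid.shape[1]
        return (np.arange(nx) - (nx - 1) / 2) * self.pixel_size

    def y_coords(self) -> np.ndarray:
        ny = self.grid.shape[0]
        return (np.arange(ny) - (ny - 1) / 2) * self.pixel_size

    def to_text(self, path) -> None:
        header = (f"pixel_size={self.pixel_size} plane_offset={self.plane_offset} "
                  f"B_in_plane_axis={self.B_in_plane_axis}")
        np.savetxt(path, self.grid, header=header)

    @classmethod
    def from_text(cls, path) -> "DoseMap2D":
        with open(path) as fh:
            meta = dict(tok.split("=") for tok in fh.readline().lstrip("# ").split())
        return cls(np.loadtxt(path), float(meta["pixel_size"]),
                   float(meta["plane_offset"]), meta["B_in_plane_axis"])

    def to_png(self, path) -> None:
        """16-bit grayscale PNG scaled to the dose maximum."""
        from PIL import Image
        top = self.grid.max()
        img = (self.grid / top * 65535).astype(np.uint16) if top > 0 \
            else np.zeros_like(self.grid, dtype=np.uint16)
        Image.fromarray(img, mode="I;16").save(path)


@dataclass
class IsodoseDiameters:
    """Per-level contour diameters (mm) along x (parallel to B) and y."""

    levels: np.ndarray
    diameter_x: np.ndarray
    diameter_y: np.ndarray

    def to_frame(self, **extra) -> pd.DataFrame:
        rows = []
        for lv, dx, dy in zip(self.levels, self.diameter_x, self.diameter_y):
            rows.append({"level": lv, "axis": "x", "diameter_mm": dx, **extra})
            rows.append({"level": lv, "axis": "y", "diameter_mm": dy, **extra})
        return pd.DataFrame(rows)


def bin_hits_to_plane(cloud: HitCloud, plane_offset: float,
                      slab_thickness: float = 0.3, pixel_size: float = 0.1,
                      half_extent: float | None = None) -> DoseMap2D:
    """Accumulate hit energies whose z lies in [offset, offset + thickness) into pixels.

    The grid spans ``±half_extent`` (default: the sphere radius, or the hit
    extent for synthetic clouds) with odd pixel counts.
    """
    if slab_thickness <= 0:
        raise ValueError("slab_thickness must be positive")
    if half_extent is None:
        half_extent = (cloud.config.sphere_radius if cloud.config is not None
                       else float(np.abs(np.concatenate([cloud.x, cloud.y])).max()) + pixel_size)
    n_half = int(np.ceil(half_extent / pixel_size))
    n = 2 * n_half + 1
    z = cloud.z.astype(float)
    sel = (z >= plane_offset) & (z < plane_offset + slab_thickness)
    ix = np.rint(cloud.x[sel].astype(float) / pixel_size).astype(np.int64) + n_half
    iy = np.rint(cloud.y[sel].astype(float) / pixel_size).astype(np.int64) + n_half
    ok = (ix >= 0) & (ix < n) & (iy >= 0) & (iy < n)
    grid = np.zeros((n, n))
    np.add.at(grid, (iy[ok], ix[ok]), cloud.dE[sel][ok].astype(float))
    return DoseMap2D(grid, pixel_size, plane_offset)


def score_dose_plane(config: TransportConfig, plane_offset: float,
                     slab_thickness: float = 0.3,
                     pixel_size: float = 0.1) -> DoseMap2D:
    """Run the transport engine and score dose on a plane normal to z.

    The source sits at the sphere centre; the field axis of ``config`` should
    lie in the plane (default +x).  Raises if the slab lies outside the sphere.
    """
    if plane_offset + slab_thickness > config.sphere_radius or plane_offset < -config.sphere_radius:
        raise ValueError("scoring plane lies outside the sphere")
    cloud = run_simulation(config)
    return bin_hits_to_plane(cloud, plane_offset, slab_thickness, pixel_size)


def _line_extent(mask_line: np.ndarray, pixel_size: float) -> float:
    idx = np.flatnonzero(mask_line)
    if idx.size == 0:
        return 0.0
    return (idx[-1] - idx[0] + 1) * pixel_size


def extract_isodose_diameters(dose_map: DoseMap2D, levels=DEFAULT_ISODOSE_LEVELS,
                              smoothing_sigma_px: float = 2.0) -> IsodoseDiameters:
    """Threshold the (smoothed) map at each level and measure contour diameters.

    The diameter along an axis is the extent of the thresholded region along
    the grid line through the dose maximum parallel to that axis.  Smoothing
    (Gaussian, in pixels; 0 disables) stabilizes the maximum and the contours
    against Monte Carlo noise.  An empty level yields diameter 0 with a warning.
    """
    levels = np.asarray(levels, dtype=float)
    if np.any((levels <= 0) | (levels > 1)):
        raise ValueError("levels must lie in (0, 1]")
    if np.any(np.diff(levels) >= 0):
        raise ValueError("levels must be strictly decreasing")
    g = ndimage.gaussian_filter(dose_map.grid, smoothing_sigma_px) \
        if smoothing_sigma_px > 0 else dose_map.grid
    top = g.max()
    if top <= 0:
        raise ValueError("dose map has no positive maximum")
    iy0, ix0 = np.unravel_index(int(np.argmax(g)), g.shape)
    dx = np.empty(levels.size)
    dy = np.empty(levels.size)
    for i, lv in enumerate(levels):
        mask = g >= lv * top
        dx[i] = _line_extent(mask[iy0, :], dose_map.pixel_size)
        dy[i] = _line_extent(mask[:, ix0], dose_map.pixel_size)
        if dx[i] == 0 or dy[i] == 0:
            warnings.warn(f"isodose level {lv} has an empty contour", stacklevel=2)
    return IsodoseDiameters(levels, dx, dy)


def percent_change(d_field: IsodoseDiameters, d_zero: IsodoseDiameters) -> pd.DataFrame:
    """Per-level, per-axis percent change 100 (d_B - d_0)/d_0.

    Positive values mean the contour is wider under the field.  Levels must
    match; a zero baseline diameter yields NaN and is flagged with a warning.
    """
    if not np.allclose(d_field.levels, d_zero.levels):
        raise ValueError("isodose levels differ between the two inputs")
    rows = []
    for axis in ("x", "y"):
        f = getattr(d_field, f"diameter_{axis}")
        z = getattr(d_zero, f"diameter_{axis}")
        with np.errstate(divide="ignore", invalid="ignore"):
            pc = 100.0 * (f - z) / z
        if np.any(z == 0):
            warnings.warn("zero baseline diameter: percent change undefined",
                          stacklevel=2)
            pc = np.where(z == 0, np.nan, pc)
        for lv, v in zip(d_field.levels, pc):
            rows.append({"level": lv, "axis": axis, "percent_change": v})
    return pd.DataFrame(rows)
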