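"""Slice/stripe hit counting and ellipsoid interaction-volume analysis.

The scoring geometry mirrors the simulation analysis: thin slices normal to
the y axis (0.1 mm thick, 1 mm apart), each slice histogrammed into 0.5 mm
stripes along x (parallel to B) and along z (perpendicular to B).  The
interaction volume is the ellipsoid spanned by the per-axis extents of the
hit cloud, V = (4/3) pi a b c, and confinement is quantified by the ratio
V(B)/V(0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .transport import HitCloud

__all__ = [
    "SliceSpec",
    "StripeCounts",
    "InteractionVolume",
    "slice_and_count",
    "axis_extent",
    "interaction_volume",
    "volume_ratio",
    "volume_reduction_percent",
    "center_hit_ratio",
]


@dataclass(frozen=True)
class SliceSpec:
    """Slice/stripe scoring geometry.

    Slices are normal to ``slice_axis``; their centres sit on integer
    multiples of ``slice_spacing``.  Within a slice, hits are histogrammed
    into half-open stripe bins [c - w/2, c + w/2) whose centres are integer
    multiples of ``stripe_width``.
    """

    slice_axis: str = "y"
    slice_thickness: float = 0.1
    slice_spacing: float = 1.0
    stripe_width: float = 0.5

    def __post_init__(self) -> None:
        if self.slice_axis not in ("x", "y", "z"):
            raise ValueError("slice_axis must be one of 'x', 'y', 'z'")
        if min(self.slice_thickness, self.slice_spacing, self.stripe_width) <= 0:
            raise ValueError("slice/stripe dimensions must be positive")
        if self.slice_thickness > self.slice_spacing:
            raise ValueError("slice_thickness must not exceed slice_spacing")

    def stripe_axes(self) -> tuple[str, str]:
        """The two in-slice histogram axes, parallel-to-B first."""
        return tuple(a for a in ("x", "z") if a != self.slice_axis) \
            if self.slice_axis in ("x", "z") else ("x", "z")


@dataclass
class StripeCounts:
    """Hit histogram of one slice along one in-slice axis."""

    slice_center: float
    axis: str
    stripe_centers: np.ndarray
    counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"slice_center": self.slice_center, "axis": self.axis,
                             "stripe_center": self.stripe_centers,
                             "count": self.counts})


@dataclass(frozen=True)
class InteractionVolume:
    """Ellipsoid semi-axes (mm) spanned by a hit cloud and its volume (mm^3)."""

    extent_x: float
    extent_y: float
    extent_z: float
    volume: float
    percentile_used: float

    @classmethod
    def from_semi_axes(cls, a: float, b: float, c: float, percentile: float):
        if min(a, b, c) <= 0:
            raise ValueError("semi-axes must be positive")
        return cls(a, b, c, 4.0 / 3.0 * np.pi * a * b * c, percentile)


def slice_and_count(hits: HitCloud, spec: SliceSpec = SliceSpec()) -> list[StripeCounts]:
    """Histogram hits into per-slice, per-stripe counts.

    For each slice centre k * spacing (both signs of k, within the occupied
    region), hits with |coord - centre| <= thickness/2 are counted in
    half-open stripe bins along both in-slice axes.  Returns two
    :class:`StripeCounts` per populated slice position.
    """
    if len(hits) == 0:
        raise ValueError("cannot slice an empty hit cloud")
    s = hits.coord(spec.slice_axis).astype(float)
    k_max = int(np.floor((np.abs(s).max() + spec.slice_thickness / 2)
                         / spec.slice_spacing))
    out: list[StripeCounts] = []
    w = spec.stripe_width
    for k in range(-k_max, k_max + 1):
        center = k * spec.slice_spacing
        sel = np.abs(s - center) <= spec.slice_thickness / 2
        for axis in spec.stripe_axes():
            coord = hits.coord(axis)[sel].astype(float)
            if coord.size:
                idx = np.floor(coord / w + 0.5).astype(np.int64)
                lo, hi = int(idx.min()), int(idx.max())
                counts = np.bincount(idx - lo, minlength=hi - lo + 1)
                centers = np.arange(lo, hi + 1) * w
            else:
                counts = np.zeros(1, dtype=np.int64)
                centers = np.zeros(1)
            out.append(StripeCounts(center, axis, centers, counts))
    return out


def axis_extent(hits: HitCloud, axis: str, percentile: float = 99.5) -> float:
    """Extent of the hit cloud along one axis: a percentile of |coordinate|.

    ``percentile = 100`` gives the absolute maximum; the default 99.5 is a
    seed-stable surrogate for the "range of particles on the axis".
    """
    if not 0 < percentile <= 100:
        raise ValueError("percentile must lie in (0, 100]")
    return float(np.percentile(np.abs(hits.coord(axis).astype(float)), percentile))


def interaction_volume(hits: HitCloud, percentile: float = 99.5) -> InteractionVolume:
    """Ellipsoid interaction volume spanned by per-axis extents of the cloud."""
    a = axis_extent(hits, "x", percentile)
    b = axis_extent(hits, "y", percentile)
    c = axis_extent(hits, "z", percentile)
    return InteractionVolume.from_semi_axes(a, b, c, percentile)


def _check_same_source(cloud_a: HitCloud, cloud_b: HitCloud) -> None:
    ca, cb = cloud_a.config, cloud_b.config
    if ca is not None and cb is not None and ca.source_energy != cb.source_energy:
        raise ValueError(f"source energies differ: {ca.source_energy!r} vs "
                         f"{cb.source_energy!r}")


def volume_ratio(cloud_B: HitCloud, cloud_0: HitCloud,
                 percentile: float = 99.5) -> float:
    """V(B)/V(0) for two clouds of the same source energy."""
    _check_same_source(cloud_B, cloud_0)
    return (interaction_volume(cloud_B, percentile).volume
            / interaction_volume(cloud_0, percentile).volume)


def volume_reduction_percent(cloud_B: HitCloud, cloud_0: HitCloud,
                             percentile: float = 99.5) -> float:
    """Percent reduction of the interaction volume, 100 * (1 - V(B)/V(0))."""
    return 100.0 * (1.0 - volume_ratio(cloud_B, cloud_0, percentile))


def center_hit_ratio(cloud_B: HitCloud, cloud_0: HitCloud,
                     central_region_radius: float | None = None,
                     spec: SliceSpec = SliceSpec()) -> float:
    """Ratio of central hit counts between a field run and the 0 T reference.

    The default central region is the central stripe of the innermost slice:
    |slice coord| <= thickness/2 and |stripe coord| <= width/2 (any third
    coordinate).  Passing ``central_region_radius`` uses a sphere of that
    radius about the source instead.
    """
    if cloud_B.n_particles != cloud_0.n_particles:
        raise ValueError("runs must use equal n_particles")

    def count(c: HitCloud) -> int:
        if central_region_radius is not None:
            r2 = (c.x.astype(float) ** 2 + c.y.astype(float) ** 2
                  + c.z.astype(float) ** 2)
            return int(np.count_nonzero(r2 <= central_region_radius ** 2))
        s = np.abs(c.coord(spec.slice_axis)) <= spec.slice_thickness / 2
        stripe_axis = spec.stripe_axes()[0]
        t = np.abs(c.coord(stripe_axis)) <= spec.stripe_width / 2
        return int(np.count_nonzero(s & t))

    n0 = count(cloud_0)
    if n0 == 0:
        raise ZeroDivisionError("0 T reference has no hits in the central region")
    return count(cloud_B) / n0
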