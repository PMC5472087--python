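"""Ground-truth generators for testing each analysis stage in isolation.

These fixtures mimic the statistical structure the analyses assume — a
compact hit cloud with per-axis anisotropy, a unimodal planar dose map, an
exact helix — without any transport physics, so a failure localizes to the
analysis code.  All generators are bit-reproducible for a fixed seed and
emit the same containers the pipeline produces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import physics
from .film import DoseMap2D
from .transport import HitCloud

__all__ = [
    "EllipsoidCloudSpec",
    "GaussianMapSpec",
    "generate_ellipsoid_hit_cloud",
    "generate_gaussian_dose_map",
    "generate_helix_fixture",
]


@dataclass(frozen=True)
class EllipsoidCloudSpec:
    """Point cloud with known per-axis extents.

    ``distribution`` is ``"uniform"`` (uniform inside the ellipsoid with the
    given semi-axes) or ``"gaussian"`` (independent normals with the
    semi-axes as standard deviations).
    """

    semi_axes: tuple[float, float, float]
    n_points: int
    distribution: str = "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.semi_axes) <= 0:
            raise ValueError("semi-axes must be positive")
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")
        if self.distribution not in ("uniform", "gaussian"):
            raise ValueError("distribution must be 'uniform' or 'gaussian'")


@dataclass(frozen=True)
class GaussianMapSpec:
    """Anisotropic Gaussian dose map with analytically known isodose diameters.

    At level f of the maximum the noise-free diameter along x is
    2 * sigma_x * sqrt(2 ln(1/f)).  ``noise_fraction`` adds multiplicative
    lognormal-free Gaussian noise of that relative width per pixel.
    """

    sigma_x: float
    sigma_y: float
    amplitude: float = 1.0
    pixel_size: float = 0.1
    extent: float = 10.0
    seed: int = 0
    noise_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_x <= 0 or self.sigma_y <= 0:
            raise ValueError("sigmas must be positive")
        if self.noise_fraction < 0:
            raise ValueError("noise_fraction must be non-negative")


def generate_ellipsoid_hit_cloud(spec: EllipsoidCloudSpec) -> HitCloud:
    """Cloud of unit-energy hits with known per-axis scales.

    Uniform mode draws by rejection from the bounding box, so every point
    satisfies sum((x_i/a_i)^2) <= 1 by construction.
    """
    rng = np.random.default_rng(spec.seed)
    a = np.asarray(spec.semi_axes, dtype=float)
    n = spec.n_points
    if spec.distribution == "gaussian":
        pts = rng.standard_normal((n, 3)) * a
    else:
        pts = np.empty((n, 3))
        filled = 0
        while filled < n:
            m = max(int((n - filled) * 2.0) + 16, 64)
            cand = rng.uniform(-1.0, 1.0, (m, 3))
            keep = cand[(cand ** 2).sum(axis=1) <= 1.0]
            take = min(keep.shape[0], n - filled)
            pts[filled:filled + take] = keep[:take] * a
            filled += take
    return HitCloud(pts[:, 0], pts[:, 1], pts[:, 2],
                    np.ones(n, dtype=np.float32), np.arange(n, dtype=np.int32),
                    initial_energy=np.ones(n), escaped_energy=np.zeros(n),
                    final_position=pts, config=None)


def generate_gaussian_dose_map(spec: GaussianMapSpec) -> DoseMap2D:
    """Separable Gaussian map, optionally with multiplicative pixel noise."""
    n_half = int(np.ceil(spec.extent / spec.pixel_size))
    c = np.arange(-n_half, n_half + 1) * spec.pixel_size
    gx = np.exp(-c ** 2 / (2.0 * spec.sigma_x ** 2))
    gy = np.exp(-c ** 2 / (2.0 * spec.sigma_y ** 2))
    grid = spec.amplitude * np.outer(gy, gx)
    if spec.noise_fraction > 0:
        rng = np.random.default_rng(spec.seed)
        grid = grid * np.clip(1.0 + spec.noise_fraction
                              * rng.standard_normal(grid.shape), 0.0, None)
    return DoseMap2D(grid, spec.pixel_size, plane_offset=0.0)


def generate_helix_fixture(T: float, B: float, n_steps: int,
                           direction=(0.0, 0.0, 1.0), b_axis=(1.0, 0.0, 0.0),
                           turns: float = 1.0) -> np.ndarray:
    """Analytic positions of a loss-free, scatter-free electron helix.

    Returns ``(n_steps + 1, 3)`` positions sampled uniformly in gyration
    phase over ``turns`` revolutions, starting at the origin — the
    independent oracle for the transport stepper.
    """
    if B <= 0:
        raise ValueError("B must be positive (straight line otherwise)")
    u = np.asarray(direction, dtype=float)
    u = u / np.linalg.norm(u)
    b = np.asarray(b_axis, dtype=float)
    b = b / np.linalg.norm(b)
    upar = float(u @ b)
    uperp = u - upar * b
    pmag = float(np.linalg.norm(uperp))
    phis = np.linspace(0.0, turns * 2.0 * math.pi, n_steps + 1)
    if pmag < 1e-12:
        # parallel launch: collinear points along b
        p_mom = physics.momentum_from_kinetic(T)
        arc = phis * p_mom / (0.29979 * B)
        return np.outer(arc, b)
    r_g = physics.gyroradius(T, B, pitch_fraction=pmag)
    e1 = uperp / pmag
    e2 = np.cross(b, e1)  # centre direction for the electron
    # arc length per unit phase: s = phi * p / (0.29979 B)
    p_mom = physics.momentum_from_kinetic(T)
    arc = phis * p_mom / (0.29979 * B)
    par = np.outer(arc * upar, b)
    perp = (r_g * np.sin(phis)[:, None] * e1[None, :]
            + r_g * (1.0 - np.cos(phis))[:, None] * e2[None, :])
    return par + perp
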