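"""Condensed-history electron transport in a water sphere under a uniform B field.

Histories start at the centre of a water sphere (default radius 15 mm) and
are stepped with a class-II-style condensed scheme:

1. choose a step: at most ``max_step_length`` and at most the length over
   which the current continuous stopping power removes
   ``max_fractional_energy_loss_per_step`` of the kinetic energy;
2. advance along the exact analytic helix for the uniform field (straight
   line at B = 0);
3. deposit ``S(T) * step`` at the step endpoint as one hit;
4. apply Gaussian multiple scattering (Highland width, uniform azimuth);
5. stop at the cutoff energy (residual deposited locally) or on leaving
   the sphere (residual logged as escaped energy).

Delta rays and bremsstrahlung photons are not transported: their energy is
deposited on the step ("hits" are condensed-step endpoints, a surrogate for
discrete-interaction scoring).  Each history draws every random number from
its own counter-derived substream keyed by ``(seed, particle_id)``, so a run
is bit-reproducible and independent of execution order or chunking.
"""

from __future__ import annotations

import dataclasses
import io
import json
import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from . import physics
from .physics import ELECTRON_MASS_MEV, WATER, Material, ParticleState

__all__ = [
    "TransportConfig",
    "HitRecord",
    "HitCloud",
    "helix_advance",
    "transport_particle",
    "run_simulation",
]

_TWO_PI = 2.0 * math.pi


# ---------------------------------------------------------------------------
# Configuration and containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransportConfig:
    """Source, geometry, field and stepping controls for one run.

    ``source_energy`` is either a kinetic energy in MeV (monoenergetic
    isotropic point source) or the string tag ``"Y90"`` for the yttrium-90
    beta spectrum.  The field is uniform, ``B_magnitude`` tesla along
    ``B_axis`` (default +x).
    """

    source_energy: float | str
    n_particles: int
    B_magnitude: float = 0.0
    B_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    sphere_radius: float = 15.0
    cutoff_energy: float = 0.010
    max_fractional_energy_loss_per_step: float = 0.02
    max_step_length: float = 0.1
    seed: int = 0
    scattering: bool = True

    def __post_init__(self) -> None:
        if self.sphere_radius <= 0:
            raise ValueError("sphere_radius must be positive")
        if not 0 < self.max_fractional_energy_loss_per_step < 1:
            raise ValueError("max_fractional_energy_loss_per_step must be in (0, 1)")
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if self.max_step_length <= 0:
            raise ValueError("max_step_length must be positive")
        if self.B_magnitude < 0:
            raise ValueError("B_magnitude must be non-negative")
        if isinstance(self.source_energy, str):
            if self.source_energy.upper() != "Y90":
                raise ValueError("spectrum tag must be 'Y90'")
        elif self.source_energy <= 0:
            raise ValueError("source_energy must be positive")
        b = np.asarray(self.B_axis, dtype=float)
        if b.shape != (3,) or np.linalg.norm(b) == 0:
            raise ValueError("B_axis must be a non-zero 3-vector")

    @property
    def is_spectrum(self) -> bool:
        return isinstance(self.source_energy, str)

    @property
    def max_source_energy(self) -> float:
        if self.is_spectrum:
            return physics.Y90_SPECTRUM.endpoint_energy
        return float(self.source_energy)

    def b_unit(self) -> np.ndarray:
        b = np.asarray(self.B_axis, dtype=float)
        return b / np.linalg.norm(b)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class HitRecord:
    """One energy deposition: position (mm), deposited energy (MeV), history id."""

    position: np.ndarray
    deposited_energy: float
    particle_id: int


class HitCloud:
    """Columnar set of energy-deposition points from one run.

    Attributes
    ----------
    x, y, z : float32 arrays, mm
        Hit coordinates (float32: ~1e-7 relative rounding, far below any
        geometric tolerance used downstream).
    dE : float32 array, MeV
        Energy deposited at each hit.
    particle_id : int32 array
        History index of each hit.
    initial_energy, escaped_energy : float arrays, per history
    final_position : (n, 3) array, per history stopping/exit point
    config : TransportConfig or None (None for synthetic clouds)
    """

    def __init__(self, x, y, z, dE, particle_id, initial_energy,
                 escaped_energy, final_position, config=None):
        self.x = np.asarray(x, dtype=np.float32)
        self.y = np.asarray(y, dtype=np.float32)
        self.z = np.asarray(z, dtype=np.float32)
        self.dE = np.asarray(dE, dtype=np.float32)
        self.particle_id = np.asarray(particle_id, dtype=np.int32)
        self.initial_energy = np.asarray(initial_energy, dtype=float)
        self.escaped_energy = np.asarray(escaped_energy, dtype=float)
        self.final_position = np.asarray(final_position, dtype=float)
        self.config = config

    def __len__(self) -> int:
        return self.x.size

    @property
    def n_particles(self) -> int:
        return self.initial_energy.size

    def coord(self, axis: str) -> np.ndarray:
        try:
            return {"x": self.x, "y": self.y, "z": self.z}[axis]
        except KeyError:
            raise ValueError(f"axis must be 'x', 'y' or 'z', got {axis!r}")

    def records(self):
        """Iterate hits as :class:`HitRecord` objects (small clouds only)."""
        for i in range(len(self)):
            yield HitRecord(np.array([self.x[i], self.y[i], self.z[i]], dtype=float),
                            float(self.dE[i]), int(self.particle_id[i]))

    def energy_balance(self) -> np.ndarray:
        """Per-history (initial - deposited - escaped) energy, MeV."""
        dep = np.zeros(self.n_particles)
        np.add.at(dep, self.particle_id, self.dE.astype(float))
        return self.initial_energy - dep - self.escaped_energy

    # -- serialization ------------------------------------------------------

    def _config_json(self) -> str:
        return json.dumps(self.config.to_dict() if self.config else {})

    def to_csv(self, path) -> None:
        """Columnar CSV (particle_id, x, y, z, dE) with the config in # headers."""
        with open(path, "w") as fh:
            fh.write(f"# config={self._config_json()}\n")
            fh.write("particle_id,x,y,z,dE\n")
            buf = io.StringIO()
            np.savetxt(buf, np.column_stack([self.particle_id, self.x, self.y,
                                             self.z, self.dE]),
                       fmt="%d,%.6g,%.6g,%.6g,%.6g")
            fh.write(buf.getvalue())

    def to_npz(self, path) -> None:
        """Compact binary container (NumPy .npz) with the config echoed."""
        np.savez_compressed(path, x=self.x, y=self.y, z=self.z, dE=self.dE,
                            particle_id=self.particle_id,
                            initial_energy=self.initial_energy,
                            escaped_energy=self.escaped_energy,
                            final_position=self.final_position,
                            config=np.bytes_(self._config_json().encode()))

    @classmethod
    def from_npz(cls, path) -> "HitCloud":
        with np.load(path) as dat:
            cfg_raw = json.loads(bytes(dat["config"]).decode())
            cfg = TransportConfig(**{**cfg_raw, "B_axis": tuple(cfg_raw["B_axis"])}) if cfg_raw else None
            return cls(dat["x"], dat["y"], dat["z"], dat["dE"], dat["particle_id"],
                       dat["initial_energy"], dat["escaped_energy"],
                       dat["final_position"], cfg)


# ---------------------------------------------------------------------------
# Numba scalar physics (must mirror betamag.physics; guarded by tests)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _nb_momentum(T):
    m = ELECTRON_MASS_MEV
    return math.sqrt((T + m) ** 2 - m * m)


@njit(cache=True)
def _nb_stopping(T, density, i_exc_ev, z_over_a):
    m = ELECTRON_MASS_MEV
    tau = T / m
    gamma = tau + 1.0
    beta2 = 1.0 - 1.0 / (gamma * gamma)
    i_ratio = i_exc_ev * 1e-6 / m
    log_term = math.log(tau * tau * (tau + 2.0) / (2.0 * i_ratio * i_ratio))
    f_term = 1.0 - beta2 + (tau * tau / 8.0 - (2.0 * tau + 1.0) * math.log(2.0)) / (gamma * gamma)
    return 0.1535 * z_over_a * density / beta2 * (log_term + f_term) / 10.0


@njit(cache=True)
def _nb_highland(T, step_mm, density, x0_rad):
    x = step_mm * 0.1 * density
    ratio = x / x0_rad
    if ratio <= 0.0:
        return 0.0
    m = ELECTRON_MASS_MEV
    p = _nb_momentum(T)
    beta = p / (T + m)
    corr = 1.0 + 0.038 * math.log(ratio)
    if corr < 0.0:
        corr = 0.0
    return 13.6 / (beta * p) * math.sqrt(ratio) * corr


@njit(cache=True)
def _nb_step_sigma(T, step_mm, path_before_mm, density, x0_rad):
    """Per-step scattering width, quadrature-consistent with the Highland
    width of the cumulative traversed thickness.

    Highland's logarithmic factor is calibrated for the whole absorber, so
    evaluating it on each ~0.1 mm sub-step underestimates the accumulated
    width by ~20-30%.  Here sigma_step^2 = theta0^2(X + x) - theta0^2(X) at
    the current beta*p, with X the thickness already traversed.
    """
    x = step_mm * 0.1 * density
    if x <= 0.0:
        return 0.0
    x_before = path_before_mm * 0.1 * density
    m = ELECTRON_MASS_MEV
    p = _nb_momentum(T)
    beta = p / (T + m)
    pref = 13.6 / (beta * p)
    r1 = (x_before + x) / x0_rad
    c1 = 1.0 + 0.038 * math.log(r1)
    if c1 < 0.0:
        c1 = 0.0
    th2_1 = pref * pref * r1 * c1 * c1
    if x_before > 0.0:
        r0 = x_before / x0_rad
        c0 = 1.0 + 0.038 * math.log(r0)
        if c0 < 0.0:
            c0 = 0.0
        th2_0 = pref * pref * r0 * c0 * c0
    else:
        th2_0 = 0.0
    d = th2_1 - th2_0
    if d <= 0.0:
        return 0.0
    return math.sqrt(d)


@njit(cache=True)
def _nb_beta_density(T, q, z_daughter):
    if T <= 0.0 or T >= q:
        return 0.0
    m = ELECTRON_MASS_MEV
    p = _nb_momentum(T)
    e_tot = T + m
    beta = p / e_tot
    eta = z_daughter * (1.0 / 137.035999) / beta
    xx = _TWO_PI * eta
    fermi = xx / (1.0 - math.exp(-xx))
    return p * e_tot * (q - T) ** 2 * fermi


@njit(cache=True)
def _mix_seed(seed, pid):
    """SplitMix64-style hash of (seed, particle_id) -> 31-bit stream seed."""
    z = (np.uint64(seed) * np.uint64(0x9E3779B97F4A7C15)
         + np.uint64(pid) * np.uint64(0xBF58476D1CE4E5B9) + np.uint64(0x1D8E4E27C47D124F))
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    z = z ^ (z >> np.uint64(31))
    return np.int64(z & np.uint64(0x7FFFFFFF))


@njit(cache=True)
def _transport_kernel(pos0, dir0, sample_dir, energies, sample_spectrum,
                      q_endpoint, z_daughter, env_max,
                      seed, pid_offset, bx, by, bz, b_mag, radius,
                      cutoff, frac_loss, max_step, scattering,
                      density, i_exc, x0_rad, z_over_a,
                      max_steps_pp,
                      hx, hy, hz, hde, hid, n_hits,
                      init_e, esc_e, final_pos):
    n = energies.shape[0] if not sample_spectrum else init_e.shape[0]
    r2_max = radius * radius
    omega_coef = 0.29979 * b_mag  # phase per unit pathlength = omega_coef / p
    for i in range(n):
        pid = pid_offset + i
        np.random.seed(_mix_seed(seed, pid))

        if sample_dir:
            cos_t = 2.0 * np.random.random() - 1.0
            phi0 = _TWO_PI * np.random.random()
            sin_t = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
            ux = sin_t * math.cos(phi0)
            uy = sin_t * math.sin(phi0)
            uz = cos_t
        else:
            ux, uy, uz = dir0[i, 0], dir0[i, 1], dir0[i, 2]

        if sample_spectrum:
            T = 0.0
            while True:
                t_try = q_endpoint * np.random.random()
                u_try = env_max * np.random.random()
                if u_try < _nb_beta_density(t_try, q_endpoint, z_daughter):
                    T = t_try
                    break
        else:
            T = energies[i]

        x, y, z = pos0[i, 0], pos0[i, 1], pos0[i, 2]
        init_e[i] = T
        esc_e[i] = 0.0
        base = i * max_steps_pp
        nh = 0
        path = 0.0  # cumulative pathlength, mm (enters the scattering width)

        if T <= cutoff:
            if T > 0.0:
                hx[base] = x; hy[base] = y; hz[base] = z
                hde[base] = T
                hid[base] = pid
                nh = 1
            n_hits[i] = nh
            final_pos[i, 0] = x; final_pos[i, 1] = y; final_pos[i, 2] = z
            continue

        while True:
            s_pow = _nb_stopping(T, density, i_exc, z_over_a)
            step = frac_loss * T / s_pow
            if step > max_step:
                step = max_step

            # helical (or straight) advance
            if b_mag > 0.0:
                upar = ux * bx + uy * by + uz * bz
                px = ux - upar * bx
                py = uy - upar * by
                pz = uz - upar * bz
                pmag = math.sqrt(px * px + py * py + pz * pz)
            else:
                upar = 0.0
                px = py = pz = 0.0
                pmag = 0.0
            if b_mag > 0.0 and pmag > 1e-12:
                p_mom = _nb_momentum(T)
                phi = step * omega_coef / p_mom
                r_g = p_mom * pmag / omega_coef
                e1x, e1y, e1z = px / pmag, py / pmag, pz / pmag
                # centre direction for a negative charge: b x e1
                e2x = by * e1z - bz * e1y
                e2y = bz * e1x - bx * e1z
                e2z = bx * e1y - by * e1x
                sphi = math.sin(phi)
                cphi = math.cos(phi)
                x += step * upar * bx + r_g * (sphi * e1x + (1.0 - cphi) * e2x)
                y += step * upar * by + r_g * (sphi * e1y + (1.0 - cphi) * e2y)
                z += step * upar * bz + r_g * (sphi * e1z + (1.0 - cphi) * e2z)
                ux = upar * bx + pmag * (cphi * e1x + sphi * e2x)
                uy = upar * by + pmag * (cphi * e1y + sphi * e2y)
                uz = upar * bz + pmag * (cphi * e1z + sphi * e2z)
                inv = 1.0 / math.sqrt(ux * ux + uy * uy + uz * uz)
                ux *= inv; uy *= inv; uz *= inv
            else:
                x += step * ux
                y += step * uy
                z += step * uz

            if x * x + y * y + z * z > r2_max:
                esc_e[i] = T
                break

            de = s_pow * step
            t_new = T - de
            if t_new <= cutoff:
                hx[base + nh] = x; hy[base + nh] = y; hz[base + nh] = z
                hde[base + nh] = T
                hid[base + nh] = pid
                nh += 1
                break
            hx[base + nh] = x; hy[base + nh] = y; hz[base + nh] = z
            hde[base + nh] = de
            hid[base + nh] = pid
            nh += 1
            T = t_new

            if scattering:
                sigma = _nb_step_sigma(T, step, path, density, x0_rad)
                path += step
                theta = sigma * np.random.standard_normal()
                psi = _TWO_PI * np.random.random()
                st = math.sin(theta)
                ct = math.cos(theta)
                us = st * math.cos(psi)
                vs = st * math.sin(psi)
                if abs(uz) > 0.999999:
                    sgn = 1.0 if uz > 0.0 else -1.0
                    ux, uy, uz = us, vs * sgn, ct * sgn
                else:
                    denom = math.sqrt(1.0 - uz * uz)
                    nx = ux * ct + (ux * uz * us - uy * vs) / denom
                    ny = uy * ct + (uy * uz * us + ux * vs) / denom
                    nz = uz * ct - denom * us
                    inv = 1.0 / math.sqrt(nx * nx + ny * ny + nz * nz)
                    ux, uy, uz = nx * inv, ny * inv, nz * inv

        n_hits[i] = nh
        final_pos[i, 0] = x; final_pos[i, 1] = y; final_pos[i, 2] = z


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def helix_advance(state: ParticleState, B: np.ndarray, step_length: float) -> ParticleState:
    """Advance one electron along the exact helix for a uniform field ``B`` (tesla).

    Energy is unchanged; B = 0 (or motion parallel to B) reduces to a
    straight-line advance.  Returns a new :class:`ParticleState`.
    """
    if step_length <= 0:
        raise ValueError("step_length must be positive")
    B = np.asarray(B, dtype=float)
    b_mag = float(np.linalg.norm(B))
    u = state.direction.astype(float)
    pos = state.position.astype(float)
    if b_mag == 0.0:
        return ParticleState(pos + step_length * u, u.copy(), state.kinetic_energy,
                             state.alive)
    b = B / b_mag
    upar = float(u @ b)
    uperp = u - upar * b
    pmag = float(np.linalg.norm(uperp))
    if pmag < 1e-12:
        return ParticleState(pos + step_length * u, u.copy(), state.kinetic_energy,
                             state.alive)
    p_mom = physics.momentum_from_kinetic(state.kinetic_energy)
    omega = 0.29979 * b_mag
    phi = step_length * omega / p_mom
    r_g = p_mom * pmag / omega
    e1 = uperp / pmag
    e2 = np.cross(b, e1)  # centre direction for the electron's negative charge
    new_pos = pos + step_length * upar * b + r_g * (math.sin(phi) * e1
                                                    + (1.0 - math.cos(phi)) * e2)
    new_u = upar * b + pmag * (math.cos(phi) * e1 + math.sin(phi) * e2)
    new_u /= np.linalg.norm(new_u)
    return ParticleState(new_pos, new_u, state.kinetic_energy, state.alive)


def _max_steps_bound(config: TransportConfig, material: Material) -> int:
    t0 = config.max_source_energy
    f = config.max_fractional_energy_loss_per_step
    n_frac = math.log(t0 / config.cutoff_energy) / -math.log1p(-f)
    n_cap = physics.csda_range(t0, material, config.cutoff_energy) / config.max_step_length
    return int(n_frac + n_cap) + 8


def _run_chunk(config: TransportConfig, material: Material, pos0, dir0,
               sample_dir, energies, n, pid_offset, max_steps):
    hx = np.empty(n * max_steps, dtype=np.float32)
    hy = np.empty_like(hx)
    hz = np.empty_like(hx)
    hde = np.empty_like(hx)
    hid = np.empty(n * max_steps, dtype=np.int32)
    n_hits = np.zeros(n, dtype=np.int64)
    init_e = np.zeros(n)
    esc_e = np.zeros(n)
    final_pos = np.zeros((n, 3))
    if config.is_spectrum:
        spec = physics.Y90_SPECTRUM
        grid = np.linspace(1e-6, spec.endpoint_energy - 1e-9, 4096)
        env = 1.05 * physics.beta_spectrum_density(grid, spec).max()
        q, zd = spec.endpoint_energy, float(spec.atomic_number_daughter)
        energies = np.zeros(n)
        sample_spectrum = True
    else:
        env, q, zd = 0.0, 0.0, 0.0
        sample_spectrum = False
    b = config.b_unit()
    _transport_kernel(pos0, dir0, sample_dir, energies, sample_spectrum,
                      q, zd, env, config.seed, pid_offset,
                      b[0], b[1], b[2], config.B_magnitude, config.sphere_radius,
                      config.cutoff_energy, config.max_fractional_energy_loss_per_step,
                      config.max_step_length, config.scattering,
                      material.density, material.mean_excitation_energy,
                      material.radiation_length, material.Z_over_A,
                      max_steps,
                      hx, hy, hz, hde, hid, n_hits, init_e, esc_e, final_pos)
    keep = np.repeat(np.arange(n) * max_steps, n_hits) + _ranges(n_hits)
    return (hx[keep], hy[keep], hz[keep], hde[keep], hid[keep],
            init_e, esc_e, final_pos)


def _ranges(counts: np.ndarray) -> np.ndarray:
    """Concatenated [0..c) ranges for each count, vectorised."""
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    idx = np.arange(total, dtype=np.int64)
    starts = np.repeat(np.cumsum(counts) - counts, counts)
    return idx - starts


def transport_particle(initial: ParticleState, config: TransportConfig,
                       rng_seed: int | None = None,
                       material: Material = WATER) -> list[HitRecord]:
    """Transport a single electron from ``initial``; return its hit records.

    ``rng_seed`` keys the history's random substream (default: config.seed
    with particle id 0).  Raises ``ValueError`` if the start point lies
    outside the sphere.
    """
    if float(np.linalg.norm(initial.position)) > config.sphere_radius:
        raise ValueError("initial position lies outside the sphere")
    cfg = dataclasses.replace(config, n_particles=1,
                              seed=config.seed if rng_seed is None else rng_seed)
    max_steps = _max_steps_bound(cfg, material)
    pos0 = initial.position.reshape(1, 3).astype(np.float64)
    dir0 = initial.direction.reshape(1, 3).astype(np.float64)
    energies = np.array([float(initial.kinetic_energy)])
    hx, hy, hz, hde, hid, init_e, esc_e, fpos = _run_chunk(
        dataclasses.replace(cfg, source_energy=float(initial.kinetic_energy))
        if cfg.is_spectrum else cfg,
        material, pos0, dir0, False, energies, 1, 0, max_steps)
    return [HitRecord(np.array([hx[i], hy[i], hz[i]], dtype=float),
                      float(hde[i]), int(hid[i])) for i in range(hx.size)]


def run_simulation(config: TransportConfig, material: Material = WATER,
                   chunk_size: int = 20_000) -> HitCloud:
    """Run ``config.n_particles`` isotropic histories from the sphere centre.

    Histories are processed in chunks to bound memory; per-particle
    substreams make the result identical for any chunk size.
    """
    max_steps = _max_steps_bound(config, material)
    parts = []
    per_particle = ([], [], [])
    n_total = config.n_particles
    for start in range(0, n_total, chunk_size):
        n = min(chunk_size, n_total - start)
        pos0 = np.zeros((n, 3))
        dir0 = np.zeros((n, 3))
        energies = (np.zeros(n) if config.is_spectrum
                    else np.full(n, float(config.source_energy)))
        out = _run_chunk(config, material, pos0, dir0, True, energies, n,
                         start, max_steps)
        parts.append(out[:5])
        per_particle[0].append(out[5])
        per_particle[1].append(out[6])
        per_particle[2].append(out[7])
    hx, hy, hz, hde, hid = (np.concatenate([p[k] for p in parts]) for k in range(5))
    return HitCloud(hx, hy, hz, hde, hid,
                    np.concatenate(per_particle[0]),
                    np.concatenate(per_particle[1]),
                    np.vstack(per_particle[2]),
                    config)
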