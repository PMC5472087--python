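"""Electron physics ingredients: kinematics, stopping power, scattering, beta spectra.

Everything downstream (the condensed-history transport engine, the
analysis stages) consumes only what is defined here, so the project-wide
unit system is fixed in this module:

    length   mm
    energy   MeV (kinetic unless noted)
    field    tesla
    density  g/cm^3

The medium is liquid water throughout; other materials can be described
with :class:`Material` but no other preset is shipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate

__all__ = [
    "ELECTRON_MASS_MEV",
    "Material",
    "WATER",
    "BetaSpectrum",
    "Y90_SPECTRUM",
    "ParticleState",
    "momentum_from_kinetic",
    "kinetic_from_momentum",
    "beta_from_kinetic",
    "gyroradius",
    "collision_stopping_power",
    "csda_range",
    "highland_sigma",
    "beta_spectrum_density",
    "sample_y90_spectrum",
    "sample_beta_spectrum",
]

#: Electron rest mass energy, MeV.
ELECTRON_MASS_MEV = 0.510999

#: 2*pi*N_A*r_e^2*m_e*c^2 in MeV cm^2/g — prefactor of the Bethe formula.
_BETHE_K = 0.1535

#: Fine-structure constant.
_ALPHA = 1.0 / 137.035999

#: p[MeV/c] = 0.29979 * B[T] * r[mm] for unit charge.
_PC_PER_TESLA_MM = 0.29979


@dataclass(frozen=True)
class Material:
    """Bulk material description for electron transport.

    Parameters
    ----------
    density : float
        Mass density in g/cm^3.
    mean_excitation_energy : float
        Mean excitation energy I in eV (enters the Bethe logarithm).
    radiation_length : float
        Radiation length X0 in g/cm^2 (enters multiple scattering).
    Z_over_A : float
        Ratio of atomic number to mass number, electrons per nucleon.
    """

    density: float
    mean_excitation_energy: float
    radiation_length: float
    Z_over_A: float

    def __post_init__(self) -> None:
        for name in ("density", "mean_excitation_energy", "radiation_length", "Z_over_A"):
            if getattr(self, name) <= 0:
                raise ValueError(f"Material.{name} must be strictly positive")


#: Liquid water: I = 75 eV, X0 = 36.08 g/cm^2, Z/A = 0.5551.
WATER = Material(density=1.0, mean_excitation_energy=75.0,
                 radiation_length=36.08, Z_over_A=0.5551)

_MATERIAL_PRESETS = {"water": WATER}


def get_material(name: str) -> Material:
    """Look up a material preset by name (currently only ``"water"``)."""
    try:
        return _MATERIAL_PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown material preset {name!r}; known: {sorted(_MATERIAL_PRESETS)}")


@dataclass(frozen=True)
class BetaSpectrum:
    """Allowed beta-minus spectrum with endpoint ``endpoint_energy`` (Q value, MeV).

    ``atomic_number_daughter`` is the Z entering the Fermi function.
    ``half_life_h`` is carried as metadata only; it plays no role in transport.
    """

    endpoint_energy: float
    atomic_number_daughter: int
    normalization: float = 1.0
    half_life_h: float | None = None

    def __post_init__(self) -> None:
        if self.endpoint_energy <= 0:
            raise ValueError("endpoint_energy must be positive")
        if self.atomic_number_daughter < 0:
            raise ValueError("atomic_number_daughter must be non-negative")


#: Y-90 beta decay: Q = 2.28 MeV, daughter Zr (Z = 40), half-life 64.1 h.
Y90_SPECTRUM = BetaSpectrum(endpoint_energy=2.28, atomic_number_daughter=40,
                            half_life_h=64.1)


@dataclass
class ParticleState:
    """Position (mm), unit direction, kinetic energy (MeV) of one electron."""

    position: np.ndarray
    direction: np.ndarray
    kinetic_energy: float
    alive: bool = True

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        norm = float(np.linalg.norm(self.direction))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector (|u| = 1 within 1e-9)")
        if self.kinetic_energy < 0:
            raise ValueError("kinetic_energy must be non-negative")


# ---------------------------------------------------------------------------
# Relativistic kinematics
# ---------------------------------------------------------------------------

def momentum_from_kinetic(T):
    """Electron momentum p (MeV/c) from kinetic energy T (MeV).

    p = sqrt((T + m)^2 - m^2) with m = 0.510999 MeV.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T < 0):
        raise ValueError("kinetic energy must be non-negative")
    m = ELECTRON_MASS_MEV
    p = np.sqrt((T + m) ** 2 - m * m)
    return float(p) if p.ndim == 0 else p


def kinetic_from_momentum(p):
    """Inverse of :func:`momentum_from_kinetic`."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("momentum must be non-negative")
    m = ELECTRON_MASS_MEV
    T = np.sqrt(p * p + m * m) - m
    return float(T) if T.ndim == 0 else T


def beta_from_kinetic(T):
    """Velocity in units of c: beta = p / E_total."""
    T = np.asarray(T, dtype=float)
    m = ELECTRON_MASS_MEV
    b = np.sqrt(T * (T + 2 * m)) / (T + m)
    return float(b) if b.ndim == 0 else b


def gyroradius(T: float, B: float, pitch_fraction: float = 1.0) -> float:
    """Larmor radius in mm of an electron of kinetic energy T in a field B.

    ``pitch_fraction`` is the fraction of the momentum perpendicular to B,
    so ``r = p * pitch_fraction / (0.29979 * B)``.

    Raises
    ------
    ZeroDivisionError
        For B = 0 (infinite radius; callers use a straight-line advance).
    """
    if not 0.0 <= pitch_fraction <= 1.0:
        raise ValueError("pitch_fraction must lie in [0, 1]")
    if B == 0:
        raise ZeroDivisionError("gyroradius is infinite at B = 0; use a straight step")
    if B < 0:
        raise ValueError("B must be non-negative")
    return momentum_from_kinetic(T) * pitch_fraction / (_PC_PER_TESLA_MM * B)


# ---------------------------------------------------------------------------
# Stopping power and range
# ---------------------------------------------------------------------------

def collision_stopping_power(T, material: Material = WATER):
    """Collision (electronic) stopping power of electrons, MeV/mm.

    Bethe formula with the Moller closure for free-electron collisions,

        S = K (Z/A) rho / beta^2 [ ln( tau^2 (tau+2) / (2 (I/m)^2) ) + F(tau) ]

    with tau = T/m and

        F(tau) = 1 - beta^2 + [ tau^2/8 - (2 tau + 1) ln 2 ] / (tau + 1)^2.

    The density-effect correction is omitted: below ~2.3 MeV in water it is
    a sub-percent effect, and leaving it out keeps the expression closed-form.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("kinetic energy must be strictly positive")
    m = ELECTRON_MASS_MEV
    tau = T / m
    gamma = tau + 1.0
    beta2 = 1.0 - 1.0 / (gamma * gamma)
    i_ratio = material.mean_excitation_energy * 1e-6 / m
    log_term = np.log(tau * tau * (tau + 2.0) / (2.0 * i_ratio * i_ratio))
    f_term = 1.0 - beta2 + (tau * tau / 8.0 - (2.0 * tau + 1.0) * math.log(2.0)) / (gamma * gamma)
    s_mev_per_cm = _BETHE_K * material.Z_over_A * material.density / beta2 * (log_term + f_term)
    s = s_mev_per_cm / 10.0  # MeV/cm -> MeV/mm
    return float(s) if s.ndim == 0 else s


def csda_range(T: float, material: Material = WATER, cutoff: float = 0.010) -> float:
    """Continuous-slowing-down range in mm: integral of dT'/S(T') from cutoff to T.

    The sub-cutoff residual pathlength (a few microns for a 10 keV cutoff)
    is neglected, matching the transport engine which deposits the residual
    energy locally.
    """
    if T <= cutoff:
        return 0.0
    val, err = integrate.quad(lambda t: 1.0 / collision_stopping_power(t, material),
                              cutoff, T, limit=200)
    if not np.isfinite(val) or (val > 0 and err / val > 1e-6):
        raise ArithmeticError("CSDA range quadrature did not converge")
    return float(val)


def highland_sigma(T, step_length, material: Material = WATER):
    """Gaussian multiple-scattering polar width (radian) over one step.

    Highland parameterisation: theta0 = 13.6 MeV / (beta p) * sqrt(x/X0)
    * (1 + 0.038 ln(x/X0)), with x the step in mass thickness (g/cm^2).
    The logarithmic factor is clamped at zero so the width is never negative.
    """
    T = np.asarray(T, dtype=float)
    step_length = np.asarray(step_length, dtype=float)
    if np.any(step_length < 0):
        raise ValueError("step_length must be non-negative")
    if np.any(T <= 0):
        raise ValueError("kinetic energy must be strictly positive")
    x = step_length * 0.1 * material.density  # mm -> cm, times g/cm^3
    ratio = x / material.radiation_length
    p = momentum_from_kinetic(T)
    beta = beta_from_kinetic(T)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.where(ratio > 0, 1.0 + 0.038 * np.log(ratio), 0.0)
        sigma = np.where(ratio > 0,
                         13.6 / (beta * p) * np.sqrt(ratio) * np.maximum(corr, 0.0),
                         0.0)
    return float(sigma) if sigma.ndim == 0 else sigma


# ---------------------------------------------------------------------------
# Beta spectrum
# ---------------------------------------------------------------------------

def _fermi_function(T, Z: int):
    """Non-relativistic Fermi function F = 2 pi eta / (1 - exp(-2 pi eta)).

    eta = Z alpha E_tot / p = Z alpha / beta for a beta-minus electron in the
    Coulomb field of the daughter nucleus of charge Z.
    """
    beta = beta_from_kinetic(T)
    eta = Z * _ALPHA / beta
    x = 2.0 * np.pi * eta
    return x / (-np.expm1(-x))


def beta_spectrum_density(T, spectrum: BetaSpectrum = Y90_SPECTRUM,
                          fermi: bool = True):
    """Unnormalised allowed beta-spectrum density N(T) on (0, Q).

    N(T) = p * E_tot * (Q - T)^2 * F(Z, E); zero outside (0, Q).
    """
    T = np.asarray(T, dtype=float)
    q = spectrum.endpoint_energy
    inside = (T > 0) & (T < q)
    Ts = np.where(inside, T, 0.5 * q)  # dummy value to keep kinematics finite
    p = momentum_from_kinetic(Ts)
    e_tot = Ts + ELECTRON_MASS_MEV
    dens = p * e_tot * (q - Ts) ** 2
    if fermi:
        dens = dens * _fermi_function(Ts, spectrum.atomic_number_daughter)
    dens = np.where(inside, dens, 0.0)
    return float(dens) if dens.ndim == 0 else dens


def beta_spectrum_norm(spectrum: BetaSpectrum = Y90_SPECTRUM, fermi: bool = True) -> float:
    """Integral of the unnormalised density over (0, Q)."""
    val, _ = integrate.quad(lambda t: beta_spectrum_density(t, spectrum, fermi),
                            0.0, spectrum.endpoint_energy, limit=200)
    return float(val)


def sample_beta_spectrum(n: int, seed, spectrum: BetaSpectrum = Y90_SPECTRUM,
                         fermi: bool = True) -> np.ndarray:
    """Draw ``n`` kinetic energies (MeV) by rejection against the analytic density.

    The envelope is a constant 1.05 x the density maximum found on a fine
    grid, so accepted samples follow the exact analytic shape.  ``seed`` may
    be an int or a numpy Generator; results are reproducible per seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    q = spectrum.endpoint_energy
    grid = np.linspace(1e-6, q - 1e-9, 4096)
    env = 1.05 * beta_spectrum_density(grid, spectrum, fermi).max()
    out = np.empty(n)
    filled = 0
    while filled < n:
        m = max(int((n - filled) * 1.8) + 16, 64)
        t = rng.uniform(0.0, q, m)
        u = rng.uniform(0.0, env, m)
        acc = t[u < beta_spectrum_density(t, spectrum, fermi)]
        take = min(acc.size, n - filled)
        out[filled:filled + take] = acc[:take]
        filled += take
    return out


def sample_y90_spectrum(n: int, seed) -> np.ndarray:
    """Draw ``n`` Y-90 beta kinetic energies (Q = 2.28 MeV, Fermi-corrected)."""
    return sample_beta_spectrum(n, seed, Y90_SPECTRUM, fermi=True)
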