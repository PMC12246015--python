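"""Ogden hyperelasticity, octahedral shear strain, and the loading protocol.

The scaffold material (an oxidized alginate-gelatin hydrogel) is modeled as
a one-term Ogden solid with mu_1 = -5.8 kPa, alpha_1 = -1.3, assumed fully
incompressible (d_1 = 0).  Loading is a single raised-cosine compression
cycle: the piston displacement is

    d(t) = A/2 * (1 - cos(2 pi f t)),   A = amplitude_fraction * H_scaffold,

so displacement and velocity vanish at t = 0, the peak compression (5 % of
the scaffold height by default) occurs at mid-cycle, and the release phase
mirrors the compression phase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OgdenParams",
    "StretchState",
    "PrincipalStrains",
    "LoadingProtocol",
    "strain_energy",
    "uniaxial_nominal_stress",
    "octahedral_shear_strain",
    "piston_displacement",
    "piston_velocity",
]


@dataclass(frozen=True)
class OgdenParams:
    """Ogden material constants.

    ``terms`` is a sequence of ``(mu_i [kPa], alpha_i, d_i [1/kPa])``.
    ``d_i = 0`` is the incompressibility sentinel: the corresponding
    volumetric term is omitted rather than divided by zero.
    """

    terms: tuple[tuple[float, float, float], ...] = ((-5.8, -1.3, 0.0),)

    def __post_init__(self) -> None:
        if len(self.terms) < 1:
            raise ValueError("at least one Ogden term is required")
        for mu, alpha, d in self.terms:
            if alpha == 0:
                raise ValueError("alpha_i = 0 is not a valid Ogden exponent")
            if d < 0:
                raise ValueError("d_i must be non-negative")

    @property
    def incompressible(self) -> bool:
        return all(d == 0.0 for _, _, d in self.terms)


@dataclass(frozen=True)
class StretchState:
    """Principal stretches and volume ratio."""

    l1: float
    l2: float
    l3: float

    def __post_init__(self) -> None:
        if min(self.l1, self.l2, self.l3) <= 0:
            raise ValueError("principal stretches must be positive")

    @property
    def J(self) -> float:
        return self.l1 * self.l2 * self.l3

    @classmethod
    def uniaxial_incompressible(cls, l: float) -> "StretchState":
        """Uniaxial stretch ``l`` with equal lateral stretches, J = 1."""
        return cls(l, l**-0.5, l**-0.5)


@dataclass(frozen=True)
class PrincipalStrains:
    e1: float
    e2: float
    e3: float


@dataclass(frozen=True)
class LoadingProtocol:
    """Sinusoidal compression protocol (one cycle)."""

    frequency: float = 1.0  # Hz
    amplitude_fraction: float = 0.05
    scaffold_height: float = 4.8  # mm
    timestep: float = 0.01  # s

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if not 0 < self.amplitude_fraction < 1:
            raise ValueError("amplitude_fraction must lie in (0, 1)")
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")

    @property
    def period(self) -> float:
        return 1.0 / self.frequency

    @property
    def amplitude(self) -> float:
        """Peak piston displacement in mm."""
        return self.amplitude_fraction * self.scaffold_height

    def times(self) -> np.ndarray:
        """Sample times covering one full cycle, both endpoints included."""
        n = int(round(self.period / self.timestep))
        return np.linspace(0.0, self.period, n + 1)


def strain_energy(params: OgdenParams, state: StretchState) -> float:
    """Ogden strain-energy density W in kPa.

    ``W = sum_i mu_i/alpha_i (l1^a_i + l2^a_i + l3^a_i - 3)
         + sum_i (1/d_i)(J - 1)^(2i)`` with the volumetric sum skipped for
    ``d_i = 0``.  Deviatoric stretches equal the principal stretches for
    incompressible states (J = 1), which is the only mode exercised here.
    """
    l1, l2, l3 = state.l1, state.l2, state.l3
    J = state.J
    w = 0.0
    for i, (mu, alpha, d) in enumerate(params.terms, start=1):
        w += mu / alpha * (l1**alpha + l2**alpha + l3**alpha - 3.0)
        if d > 0:
            w += (J - 1.0) ** (2 * i) / d
    return w


def uniaxial_nominal_stress(params: OgdenParams, l: float) -> float:
    """Nominal (first Piola-Kirchhoff) stress in kPa for incompressible
    uniaxial loading at stretch ``l``.

    Closed form ``P = sum_i mu_i (l^(a_i - 1) - l^(-a_i/2 - 1))`` obtained by
    eliminating the pressure with the traction-free lateral faces.  With the
    default constants compression (l < 1) gives negative stress.
    """
    if l <= 0:
        raise ValueError("stretch must be positive")
    if not params.incompressible:
        raise ValueError("closed form requires a fully incompressible parameter set")
    return sum(
        mu * (l ** (alpha - 1.0) - l ** (-alpha / 2.0 - 1.0))
        for mu, alpha, _ in params.terms
    )


def octahedral_shear_strain(strains: PrincipalStrains | np.ndarray) -> float | np.ndarray:
    """Octahedral shear strain from elastic principal strains.

    ``OSS = 2/3 sqrt((e1-e2)^2 + (e2-e3)^2 + (e3-e1)^2)``; invariant under
    permutation of the strains and under adding a constant to all three.
    Accepts a :class:`PrincipalStrains` or an array with the three strains
    on the last axis.
    """
    if isinstance(strains, PrincipalStrains):
        e1, e2, e3 = strains.e1, strains.e2, strains.e3
    else:
        arr = np.asarray(strains, dtype=float)
        e1, e2, e3 = arr[..., 0], arr[..., 1], arr[..., 2]
    if not np.all(np.isfinite(e1)) or not np.all(np.isfinite(e2)) or not np.all(
        np.isfinite(e3)
    ):
        raise ValueError("principal strains must be finite")
    return (2.0 / 3.0) * np.sqrt(
        (e1 - e2) ** 2 + (e2 - e3) ** 2 + (e3 - e1) ** 2
    )


def _check_cycle_time(protocol: LoadingProtocol, t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < -1e-12) or np.any(t > protocol.period + 1e-12):
        raise ValueError(f"time outside the loading cycle [0, {protocol.period}] s")
    return t


def piston_displacement(protocol: LoadingProtocol, t: float | np.ndarray):
    """Downward piston displacement (mm) at time ``t`` within one cycle."""
    t = _check_cycle_time(protocol, t)
    a = protocol.amplitude
    out = 0.5 * a * (1.0 - np.cos(2.0 * math.pi * protocol.frequency * t))
    return float(out) if np.isscalar(t) or out.ndim == 0 else out


def piston_velocity(protocol: LoadingProtocol, t: float | np.ndarray):
    """Piston speed (mm/s, signed; positive while compressing)."""
    t = _check_cycle_time(protocol, t)
    a = protocol.amplitude
    w = 2.0 * math.pi * protocol.frequency
    out = 0.5 * a * w * np.sin(w * t)
    return float(out) if np.isscalar(t) or out.ndim == 0 else out
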