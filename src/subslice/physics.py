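"""Electron-interaction physics for keV electrons in light-element resins.

Quantities needed by the Monte Carlo engine: total elastic cross sections
(screened-Rutherford analytic form with a relativistic screening factor),
elastic mean free paths, mean ionization potentials and Bethe stopping power
in the Joy-Luo low-energy modification.  Units are keV for energies, nm for
lengths, g/cm^3 for mass densities; number densities are atoms/nm^3.

The elastic model is a deliberate analytic surrogate for tabulated
Mott/ELSEPA partial-wave cross sections: absolute backscatter yields can
differ from partial-wave codes by tens of percent for high-Z elements at
energies at or below 1 keV.  The cross-section callable is pluggable
(see :class:`CrossSectionModel`) so tabulated data can be substituted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Element",
    "Material",
    "elastic_cross_section",
    "browning_cross_section",
    "screening_parameter",
    "sample_scatter_cosine",
    "mean_scatter_cosine",
    "mean_ionization_potential",
    "stopping_power",
    "elastic_mfp",
    "epon812",
    "stained_epon812",
    "methods_resin",
    "ATOMIC_MASSES",
]

#: Avogadro's number scaled so that rho [g/cm^3] * N_A / A [g/mol] is in
#: atoms/nm^3 (1 cm^3 = 1e21 nm^3).
_NA_PER_NM3 = 6.02214076e23 / 1.0e21  # = 602.214... atoms*mol/(g*nm^3) scale

#: Standard atomic masses (g/mol) for elements relevant to stained resins.
ATOMIC_MASSES = {
    1: 1.008,    # H
    6: 12.011,   # C
    7: 14.007,   # N
    8: 15.999,   # O
    16: 32.06,   # S
    17: 35.45,   # Cl
    29: 63.546,  # Cu
    76: 190.23,  # Os
    82: 207.2,   # Pb
    92: 238.03,  # U
}

_E_MIN, _E_MAX = 0.05, 30.0  # keV validity window of the analytic forms
_Z_MIN, _Z_MAX = 1, 92

#: Joy-Luo low-energy correction constant (dimensionless), default for all
#: elements; overridable per element through Material.
DEFAULT_JOY_LUO_K = 0.77


def screening_parameter(Z: float, E: float) -> float:
    """Screened-Rutherford screening parameter alpha = 3.4e-3 Z^0.67 / E."""
    return 3.4e-3 * Z**0.67 / E


def elastic_cross_section(Z, E):
    """Total elastic cross section per atom, in nm^2.

    Screened-Rutherford analytic form with relativistic factor::

        sigma = 5.21e-21 * Z^2/E^2 * 4 pi / (alpha (1 + alpha))
                * ((E + 511)/(E + 1024))^2   [cm^2]

    with ``alpha = 3.4e-3 Z^0.67 / E`` and E in keV.

    Parameters
    ----------
    Z : int or array
        Atomic number, 1..92.
    E : float or array
        Electron energy in keV, 0.05..30.
    """
    Z = np.asarray(Z)
    E = np.asarray(E)
    if np.any(E < _E_MIN) or np.any(E > _E_MAX):
        raise ValueError(f"energy outside supported range [{_E_MIN}, {_E_MAX}] keV")
    if np.any(Z < _Z_MIN) or np.any(Z > _Z_MAX):
        raise ValueError(f"atomic number outside supported range [{_Z_MIN}, {_Z_MAX}]")
    alpha = 3.4e-3 * Z**0.67 / E
    rel = ((E + 511.0) / (E + 1024.0)) ** 2
    sigma_cm2 = 5.21e-21 * (Z.astype(float) ** 2 / E**2) * (4.0 * np.pi) / (
        alpha * (1.0 + alpha)
    ) * rel
    return sigma_cm2 * 1.0e14  # cm^2 -> nm^2


def browning_cross_section(Z, E):
    """Total elastic cross section per atom in nm^2, Browning empirical fit.

    Browning's fit to tabulated Mott partial-wave cross sections::

        sigma = 3.0e-18 * Z^1.7
                / (E + 0.005 Z^1.7 sqrt(E) + 0.0007 Z^2 / sqrt(E))   [cm^2]

    with E in keV, stated valid for 0.1-30 keV and all Z.  Unlike the
    screened-Rutherford form it does not blow up for heavy elements at low
    energy (for Pb at 1 keV it is ~4x smaller), which matters for the
    absolute backscatter yield of heavy-atom stains.
    """
    Z = np.asarray(Z, dtype=float)
    E = np.asarray(E, dtype=float)
    if np.any(E < _E_MIN) or np.any(E > _E_MAX):
        raise ValueError(f"energy outside supported range [{_E_MIN}, {_E_MAX}] keV")
    if np.any(Z < _Z_MIN) or np.any(Z > _Z_MAX):
        raise ValueError(f"atomic number outside supported range [{_Z_MIN}, {_Z_MAX}]")
    z17 = Z**1.7
    sigma_cm2 = 3.0e-18 * z17 / (E + 0.005 * z17 * np.sqrt(E) + 0.0007 * Z**2 / np.sqrt(E))
    return sigma_cm2 * 1.0e14  # cm^2 -> nm^2


def sample_scatter_cosine(alpha, u):
    """Polar scattering cosine for the screened-Rutherford angular law.

    ``cos(theta) = 1 - 2 alpha u / (1 + alpha - u)`` maps a uniform variate
    u in [0, 1] to cos(theta) in [-1, 1] (u=0 -> no deflection, u=1 ->
    backscatter through pi).
    """
    alpha = np.asarray(alpha, dtype=float)
    u = np.asarray(u, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("screening parameter must be positive")
    if np.any((u < 0) | (u > 1)):
        raise ValueError("uniform variate must lie in [0, 1]")
    c = 1.0 - 2.0 * alpha * u / (1.0 + alpha - u)
    return np.clip(c, -1.0, 1.0)


def mean_scatter_cosine(alpha: float) -> float:
    """Analytic mean of the sampled scattering cosine at fixed alpha.

    E[cos theta] = 1 + 2 alpha - 2 alpha (1 + alpha) ln((1 + alpha)/alpha),
    obtained by integrating the sampling map over u ~ U[0, 1].
    """
    a = float(alpha)
    return 1.0 + 2.0 * a - 2.0 * a * (1.0 + a) * math.log((1.0 + a) / a)


def mean_ionization_potential(Z) -> np.ndarray | float:
    """Mean ionization potential J in keV (Berger-Seltzer fit).

    ``J = (9.76 Z + 58.5 Z^-0.19) * 1e-3`` keV.  The fit is known to be
    rough for hydrogen (Z=1); the Material class accepts per-element
    overrides should a measured value be preferred.
    """
    Z = np.asarray(Z)
    if np.any(Z < 1):
        raise ValueError("Z must be >= 1")
    return (9.76 * Z + 58.5 * Z ** (-0.19)) * 1.0e-3


@dataclass(frozen=True)
class Element:
    """One elemental constituent of a compound material."""

    Z: int
    atomic_fraction: float
    atomic_mass: float | None = None  # g/mol; looked up when omitted
    joy_luo_k: float = DEFAULT_JOY_LUO_K
    J_override: float | None = None  # keV; optional measured J

    def __post_init__(self):
        if not (_Z_MIN <= self.Z <= _Z_MAX):
            raise ValueError(f"Z={self.Z} outside [{_Z_MIN}, {_Z_MAX}]")
        if not (0.0 <= self.atomic_fraction <= 1.0):
            raise ValueError("atomic fraction must lie in [0, 1]")
        if self.atomic_mass is None:
            if self.Z not in ATOMIC_MASSES:
                raise ValueError(
                    f"no built-in atomic mass for Z={self.Z}; pass atomic_mass"
                )
            object.__setattr__(self, "atomic_mass", ATOMIC_MASSES[self.Z])
        if self.atomic_mass <= 0:
            raise ValueError("atomic mass must be positive")

    @property
    def J(self) -> float:
        """Mean ionization potential in keV."""
        if self.J_override is not None:
            return self.J_override
        return float(mean_ionization_potential(self.Z))


@dataclass(frozen=True)
class Material:
    """Compound material: elemental composition plus mass density.

    Atomic fractions must sum to one.  Derived per-element number densities
    (atoms/nm^3) follow from ``n_i = f_i * rho * N_A / <A>`` with
    ``<A> = sum_i f_i A_i`` the mean atomic mass.
    """

    elements: tuple[Element, ...]
    mass_density: float  # g/cm^3
    name: str = ""

    def __post_init__(self):
        object.__setattr__(self, "elements", tuple(self.elements))
        if self.mass_density <= 0:
            raise ValueError("mass density must be positive")
        total = sum(e.atomic_fraction for e in self.elements)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"atomic fractions sum to {total}, expected 1")

    @classmethod
    def from_fractions(
        cls, composition: Sequence[tuple[int, float]], mass_density: float, name: str = ""
    ) -> "Material":
        """Build from ``[(Z, atomic_fraction), ...]`` plus density."""
        elements = tuple(Element(Z=z, atomic_fraction=f) for z, f in composition)
        return cls(elements=elements, mass_density=mass_density, name=name)

    @property
    def mean_atomic_mass(self) -> float:
        """Mean atomic mass <A> in g/mol."""
        return sum(e.atomic_fraction * e.atomic_mass for e in self.elements)

    @property
    def total_number_density(self) -> float:
        """Total atom number density in atoms/nm^3."""
        return self.mass_density * _NA_PER_NM3 / self.mean_atomic_mass

    @property
    def number_densities(self) -> np.ndarray:
        """Per-element number densities, atoms/nm^3, ordered as elements."""
        n_tot = self.total_number_density
        return np.array([e.atomic_fraction * n_tot for e in self.elements])

    @property
    def mass_fractions(self) -> np.ndarray:
        mean_a = self.mean_atomic_mass
        return np.array(
            [e.atomic_fraction * e.atomic_mass / mean_a for e in self.elements]
        )


def stopping_power(material: Material, E) -> np.ndarray | float:
    """Collision stopping power dE/ds in keV/nm (Joy-Luo modified Bethe).

    Bragg additivity over elements::

        dE/ds = 7.85e-3 * rho / E
                * sum_i w_i (Z_i/A_i) ln(1.166 (E + k_i J_i) / J_i)

    with rho in g/cm^3, mass fractions w_i, and J_i in keV.  The Joy-Luo
    term ``k_i J_i`` keeps the logarithm positive down to the tracking
    cutoff, where the plain Bethe formula would turn negative.
    """
    E = np.asarray(E, dtype=float)
    if np.any(E <= 0):
        raise ValueError("energy must be positive")
    w = material.mass_fractions
    acc = np.zeros_like(E, dtype=float)
    for wi, el in zip(w, material.elements):
        J = el.J
        acc = acc + wi * (el.Z / el.atomic_mass) * np.log(
            1.166 * (E + el.joy_luo_k * J) / J
        )
    out = 7.85e-3 * material.mass_density / E * acc
    return out if out.ndim else float(out)


def elastic_mfp(
    material: Material, E, cross_section: "CrossSectionModel" = elastic_cross_section
) -> np.ndarray | float:
    """Elastic mean free path in nm: ``lambda = 1 / sum_i n_i sigma_i(E)``."""
    n = material.number_densities
    E = np.asarray(E, dtype=float)
    sig = np.array([cross_section(el.Z, E) for el in material.elements])
    total = np.tensordot(n, sig, axes=(0, 0))
    out = 1.0 / total
    return out if np.ndim(out) else float(out)


# A pluggable cross-section hook: callable (Z, E_keV) -> sigma_nm2.  The
# Monte Carlo engine takes this as an argument so tabulated Mott data can be
# dropped in without touching the transport code.
CrossSectionModel = Callable[[np.ndarray, np.ndarray], np.ndarray]


def epon812() -> Material:
    """Unstained Epon 812 epoxy resin: H 0.53 / C 0.35 / O 0.12, 1.22 g/cm^3."""
    return Material.from_fractions(
        [(1, 0.53), (6, 0.35), (8, 0.12)], mass_density=1.22, name="epon812"
    )


def stained_epon812(pb_atomic_fraction: float = 0.03, mass_density: float = 1.52) -> Material:
    """Epoxy resin containing lead at a given fraction of the total atom count.

    The default (3 at% Pb, 1.52 g/cm^3) is the bulk stained-block material
    used for yield benchmarks.  Resin H/C/O proportions are rescaled by
    (1 - f) so fractions sum to one.
    """
    f = pb_atomic_fraction
    if not (0.0 <= f < 0.5):
        raise ValueError("Pb atomic fraction must lie in [0, 0.5)")
    comp = [(1, 0.53 * (1 - f)), (6, 0.35 * (1 - f)), (8, 0.12 * (1 - f)), (82, f)]
    return Material.from_fractions(
        comp, mass_density=mass_density, name=f"epon812+Pb({f:g})"
    )


def methods_resin() -> Material:
    """Epoxy resin with the composition used for stain-content estimates:
    C 0.36 / H 0.52 / O 0.12 at 1.22 g/cm^3."""
    return Material.from_fractions(
        [(6, 0.36), (1, 0.52), (8, 0.12)], mass_density=1.22, name="resin(C36H52O12)"
    )
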