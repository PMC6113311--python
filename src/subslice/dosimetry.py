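"""Electron-dose and stain-content arithmetic.

Fluence budgeting against the radiation-induced shrinkage limit of resin
blocks (~15-20 e/nm^2 total across both energy channels), and estimation
of heavy-atom stain content from measured block densities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .physics import Material, methods_resin

__all__ = [
    "ELEMENTARY_CHARGE",
    "PB_ATOMIC_MASS",
    "AcquisitionSettings",
    "electrons_from_current",
    "total_fluence",
    "fluence_budget_check",
    "stain_mass_ratio",
    "heavy_atom_fraction",
]

ELEMENTARY_CHARGE = 1.602176634e-19  # C
PB_ATOMIC_MASS = 207.2  # g/mol; default stain species for NCMIR-style blocks

#: Total-fluence band above which resin blocks shrink and cut non-uniformly.
DEFAULT_FLUENCE_LIMIT = 15.0  # e/nm^2 (conservative end of the 15-20 band)


@dataclass(frozen=True)
class AcquisitionSettings:
    """Probe and scan settings for one dual-energy acquisition."""

    probe_current_pA: float
    dwell_us: tuple[float, ...]  # one dwell per energy channel
    pixel_nm: float
    energies_keV: tuple[float, ...] = ()
    cut_increment_nm: float = 25.0

    def __post_init__(self):
        if self.probe_current_pA <= 0:
            raise ValueError("probe current must be positive")
        if any(d <= 0 for d in self.dwell_us):
            raise ValueError("dwell times must be positive")
        if self.pixel_nm <= 0:
            raise ValueError("pixel size must be positive")


def electrons_from_current(current_pA: float, dwell_us: float) -> float:
    """Electrons delivered by a probe current over one dwell: Q = I t / e."""
    if current_pA < 0 or dwell_us < 0:
        raise ValueError("current and dwell must be nonnegative")
    return current_pA * 1e-12 * dwell_us * 1e-6 / ELEMENTARY_CHARGE


def total_fluence(settings: AcquisitionSettings) -> float:
    """Total incident fluence in e/nm^2, summed over energy channels."""
    electrons = sum(
        electrons_from_current(settings.probe_current_pA, d) for d in settings.dwell_us
    )
    return electrons / settings.pixel_nm**2


def fluence_budget_check(
    fluence: float, limit: float = DEFAULT_FLUENCE_LIMIT
) -> dict:
    """Compare a fluence against the shrinkage limit.

    Returns ``{"ok": bool, "fluence": ..., "limit": ..., "margin": ...}``;
    a fluence exactly at the limit passes with zero margin.
    """
    if fluence < 0:
        raise ValueError("fluence must be nonnegative")
    margin = limit - fluence
    return {"ok": margin >= 0.0, "fluence": fluence, "limit": limit, "margin": margin}


def stain_mass_ratio(rho_stained: float, rho_resin: float) -> float:
    """Grams of stain per gram of resin from the two block densities:
    ``(rho_stained - rho_resin) / rho_resin``."""
    if not rho_stained >= rho_resin > 0:
        raise ValueError("need rho_stained >= rho_resin > 0")
    return (rho_stained - rho_resin) / rho_resin


def heavy_atom_fraction(
    mass_ratio: float,
    resin: Material | None = None,
    stain_mean_mass: float = PB_ATOMIC_MASS,
) -> float:
    """Atomic fraction of heavy stain atoms implied by a stain mass ratio.

    With m = grams of stain per gram of resin, M_s the mean stain atomic
    mass and <A> the resin's mean atomic mass, the stain atoms per resin
    gram are m/M_s against 1/<A> resin atoms, so

        f = (m/M_s) / (m/M_s + 1/<A>).

    The default stain species is pure lead; en-bloc protocols deposit an
    Os/Pb/U mix whose proportions are preparation-dependent, so the mean
    stain mass is configurable.
    """
    if mass_ratio < 0:
        raise ValueError("mass ratio must be nonnegative")
    if stain_mean_mass <= 0:
        raise ValueError("stain mean atomic mass must be positive")
    if resin is None:
        resin = methods_resin()
    stain_moles = mass_ratio / stain_mean_mass
    resin_moles = 1.0 / resin.mean_atomic_mass
    return stain_moles / (stain_moles + resin_moles)
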