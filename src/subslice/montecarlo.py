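"""Trajectory-level Monte Carlo of keV electrons in voxelized specimens.

Single-scattering transport: free paths are exponential with the local
elastic mean free path, energy decreases continuously along the path
(continuous-slowing-down approximation with Joy-Luo stopping power), and
elastic collisions deflect the electron by the screened-Rutherford angular
law.  An electron terminates when its energy falls below the tracking
cutoff (absorbed), when it exits through the top surface (backscattered,
if above cutoff), or when it leaves the block through a side or the bottom.

The stepping loop is vectorized over batches of electrons; steps inside a
voxel phantom are capped at a quarter of the smallest voxel edge so thin
stained layers are never overshot (the exponential free path is memoryless,
so truncating and re-sampling is unbiased).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .physics import (
    ATOMIC_MASSES,
    DEFAULT_JOY_LUO_K,
    Element,
    Material,
    browning_cross_section,
    elastic_cross_section,
    mean_ionization_potential,
    stopping_power,
)

#: Elastic models usable by the transport loop.  Both sample scattering
#: angles from the screened-Rutherford angular law; they differ in the
#: total elastic cross section that sets collision rates.  "browning"
#: (default) uses Browning's empirical fit to Mott partial-wave totals,
#: which stays accurate for heavy elements at ~1 keV where the analytic
#: screened-Rutherford total is several times too large; "rutherford" is
#: the pure analytic model throughout.
_MODELS = {
    "browning": browning_cross_section,
    "rutherford": elastic_cross_section,
}
DEFAULT_MODEL = "browning"
from .phantom import VoxelPhantom

__all__ = [
    "BeamParameters",
    "DetectorModel",
    "TrajectoryRecord",
    "BSEImage",
    "simulate_trajectory",
    "bulk_yield",
    "simulate_image",
    "csda_range",
]

_OUTCOME_NAMES = {1: "backscattered", 2: "absorbed", 3: "escaped_side_or_bottom"}
_CHUNK = 200_000
_MAX_STEPS = 50_000


@dataclass(frozen=True)
class BeamParameters:
    """Incident probe settings for one landing energy."""

    energy_keV: float
    electrons_per_pixel: int
    pixel_nm: float
    cutoff_keV: float = 0.05
    gaussian_sigma_nm: float | None = None  # None = delta probe at pixel center

    def __post_init__(self):
        if not (0.5 <= self.energy_keV <= 5.0):
            raise ValueError("landing energy outside supported range 0.5-5 keV")
        if self.electrons_per_pixel < 1:
            raise ValueError("need at least one electron per pixel")
        if self.cutoff_keV >= self.energy_keV:
            raise ValueError("tracking cutoff must be below the landing energy")

    @property
    def fluence(self) -> float:
        """Incident fluence J0 in electrons/nm^2."""
        return self.electrons_per_pixel / self.pixel_nm**2


@dataclass(frozen=True)
class DetectorModel:
    """BSE detector: every top-surface escape above cutoff counts, scaled by
    a collection efficiency (no angular restriction by default)."""

    efficiency: float = 1.0

    def __post_init__(self):
        if not (0.0 < self.efficiency <= 1.0):
            raise ValueError("detector efficiency must lie in (0, 1]")


@dataclass
class TrajectoryRecord:
    outcome: str
    exit_energy_keV: float
    exit_direction: tuple[float, float, float] | None
    vertices: np.ndarray | None = None  # (n, 3) path positions in nm


@dataclass
class BSEImage:
    """Per-pixel backscattered counts with acquisition metadata."""

    counts: np.ndarray  # (ny, nx), float (expected) or int (realized)
    energy_keV: float
    electrons_per_pixel: float
    pixel_nm: float
    meta: dict = field(default_factory=dict)

    @property
    def eta(self) -> np.ndarray:
        """Backscattering coefficient per pixel: counts / electrons per pixel."""
        return np.asarray(self.counts, dtype=float) / self.electrons_per_pixel


class _TransportTables:
    """Energy-interpolated material quantities for one base material plus an
    optional stain element at variable number density."""

    def __init__(
        self,
        material: Material,
        stain_Z: int,
        E0: float,
        cutoff: float,
        model: str = DEFAULT_MODEL,
    ):
        if model not in _MODELS:
            raise ValueError(f"unknown elastic model {model!r}; use one of {sorted(_MODELS)}")
        cross_section = _MODELS[model]
        self.model = model
        self.material = material
        grid = np.geomspace(max(0.05, 0.8 * cutoff), E0 * 1.0001, 256)
        self.grid = grid
        n = material.number_densities
        self.matrix_Z = np.array([el.Z for el in material.elements])
        # per-element macroscopic elastic cross sections n_i * sigma_i(E), 1/nm
        self.matrix_nsig = np.stack(
            [ni * cross_section(el.Z, grid) for ni, el in zip(n, material.elements)]
        )
        self.matrix_nsig_tot = self.matrix_nsig.sum(axis=0)
        self.stain_Z = stain_Z
        self.stain_sig = cross_section(stain_Z, grid)  # nm^2 per stain atom
        self.sp_matrix = stopping_power(material, grid)  # keV/nm
        # stain contribution to stopping power per unit stain number density:
        # (keV/nm) per (atom/nm^3)
        A_st = ATOMIC_MASSES[stain_Z]
        J_st = float(mean_ionization_potential(stain_Z))
        rho_per_n = A_st / 602.214076  # g/cm^3 per atom/nm^3
        self.sp_stain_per_n = (
            7.85e-3
            * rho_per_n
            / grid
            * (stain_Z / A_st)
            * np.log(1.166 * (grid + DEFAULT_JOY_LUO_K * J_st) / J_st)
        )
        self.alpha_coef_matrix = 3.4e-3 * self.matrix_Z.astype(float) ** 0.67
        self.alpha_coef_stain = 3.4e-3 * float(stain_Z) ** 0.67
        self.all_Z = np.append(self.matrix_Z.astype(float), float(stain_Z))

    def interp(self, table: np.ndarray, E: np.ndarray) -> np.ndarray:
        return np.interp(E, self.grid, table)


def csda_range(material: Material, E: float, cutoff: float = 0.05) -> float:
    """Continuous-slowing-down range in nm, by quadrature of 1/(dE/ds)."""
    grid = np.linspace(cutoff, E, 512)
    sp = stopping_power(material, grid)
    return float(np.trapezoid(1.0 / sp, grid))


def _rotate(ux, uy, uz, cos_t, phi):
    """Deflect unit vectors by polar angle theta and azimuth phi."""
    sin_t = np.sqrt(np.maximum(0.0, 1.0 - cos_t**2))
    cp, sp = np.cos(phi), np.sin(phi)
    denom = np.sqrt(np.maximum(1e-24, 1.0 - uz**2))
    near_pole = denom < 1e-6
    nux = ux * cos_t + sin_t * (ux * uz * cp - uy * sp) / denom
    nuy = uy * cos_t + sin_t * (uy * uz * cp + ux * sp) / denom
    nuz = uz * cos_t - denom * sin_t * cp
    # beam along +/-z: rotate about an arbitrary azimuth
    if np.any(near_pole):
        s = np.sign(uz[near_pole])
        nux[near_pole] = sin_t[near_pole] * cp[near_pole]
        nuy[near_pole] = sin_t[near_pole] * sp[near_pole]
        nuz[near_pole] = s * cos_t[near_pole]
    norm = np.sqrt(nux**2 + nuy**2 + nuz**2)
    return nux / norm, nuy / norm, nuz / norm


def _transport(
    x: np.ndarray,
    y: np.ndarray,
    tables: _TransportTables,
    E0: float,
    cutoff: float,
    rng: np.random.Generator,
    stain: np.ndarray | None = None,  # (nz, ny, nx) atoms/nm^3
    voxel_nm: tuple[float, float, float] | None = None,
    depth_nm: float = np.inf,
    lateral_extent: tuple[float, float] | None = None,
    clamp_lateral: bool = False,
    record_path: bool = False,
):
    """Run one batch of electrons entering at (x, y, z=0) along +z.

    Returns (outcome, exit_E, exit_u, paths): outcome codes 1 =
    backscattered, 2 = absorbed, 3 = escaped side/bottom; exit_u holds the
    exit direction for backscattered electrons.
    """
    n = x.size
    x = x.astype(float).copy()
    y = y.astype(float).copy()
    z = np.zeros(n)
    ux = np.zeros(n)
    uy = np.zeros(n)
    uz = np.ones(n)
    E = np.full(n, float(E0))
    outcome = np.zeros(n, dtype=np.uint8)
    exit_E = np.zeros(n)
    exit_u = np.zeros((n, 3))
    paths = [[(xi, yi, 0.0)] for xi, yi in zip(x, y)] if record_path else None

    if stain is not None:
        nz_g, ny_g, nx_g = stain.shape
        dx, dy, dz = voxel_nm
        s_cap = min(voxel_nm) / 4.0
        stain_flat = stain.reshape(-1)
    else:
        s_cap = None

    act = np.arange(n)
    for _ in range(_MAX_STEPS):
        if act.size == 0:
            break
        Ea = np.clip(E[act], tables.grid[0], tables.grid[-1])
        if stain is not None:
            ix = np.floor(x[act] / dx).astype(np.int64)
            iy = np.floor(y[act] / dy).astype(np.int64)
            iz = np.floor(z[act] / dz).astype(np.int64)
            np.clip(ix, 0, nx_g - 1, out=ix)
            np.clip(iy, 0, ny_g - 1, out=iy)
            np.clip(iz, 0, nz_g - 1, out=iz)
            S = stain_flat[(iz * ny_g + iy) * nx_g + ix].astype(float)
        else:
            S = 0.0
        sig_tot = tables.interp(tables.matrix_nsig_tot, Ea)
        sig_st = tables.interp(tables.stain_sig, Ea)
        Sigma = sig_tot + S * sig_st
        lam = 1.0 / Sigma
        s_col = -lam * np.log1p(-rng.random(act.size))
        if s_cap is not None:
            s = np.minimum(s_col, s_cap)
            collide = s_col <= s_cap
        else:
            s = s_col
            collide = np.ones(act.size, dtype=bool)
        sp = tables.interp(tables.sp_matrix, Ea) + S * tables.interp(
            tables.sp_stain_per_n, Ea
        )
        E_new = E[act] - s * sp
        xn = x[act] + s * ux[act]
        yn = y[act] + s * uy[act]
        zn = z[act] + s * uz[act]
        x[act], y[act], z[act], E[act] = xn, yn, zn, E_new
        if record_path:
            for i, j in enumerate(act):
                paths[j].append((xn[i], yn[i], zn[i]))

        backs = (zn < 0.0) & (E_new > cutoff)
        absorbed = E_new <= cutoff
        out_bottom = zn >= depth_nm
        if lateral_extent is not None and not clamp_lateral:
            X, Y = lateral_extent
            out_side = (xn < 0) | (xn >= X) | (yn < 0) | (yn >= Y)
        else:
            out_side = np.zeros(act.size, dtype=bool)
        escaped = (out_bottom | out_side) & ~backs & ~absorbed
        done = backs | absorbed | escaped
        idx_b = act[backs]
        outcome[idx_b] = 1
        exit_E[idx_b] = E_new[backs]
        exit_u[idx_b, 0] = ux[idx_b]
        exit_u[idx_b, 1] = uy[idx_b]
        exit_u[idx_b, 2] = uz[idx_b]
        outcome[act[absorbed & ~backs & ~escaped]] = 2
        outcome[act[escaped]] = 3

        live = ~done
        scat = live & collide
        if np.any(scat):
            idx_s = act[scat]
            Es = np.clip(E[idx_s], tables.grid[0], tables.grid[-1])
            # pick the scattering element with probability n_i sigma_i / Sigma
            k = tables.matrix_nsig.shape[0]
            weights = np.empty((k + 1, idx_s.size))
            for j in range(k):
                weights[j] = tables.interp(tables.matrix_nsig[j], Es)
            Ss = S[scat] if isinstance(S, np.ndarray) else 0.0
            weights[k] = Ss * tables.interp(tables.stain_sig, Es)
            cum = np.cumsum(weights, axis=0)
            r = rng.random(idx_s.size) * cum[-1]
            sel = (r[None, :] >= cum[:-1]).sum(axis=0) if k > 0 else np.zeros(
                idx_s.size, dtype=int
            )
            alpha_coefs = np.append(tables.alpha_coef_matrix, tables.alpha_coef_stain)
            alpha = alpha_coefs[sel] / Es
            u2 = rng.random(idx_s.size)
            cos_t = 1.0 - 2.0 * alpha * u2 / (1.0 + alpha - u2)
            phi = 2.0 * np.pi * rng.random(idx_s.size)
            nux, nuy, nuz = _rotate(ux[idx_s], uy[idx_s], uz[idx_s], cos_t, phi)
            ux[idx_s], uy[idx_s], uz[idx_s] = nux, nuy, nuz
        act = act[live]
    else:
        # safety: anything still in flight is deemed absorbed
        outcome[act] = 2

    return outcome, exit_E, exit_u, paths


def simulate_trajectory(
    phantom: VoxelPhantom,
    beam: BeamParameters,
    entry: tuple[float, float],
    rng: np.random.Generator,
    model: str = DEFAULT_MODEL,
) -> TrajectoryRecord:
    """Track a single electron through a phantom, recording path vertices."""
    X, Y, Z = phantom.extent_nm
    ex, ey = entry
    if not (0 <= ex < X and 0 <= ey < Y):
        raise ValueError("entry point outside the block's lateral extent")
    tables = _TransportTables(
        phantom.material, phantom.stain_Z, beam.energy_keV, beam.cutoff_keV, model
    )
    outcome, exit_E, exit_u, paths = _transport(
        np.array([ex]),
        np.array([ey]),
        tables,
        beam.energy_keV,
        beam.cutoff_keV,
        rng,
        stain=phantom.stain,
        voxel_nm=phantom.voxel_nm,
        depth_nm=Z,
        lateral_extent=(X, Y),
        record_path=True,
    )
    code = int(outcome[0])
    return TrajectoryRecord(
        outcome=_OUTCOME_NAMES[code],
        exit_energy_keV=float(exit_E[0]),
        exit_direction=tuple(exit_u[0]) if code == 1 else None,
        vertices=np.array(paths[0]),
    )


def bulk_yield(
    material: Material,
    E: float,
    n_electrons: int,
    rng: np.random.Generator,
    cutoff: float = 0.05,
    return_exits: bool = False,
    model: str = DEFAULT_MODEL,
):
    """Backscattering coefficient of a semi-infinite homogeneous block.

    Returns ``(eta, standard_error)``; with ``return_exits`` also the exit
    energies and directions of the backscattered electrons.
    """
    if n_electrons < 1000:
        raise ValueError("use at least 1e3 electrons for a yield estimate")
    tables = _TransportTables(material, 82, E, cutoff, model)
    depth = 4.0 * csda_range(material, E, cutoff)
    n_bs = 0
    exitsE, exitsU = [], []
    for start in range(0, n_electrons, _CHUNK):
        m = min(_CHUNK, n_electrons - start)
        outcome, exit_E, exit_u, _ = _transport(
            np.zeros(m), np.zeros(m), tables, E, cutoff, rng, depth_nm=depth
        )
        bs = outcome == 1
        n_bs += int(bs.sum())
        if return_exits:
            exitsE.append(exit_E[bs])
            exitsU.append(exit_u[bs])
    eta = n_bs / n_electrons
    se = float(np.sqrt(max(eta * (1.0 - eta), 1e-12) / n_electrons))
    if return_exits:
        return eta, se, np.concatenate(exitsE), np.vstack(exitsU)
    return eta, se


def simulate_image(
    phantom: VoxelPhantom,
    beam: BeamParameters,
    detector: DetectorModel,
    rng: np.random.Generator,
    roi_nm: tuple[float, float, float, float] | None = None,
    model: str = DEFAULT_MODEL,
) -> BSEImage:
    """Scan a pixel grid over the phantom and collect backscatter counts.

    ``roi_nm = (x0, y0, width, height)`` selects the scanned region
    (default: the full lateral extent); the pixel pitch is
    ``beam.pixel_nm`` and each pixel receives ``beam.electrons_per_pixel``
    electrons at its center (or Gaussian-blurred entry points when the beam
    declares a probe sigma).
    """
    X, Y, Z = phantom.extent_nm
    p = beam.pixel_nm
    if roi_nm is None:
        roi_nm = (0.0, 0.0, X, Y)
    x0, y0, w, h = roi_nm
    if x0 < 0 or y0 < 0 or x0 + w > X + 1e-9 or y0 + h > Y + 1e-9:
        raise ValueError("ROI extends outside the block")
    nx_px = int(round(w / p))
    ny_px = int(round(h / p))
    if nx_px < 1 or ny_px < 1:
        raise ValueError("ROI smaller than one pixel")
    tables = _TransportTables(
        phantom.material, phantom.stain_Z, beam.energy_keV, beam.cutoff_keV, model
    )
    counts = np.zeros(ny_px * nx_px, dtype=np.int64)
    J = beam.electrons_per_pixel
    pix_ids = np.repeat(np.arange(ny_px * nx_px), J)
    cx = x0 + (np.arange(nx_px) + 0.5) * p
    cy = y0 + (np.arange(ny_px) + 0.5) * p
    ex = np.tile(cx, ny_px)[:, None].repeat(J, axis=1).ravel()
    ey = np.repeat(cy, nx_px)[:, None].repeat(J, axis=1).ravel()
    if beam.gaussian_sigma_nm:
        ex = ex + rng.normal(0.0, beam.gaussian_sigma_nm, ex.size)
        ey = ey + rng.normal(0.0, beam.gaussian_sigma_nm, ey.size)
        np.clip(ex, 0.0, X * (1 - 1e-12), out=ex)
        np.clip(ey, 0.0, Y * (1 - 1e-12), out=ey)
    for start in range(0, ex.size, _CHUNK):
        sl = slice(start, min(start + _CHUNK, ex.size))
        outcome, _, _, _ = _transport(
            ex[sl],
            ey[sl],
            tables,
            beam.energy_keV,
            beam.cutoff_keV,
            rng,
            stain=phantom.stain,
            voxel_nm=phantom.voxel_nm,
            depth_nm=Z,
            lateral_extent=(X, Y),
        )
        bs = outcome == 1
        np.add.at(counts, pix_ids[sl][bs], 1)
    if detector.efficiency < 1.0:
        counts = rng.binomial(counts, detector.efficiency)
    return BSEImage(
        counts=counts.reshape(ny_px, nx_px),
        energy_keV=beam.energy_keV,
        electrons_per_pixel=J,
        pixel_nm=p,
        meta={"roi_nm": list(roi_nm), "detector_efficiency": detector.efficiency},
    )


def depth_profile_yield(
    profile_S: np.ndarray,
    dz: float,
    material: Material,
    stain_Z: int,
    E: float,
    n_electrons: int,
    rng: np.random.Generator,
    cutoff: float = 0.05,
    model: str = DEFAULT_MODEL,
) -> tuple[float, float]:
    """Backscatter yield of a laterally infinite layered target.

    ``profile_S[k]`` is the stain density (atoms/nm^3) in the depth slab
    [k*dz, (k+1)*dz); below the profile the target continues as unstained
    resin out to several CSDA ranges.  Used by the calibration module,
    where laterally extended slabs suppress probe-spread edge losses.
    """
    depth = 4.0 * csda_range(material, E, cutoff)
    n_deep = max(0, int(np.ceil(depth / dz)) - profile_S.size)
    prof = np.concatenate([np.asarray(profile_S, dtype=np.float32), np.zeros(n_deep, np.float32)])
    stain = prof.reshape(-1, 1, 1)
    tables = _TransportTables(material, stain_Z, E, cutoff, model)
    n_bs = 0
    for start in range(0, n_electrons, _CHUNK):
        m = min(_CHUNK, n_electrons - start)
        outcome, _, _, _ = _transport(
            np.full(m, 0.5),
            np.full(m, 0.5),
            tables,
            E,
            cutoff,
            rng,
            stain=stain,
            voxel_nm=(1.0, 1.0, dz),
            depth_nm=prof.size * dz,
            clamp_lateral=True,
        )
        n_bs += int((outcome == 1).sum())
    eta = n_bs / n_electrons
    se = float(np.sqrt(max(eta * (1.0 - eta), 1e-12) / n_electrons))
    return eta, se
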