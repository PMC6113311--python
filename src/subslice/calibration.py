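"""Depth-response calibration: the matrix linking stain density to signal.

The per-pixel forward model is ``B_m = J0_px * dz * sum_n A[m, n] * S_n``,
where ``B_m`` is the background-subtracted stain signal (counts/pixel) at
landing energy ``E_m``, ``S_n`` the stain density (atoms/nm^3) in depth
layer n of thickness dz, and ``A`` an effective per-atom scattering cross
section in nm^2.  A is measured by Monte Carlo: for each energy, one
laterally extended stained slab per layer plus an unstained reference, with

    A[m, n] = (eta_stained - eta_background) / (S * dz).

Slabs (rather than finite cuboids) suppress lateral point-spread edge
losses; a cuboid-mode flag reproduces finite-target calibrations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .montecarlo import DEFAULT_MODEL, depth_profile_yield
from .phantom import NOMINAL_STAIN_DENSITY
from .physics import Material, epon812

__all__ = [
    "ResponseMatrix",
    "DepthResponseTable",
    "compute_depth_response",
    "build_response_matrix",
    "invert_response",
    "suggest_energy_pair",
    "PUBLISHED_RESPONSE_MATRIX",
]

#: Published 2x2 reference matrix for landing energies (1.0, 1.4) keV and
#: 12.5-nm sub-slices (units nm^2); rows are energies, columns layers.
PUBLISHED_RESPONSE_MATRIX = np.array(
    [[1.043e-3, 0.130e-3], [0.898e-3, 0.648e-3]]
)

DEFAULT_CONDITION_LIMIT = 50.0


@dataclass
class ResponseMatrix:
    """N x N depth-response coefficients with provenance.

    ``A[m, n]`` couples stain in layer n (thickness ``dz`` nm) to the
    signal at energy ``energies[m]``; units nm^2.  ``A_inv`` (nm^-2) is
    populated by :func:`invert_response`.
    """

    energies: tuple[float, ...]  # keV, one per row
    dz: float  # layer thickness, nm
    A: np.ndarray  # (N, N) nm^2
    A_err: np.ndarray | None = None  # standard errors, same shape
    A_inv: np.ndarray | None = None  # (N, N) nm^-2
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 2 or self.A.shape[0] != self.A.shape[1]:
            raise ValueError("A must be square")
        if len(self.energies) != self.A.shape[0]:
            raise ValueError("one energy per matrix row is required")
        if self.dz <= 0:
            raise ValueError("layer thickness must be positive")

    @property
    def n_layers(self) -> int:
        return self.A.shape[0]

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.A))

    @property
    def scaling_ratio(self) -> float:
        """Row-sum ratio (A11+A12)/(A21+A22): the factor by which the mean
        intensity of a through-thickness structure at E_low relates to the
        same structure at E_high (used to put acquired stacks on one scale)."""
        sums = self.A.sum(axis=1)
        return float(sums[0] / sums[-1])

    def to_dict(self) -> dict:
        return {
            "energies_keV": list(self.energies),
            "dz_nm": self.dz,
            "A_nm2": self.A.tolist(),
            "A_err_nm2": None if self.A_err is None else self.A_err.tolist(),
            "A_inv_nm-2": None if self.A_inv is None else self.A_inv.tolist(),
            "condition_number": self.condition_number,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ResponseMatrix":
        return cls(
            energies=tuple(d["energies_keV"]),
            dz=d["dz_nm"],
            A=np.array(d["A_nm2"]),
            A_err=None if d.get("A_err_nm2") is None else np.array(d["A_err_nm2"]),
            A_inv=None if d.get("A_inv_nm-2") is None else np.array(d["A_inv_nm-2"]),
            provenance=d.get("provenance", {}),
        )


@dataclass
class DepthResponseTable:
    """Background-subtracted stain signal per incident electron, indexed by
    (energy, layer depth), with binomial standard errors."""

    energies: np.ndarray  # (M,) keV
    dz: float  # nm
    signal: np.ndarray  # (M, N) delta-eta per incident electron
    signal_err: np.ndarray  # (M, N)
    background: np.ndarray  # (M,) unstained-resin eta
    stain_density: float  # atoms/nm^3 used in the stained slabs
    provenance: dict = field(default_factory=dict)

    def layer_share(self, m: int) -> np.ndarray:
        """Fraction of the total stain signal contributed by each layer at
        energy index m (negative noise floor values are clipped to zero)."""
        s = np.clip(self.signal[m], 0.0, None)
        tot = s.sum()
        if tot <= 0:
            return np.zeros_like(s)
        return s / tot


def compute_depth_response(
    energies,
    dz: float = 12.5,
    n_layers: int = 2,
    stain_density: float = NOMINAL_STAIN_DENSITY,
    n_electrons: int = 50_000,
    rng: np.random.Generator | None = None,
    material: Material | None = None,
    stain_Z: int = 82,
    cutoff: float = 0.05,
    model: str = DEFAULT_MODEL,
    geometry: str = "slab",
    cuboid_xy: float = 50.0,
) -> DepthResponseTable:
    """Measure the per-layer depth response by Monte Carlo.

    For each energy (ascending), simulates an unstained reference target and
    one single-layer stained target per depth layer; the tabulated signal is
    ``eta_stained - eta_background`` per incident electron.

    ``geometry="slab"`` (default) uses laterally infinite stained slabs,
    which measure the plateau response free of lateral point-spread edge
    losses.  ``geometry="cuboid"`` reproduces finite-target fidelity runs:
    a single ``cuboid_xy``-sized stained cuboid per layer, probed at its
    central pixels, which yields slightly smaller coefficients because
    part of the interaction volume leaves the stained region.
    """
    energies = np.asarray(sorted(float(e) for e in np.atleast_1d(energies)))
    if rng is None:
        rng = np.random.default_rng()
    if material is None:
        material = epon812()
    if stain_density < 0:
        raise ValueError("stain density must be nonnegative")
    if geometry not in ("slab", "cuboid"):
        raise ValueError(f"unknown calibration geometry {geometry!r}")
    signal = np.zeros((energies.size, n_layers))
    err = np.zeros_like(signal)
    background = np.zeros(energies.size)
    if geometry == "cuboid":
        yields = _cuboid_yields(
            energies, dz, n_layers, stain_density, cuboid_xy, n_electrons,
            rng, material, stain_Z, cutoff, model,
        )
    for m, E in enumerate(energies):
        if geometry == "cuboid":
            (eta_bg, se_bg), per_layer = yields[m]
        else:
            eta_bg, se_bg = depth_profile_yield(
                np.zeros(1), dz, material, stain_Z, E, n_electrons, rng, cutoff, model
            )
        background[m] = eta_bg
        for n in range(n_layers):
            if geometry == "cuboid":
                eta, se = per_layer[n]
            else:
                profile = np.zeros(n + 1)
                profile[n] = stain_density
                eta, se = depth_profile_yield(
                    profile, dz, material, stain_Z, E, n_electrons, rng, cutoff, model
                )
            signal[m, n] = eta - eta_bg
            err[m, n] = float(np.hypot(se, se_bg))
    if np.any(signal[:, 0] < 3 * err[:, 0]) and stain_density > 0:
        warnings.warn(
            "layer-1 signal not resolved at 3 sigma for some energies; "
            "increase n_electrons",
            stacklevel=2,
        )
    return DepthResponseTable(
        energies=energies,
        dz=dz,
        signal=signal,
        signal_err=err,
        background=background,
        stain_density=stain_density,
        provenance={
            "n_electrons": n_electrons,
            "model": model,
            "cutoff_keV": cutoff,
            "material": material.name,
        },
    )


def _cuboid_yields(
    energies, dz, n_layers, stain_density, cuboid_xy, n_electrons,
    rng, material, stain_Z, cutoff, model,
):
    """Central-pixel yields of single stained cuboids, one per layer, plus
    an unstained reference, for cuboid-mode calibration."""
    from .montecarlo import BeamParameters, DetectorModel, simulate_image
    from .phantom import Cuboid, add_cuboid, make_block

    det = DetectorModel()
    extent = max(800.0, 8 * cuboid_xy)
    n_px = max(1, int(cuboid_xy / (2 * dz)))  # central pixels only
    roi_w = n_px * dz
    out = []
    for E in energies:
        per_pixel = max(1, n_electrons // n_px**2)
        beam = BeamParameters(
            energy_keV=float(E), electrons_per_pixel=per_pixel, pixel_nm=dz,
            cutoff_keV=cutoff,
        )
        depth = max((n_layers + 1) * dz * 4, 400.0)
        center = extent / 2.0

        def _yield(layer: int | None):
            ph = make_block((extent, extent, depth), (dz, dz, dz), material)
            ph.stain_Z = stain_Z
            if layer is not None:
                add_cuboid(
                    ph,
                    Cuboid(
                        (center, center, (layer + 0.5) * dz),
                        (cuboid_xy, cuboid_xy, dz),
                        stain_density,
                    ),
                    snap=True,
                )
            img = simulate_image(
                ph, beam, det, rng,
                roi_nm=(center - roi_w / 2, center - roi_w / 2, roi_w, roi_w),
                model=model,
            )
            eta = float(img.eta.mean())
            n_tot = per_pixel * n_px**2
            se = float(np.sqrt(max(eta * (1 - eta), 1e-12) / n_tot))
            return eta, se

        bg = _yield(None)
        per_layer = [_yield(n) for n in range(n_layers)]
        out.append((bg, per_layer))
    return out


def build_response_matrix(
    E_low: float,
    E_high: float,
    dz: float = 12.5,
    stain_density: float = NOMINAL_STAIN_DENSITY,
    n_electrons: int = 200_000,
    rng: np.random.Generator | None = None,
    material: Material | None = None,
    stain_Z: int = 82,
    cutoff: float = 0.05,
    model: str = DEFAULT_MODEL,
) -> ResponseMatrix:
    """Calibrate the 2x2 response matrix for an energy pair.

    ``A[m, n] = (eta_stained(layer n, E_m) - eta_bg(E_m)) / (S * dz)`` so
    that A carries units of nm^2.  Raises if any coefficient is consistent
    with <= 0 (the energy pair cannot resolve that layer).
    """
    if not E_low < E_high:
        raise ValueError("E_low must be strictly below E_high")
    if stain_density <= 0:
        raise ValueError("stain density must be positive")
    table = compute_depth_response(
        [E_low, E_high],
        dz=dz,
        n_layers=2,
        stain_density=stain_density,
        n_electrons=n_electrons,
        rng=rng,
        material=material,
        stain_Z=stain_Z,
        cutoff=cutoff,
        model=model,
    )
    A = table.signal / (stain_density * dz)
    A_err = table.signal_err / (stain_density * dz)
    if np.any(A <= 2 * A_err):
        bad = np.argwhere(A <= 2 * A_err)[0]
        raise RuntimeError(
            f"response coefficient A[{bad[0]},{bad[1]}] is consistent with zero: "
            "this energy pair cannot resolve that layer at this electron count"
        )
    return ResponseMatrix(
        energies=(float(table.energies[0]), float(table.energies[1])),
        dz=dz,
        A=A,
        A_err=A_err,
        provenance={
            **table.provenance,
            "stain_density": stain_density,
            "background_eta": table.background.tolist(),
        },
    )


def invert_response(
    A: ResponseMatrix, condition_limit: float = DEFAULT_CONDITION_LIMIT
) -> ResponseMatrix:
    """Populate ``A_inv``; refuses ill-conditioned matrices.

    With more layers than two, coefficients for deep layers approach zero at
    practical energies and the inverse degrades quickly; the condition-number
    gate guards against that regime.
    """
    cond = A.condition_number
    if not np.isfinite(cond) or cond >= condition_limit:
        raise np.linalg.LinAlgError(
            f"response matrix condition number {cond:.3g} exceeds the limit "
            f"{condition_limit:g}: deep-layer coefficients are too close to "
            "zero for a well-defined inverse"
        )
    A.A_inv = np.linalg.inv(A.A)
    resid = np.abs(A.A @ A.A_inv - np.eye(A.n_layers)).max()
    if resid >= 1e-10:
        raise np.linalg.LinAlgError(f"inverse residual {resid:.2e} exceeds 1e-10")
    return A


def suggest_energy_pair(
    table: DepthResponseTable,
    E_min_feasible: float = 1.0,
    dominance: float = 0.80,
    deep_share_limit: float = 0.10,
) -> tuple[float, float]:
    """Recommend (E_low, E_high) from a measured depth-response table.

    E_low is the lowest feasible energy whose layer-1 share of the total
    stain signal is at least ``dominance``; E_high is the energy whose
    layer-2/layer-1 signal ratio is closest to one (the two layers then
    contribute about equally), restricted - when the table resolves more
    than two layers - to energies where layers below the second contribute
    at most ``deep_share_limit`` of the signal.  The restriction matters:
    a two-layer inversion treats any deeper-layer signal as stain in
    layers 1-2, so pushing E_high up until the ratio reaches exactly one
    would trade a balanced pair for depth leakage.
    """
    if table.energies.size < 2:
        raise ValueError("table must span at least two energies")
    if table.signal.shape[1] < 2:
        raise ValueError("table must resolve at least two layers")
    feasible = [m for m, E in enumerate(table.energies) if E >= E_min_feasible]
    if not feasible:
        raise ValueError("no tabulated energy is above the feasibility limit")
    E_low = None
    for m in feasible:
        if table.layer_share(m)[0] >= dominance:
            E_low = float(table.energies[m])
            break
    if E_low is None:
        raise ValueError(
            f"no feasible energy has a layer-1 signal share >= {dominance:.0%}; "
            "thinner layers or lower energies are required"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = table.signal[:, 1] / table.signal[:, 0]
    candidates = [
        m
        for m, E in enumerate(table.energies)
        if E > E_low and np.isfinite(ratio[m]) and table.signal[m, 0] > 0
    ]
    if not candidates:
        raise ValueError("no tabulated energy above E_low has a usable layer ratio")
    if table.signal.shape[1] > 2:
        shallow = [
            m
            for m in candidates
            if table.layer_share(m)[2:].sum() <= deep_share_limit
        ]
        candidates = shallow or candidates
    best = min(candidates, key=lambda m: abs(ratio[m] - 1.0))
    return E_low, float(table.energies[best])
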