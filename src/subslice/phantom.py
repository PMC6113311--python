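"""Voxelized specimen models: heavy-atom stain density grids in a resin block.

A phantom is a 3D grid of stain number density S (heavy atoms/nm^3) over a
uniform embedding resin.  The block surface is at z = 0, +z points into the
block, and voxel layer n spans [n*dz, (n+1)*dz).  Arrays are stored z-first
(``stain[z, y, x]``) to match image-stack conventions.

Two benchmark geometries are provided: a "ladder" of identical stained
cuboids at increasing depth (the depth-response calibration target) and a
three-cuboid sensitivity model (two full-density single-layer cuboids plus
one half-density cuboid spanning both layers, all with equal total stain).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .physics import ATOMIC_MASSES, Material, epon812

__all__ = [
    "NOMINAL_STAIN_DENSITY",
    "Cuboid",
    "VoxelPhantom",
    "at_percent_to_density",
    "make_block",
    "add_cuboid",
    "cuboid_ladder",
    "three_cuboid_model",
    "load_phantom",
]

#: Stain number density (Pb atoms/nm^3) corresponding to the nominal 3 at%
#: lead stain; used as the package-wide default so calibration and
#: reconstruction are expressed on one consistent density scale.
NOMINAL_STAIN_DENSITY = 3.24

_ALIGN_TOL = 1e-6


@dataclass(frozen=True)
class Cuboid:
    """Axis-aligned stained cuboid, positioned by center, sized in nm."""

    center: tuple[float, float, float]  # (x, y, z_c) nm
    dimensions: tuple[float, float, float]  # (wx, wy, wz) nm
    stain_density: float  # atoms/nm^3

    def __post_init__(self):
        if min(self.dimensions) <= 0:
            raise ValueError("cuboid dimensions must be positive")
        if self.stain_density < 0:
            raise ValueError("stain density must be nonnegative")

    @property
    def bounds(self) -> tuple[tuple[float, float], ...]:
        """((x0,x1), (y0,y1), (z0,z1)) in nm."""
        return tuple(
            (c - w / 2.0, c + w / 2.0) for c, w in zip(self.center, self.dimensions)
        )


@dataclass
class VoxelPhantom:
    """Stain-density grid S(z, y, x) over a uniform resin block."""

    stain: np.ndarray  # float32, shape (nz, ny, nx), atoms/nm^3
    voxel_nm: tuple[float, float, float]  # (dx, dy, dz)
    material: Material = field(default_factory=epon812)
    stain_Z: int = 82  # atomic number of the stain element
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.stain = np.asarray(self.stain, dtype=np.float32)
        if self.stain.ndim != 3:
            raise ValueError("stain grid must be 3D")
        if np.any(self.stain < 0):
            raise ValueError("stain density must be nonnegative everywhere")
        if min(self.voxel_nm) <= 0:
            raise ValueError("voxel sizes must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        """Grid shape as (nx, ny, nz)."""
        nz, ny, nx = self.stain.shape
        return (nx, ny, nz)

    @property
    def extent_nm(self) -> tuple[float, float, float]:
        nx, ny, nz = self.shape
        dx, dy, dz = self.voxel_nm
        return (nx * dx, ny * dy, nz * dz)

    def copy(self) -> "VoxelPhantom":
        return VoxelPhantom(
            stain=self.stain.copy(),
            voxel_nm=self.voxel_nm,
            material=self.material,
            stain_Z=self.stain_Z,
            meta=dict(self.meta),
        )

    def total_stain_atoms(self) -> float:
        """Total number of stain atoms in the block."""
        dx, dy, dz = self.voxel_nm
        return float(self.stain.sum(dtype=np.float64)) * dx * dy * dz

    def save(self, path: str | Path) -> None:
        """Write the grid as a multi-page float32 TIFF plus a JSON sidecar."""
        import tifffile

        path = Path(path)
        tifffile.imwrite(path, self.stain, photometric="minisblack")
        sidecar = {
            "voxel_nm": list(self.voxel_nm),
            "stain_Z": self.stain_Z,
            "material": {
                "name": self.material.name,
                "mass_density": self.material.mass_density,
                "composition": [
                    [el.Z, el.atomic_fraction] for el in self.material.elements
                ],
            },
            "meta": self.meta,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_phantom(path: str | Path) -> VoxelPhantom:
    """Read a phantom written by :meth:`VoxelPhantom.save` (lossless)."""
    import tifffile

    path = Path(path)
    stain = tifffile.imread(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    mat = sidecar["material"]
    material = Material.from_fractions(
        [(int(z), f) for z, f in mat["composition"]],
        mass_density=mat["mass_density"],
        name=mat.get("name", ""),
    )
    return VoxelPhantom(
        stain=stain,
        voxel_nm=tuple(sidecar["voxel_nm"]),
        material=material,
        stain_Z=int(sidecar["stain_Z"]),
        meta=sidecar.get("meta", {}),
    )


def at_percent_to_density(
    atomic_fraction: float,
    material: Material | None = None,
    convention: str = "added_to_matrix",
) -> float:
    """Convert a stain atomic fraction to a number density (atoms/nm^3).

    Conventions:

    - ``added_to_matrix``: stain atoms are added on top of the resin's atom
      count, ``n = f * n_resin`` with the resin at its own density.  For
      3 at% added to epoxy at 1.22 g/cm^3 this gives ~3.31 atoms/nm^3.
    - ``of_total_atoms``: the fraction refers to the total atom count of
      the mixture while the resin keeps its density,
      ``n = f/(1-f) * n_resin``.

    The package-wide default stain density used by the calibration is the
    nominal value :data:`NOMINAL_STAIN_DENSITY` = 3.24 atoms/nm^3, which sits
    between the two conventions evaluated for standard epoxy compositions.
    """
    if not (0.0 <= atomic_fraction < 0.5):
        raise ValueError("atomic fraction must lie in [0, 0.5)")
    if material is None:
        material = epon812()
    n_resin = material.total_number_density
    if convention == "added_to_matrix":
        return atomic_fraction * n_resin
    if convention == "of_total_atoms":
        return atomic_fraction / (1.0 - atomic_fraction) * n_resin
    raise ValueError(f"unknown convention {convention!r}")


def make_block(
    extent_nm: tuple[float, float, float],
    voxel_nm: tuple[float, float, float],
    material: Material | None = None,
) -> VoxelPhantom:
    """All-resin block with zero stain; extents must tile into whole voxels."""
    if material is None:
        material = epon812()
    shape_xyz = []
    for ext, dv in zip(extent_nm, voxel_nm):
        n = ext / dv
        if abs(n - round(n)) > _ALIGN_TOL * max(1.0, abs(n)):
            raise ValueError(
                f"extent {ext} nm is not an integer multiple of voxel {dv} nm"
            )
        shape_xyz.append(int(round(n)))
    nx, ny, nz = shape_xyz
    stain = np.zeros((nz, ny, nx), dtype=np.float32)
    return VoxelPhantom(
        stain=stain,
        voxel_nm=tuple(voxel_nm),
        material=material,
        meta={"extent_nm": list(extent_nm)},
    )


def _index_range(lo: float, hi: float, dv: float, n: int, snap: bool) -> tuple[int, int]:
    ilo, ihi = lo / dv, hi / dv
    if not snap:
        for v in (ilo, ihi):
            if abs(v - round(v)) > 1e-6:
                raise ValueError(
                    f"cuboid edge at {v * dv:g} nm is not aligned to the "
                    f"{dv:g} nm voxel grid (pass snap=True to snap)"
                )
    i0, i1 = int(round(ilo)), int(round(ihi))
    if i0 < 0 or i1 > n:
        raise ValueError("cuboid extends outside the block")
    return i0, i1


def add_cuboid(
    phantom: VoxelPhantom,
    cuboid: Cuboid,
    *,
    snap: bool = False,
    allow_overlap: bool = False,
) -> VoxelPhantom:
    """Stain the voxels inside a grid-aligned cuboid (in place; returns phantom).

    By default the cuboid faces must coincide with voxel boundaries and the
    target voxels must be unstained; ``snap`` rounds edges to the nearest
    boundary, ``allow_overlap`` permits overwriting stained voxels.
    """
    dx, dy, dz = phantom.voxel_nm
    nx, ny, nz = phantom.shape
    (x0, x1), (y0, y1), (z0, z1) = cuboid.bounds
    ix0, ix1 = _index_range(x0, x1, dx, nx, snap)
    iy0, iy1 = _index_range(y0, y1, dy, ny, snap)
    iz0, iz1 = _index_range(z0, z1, dz, nz, snap)
    region = phantom.stain[iz0:iz1, iy0:iy1, ix0:ix1]
    if cuboid.stain_density > 0 and not allow_overlap and np.any(region > 0):
        raise ValueError("cuboid overlaps an existing stained region")
    if cuboid.stain_density > 0:
        region[...] = cuboid.stain_density
    return phantom


def cuboid_ladder(
    n_cuboids: int = 8,
    cuboid_dims: tuple[float, float, float] = (50.0, 50.0, 12.5),
    x_spacing: float = 50.0,
    z_start: float = 6.25,
    z_step: float = 12.5,
    stain_density: float = NOMINAL_STAIN_DENSITY,
    block_extent: tuple[float, float, float] = (800.0, 800.0, 800.0),
    voxel_nm: tuple[float, float, float] = (12.5, 12.5, 12.5),
    material: Material | None = None,
) -> VoxelPhantom:
    """Ladder of identical stained cuboids at increasing depth.

    Cuboid k (k = 0..n-1) has center depth ``z_start + k*z_step``; cuboids
    are laid out along x at fixed y with ``x_spacing`` nm edge-to-edge gaps,
    centered laterally in the block.  Defaults give eight 50x50x12.5 nm
    cuboids with center depths 6.25 ... 93.75 nm in an 800 nm block.
    """
    if n_cuboids < 1:
        raise ValueError("need at least one cuboid")
    wx, wy, wz = cuboid_dims
    span_x = n_cuboids * wx + (n_cuboids - 1) * x_spacing
    X, Y, Z = block_extent
    if span_x > X:
        raise ValueError("ladder exceeds the block in x; enlarge the block")
    z_deepest = z_start + (n_cuboids - 1) * z_step + wz / 2.0
    if z_deepest > Z:
        raise ValueError("ladder exceeds the block in z")
    phantom = make_block(block_extent, voxel_nm, material)
    margin_x = (X - span_x) / 2.0
    y_c = Y / 2.0
    centers = []
    for k in range(n_cuboids):
        x_c = margin_x + k * (wx + x_spacing) + wx / 2.0
        z_c = z_start + k * z_step
        add_cuboid(phantom, Cuboid((x_c, y_c, z_c), cuboid_dims, stain_density))
        centers.append((x_c, y_c, z_c))
    phantom.meta.update(
        {
            "geometry": "cuboid_ladder",
            "cuboid_dims_nm": list(cuboid_dims),
            "cuboid_centers_nm": [list(c) for c in centers],
            "stain_density": stain_density,
        }
    )
    return phantom


def three_cuboid_model(
    cuboid_xy: float = 625.0,
    block_extent: tuple[float, float, float] | None = None,
    voxel_nm: tuple[float, float, float] = (12.5, 12.5, 12.5),
    stain_density: float = NOMINAL_STAIN_DENSITY,
    x_gap: float | None = None,
    material: Material | None = None,
) -> VoxelPhantom:
    """Three-cuboid sensitivity model with equal total stain per cuboid.

    Cuboid 1: full density, one voxel layer thick, centered at depth dz/2
    (sub-slice 1).  Cuboid 2: full density, centered at 3*dz/2 (sub-slice
    2).  Cuboid 3: half density, two layers thick, centered at dz (spans
    both sub-slices).  Cuboids are laid out along x with ``x_gap``
    edge-to-edge spacing (default: one cuboid width).

    The default lateral size (625 nm, 50 voxels at 12.5 nm) gives
    2,500 / 2,500 / 5,000 stained voxels inside a 10 um x 10 um x 10 um
    block; pass a smaller ``block_extent`` for compact runs (the block only
    needs to exceed the cuboid field by a few hundred nm of margin).
    """
    dx, dy, dz = voxel_nm
    if x_gap is None:
        x_gap = cuboid_xy
    if block_extent is None:
        block_extent = (10000.0, 10000.0, 10000.0)
    X, Y, Z = block_extent
    span_x = 3 * cuboid_xy + 2 * x_gap
    if span_x > X:
        raise ValueError("three-cuboid field exceeds the block in x")
    phantom = make_block(block_extent, voxel_nm, material)

    def _centered(v: float, dv: float) -> float:
        # center the field while keeping edges on the voxel grid
        return round(v / dv) * dv

    margin_x = _centered((X - span_x) / 2.0, dx)
    y_c = _centered((Y - cuboid_xy) / 2.0, dy) + cuboid_xy / 2.0
    specs = [
        (dz / 2.0, dz, stain_density),  # cuboid 1: layer 1
        (3.0 * dz / 2.0, dz, stain_density),  # cuboid 2: layer 2
        (dz, 2.0 * dz, stain_density / 2.0),  # cuboid 3: both layers, half S
    ]
    centers = []
    for k, (z_c, wz, s) in enumerate(specs):
        x_c = margin_x + k * (cuboid_xy + x_gap) + cuboid_xy / 2.0
        add_cuboid(phantom, Cuboid((x_c, y_c, z_c), (cuboid_xy, cuboid_xy, wz), s))
        centers.append((x_c, y_c, z_c))
    phantom.meta.update(
        {
            "geometry": "three_cuboid",
            "cuboid_xy_nm": cuboid_xy,
            "cuboid_centers_nm": [list(c) for c in centers],
            "stain_density": stain_density,
        }
    )
    return phantom
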