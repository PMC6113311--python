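"""Dual-energy stacks and the per-pixel sub-slice inversion.

Forward model per pixel and cut: ``B_m = J0_px * dz * sum_n A[m,n] S_n``
(stain-only counts; the uniform resin adds a constant per-energy
background).  Reconstruction inverts this per pixel:
``S = A^-1 eta / dz`` with ``eta = B / J0_px`` the background-subtracted
backscattering coefficient, interleaving the N recovered sub-slices of
each physical cut into a volume at dz spacing.

The operator order is enforced by state flags and mirrors the acquisition
pipeline: background subtraction -> low-to-high intensity scaling ->
per-pixel inversion -> noise clipping -> lower-sub-slice averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .calibration import ResponseMatrix, invert_response
from .montecarlo import BSEImage
from .phantom import VoxelPhantom

__all__ = [
    "DualEnergyStack",
    "SubSliceVolume",
    "forward_project",
    "apply_shot_noise",
    "subtract_background",
    "scale_low_to_high",
    "solve_subslices",
    "clip_noise",
    "smooth_lower_subslice",
    "evaluate_recovery",
]


@dataclass
class DualEnergyStack:
    """Per-cut pairs of BSE images at (E_low, E_high).

    ``counts[c, m]`` is the (ny, nx) image of cut c at energy index m
    (0 = low, 1 = high).  ``electrons_per_pixel[m]`` is the incident dose
    per pixel for energy m (the two doses differ in practice because dwell
    times are chosen per energy).
    """

    counts: np.ndarray  # (n_cuts, 2, ny, nx)
    energies: tuple[float, float]  # keV (low, high)
    electrons_per_pixel: tuple[float, float]
    pixel_nm: float
    cut_increment_nm: float
    background_subtracted: bool = False
    scaled: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 4 or self.counts.shape[1] != 2:
            raise ValueError("counts must have shape (n_cuts, 2, ny, nx)")
        if not self.energies[0] < self.energies[1]:
            raise ValueError("energies must be (low, high)")

    @property
    def n_cuts(self) -> int:
        return self.counts.shape[0]

    @property
    def eta(self) -> np.ndarray:
        """Backscattering coefficients: counts normalized by dose per energy."""
        J = np.asarray(self.electrons_per_pixel, dtype=float)
        return self.counts / J[None, :, None, None]

    def copy(self) -> "DualEnergyStack":
        out = DualEnergyStack(
            counts=self.counts.copy(),
            energies=self.energies,
            electrons_per_pixel=self.electrons_per_pixel,
            pixel_nm=self.pixel_nm,
            cut_increment_nm=self.cut_increment_nm,
            background_subtracted=self.background_subtracted,
            scaled=self.scaled,
            meta=dict(self.meta),
        )
        return out


@dataclass
class SubSliceVolume:
    """Recovered stain densities at sub-slice z-resolution.

    ``data[k]`` is the (ny, nx) density map of sub-slice k; sub-slices are
    stored surface-down, ``n_per_cut`` per physical cut, at ``dz`` spacing.
    """

    data: np.ndarray  # (n_sub, ny, nx), atoms/nm^3
    dz: float
    n_per_cut: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("volume must be 3D")
        if self.data.shape[0] % self.n_per_cut:
            raise ValueError("sub-slice count is not a whole number of cuts")

    @property
    def n_cuts(self) -> int:
        return self.data.shape[0] // self.n_per_cut

    def copy(self) -> "SubSliceVolume":
        return SubSliceVolume(
            self.data.copy(), self.dz, self.n_per_cut, dict(self.provenance)
        )


def stack_from_images(
    pairs: list[tuple[BSEImage, BSEImage]], cut_increment_nm: float
) -> DualEnergyStack:
    """Assemble simulated or loaded per-cut (low, high) image pairs into a
    dual-energy stack."""
    if not pairs:
        raise ValueError("need at least one cut")
    low0, high0 = pairs[0]
    counts = np.stack(
        [np.stack([np.asarray(lo.counts, float), np.asarray(hi.counts, float)])
         for lo, hi in pairs]
    )
    return DualEnergyStack(
        counts=counts,
        energies=(low0.energy_keV, high0.energy_keV),
        electrons_per_pixel=(low0.electrons_per_pixel, high0.electrons_per_pixel),
        pixel_nm=low0.pixel_nm,
        cut_increment_nm=cut_increment_nm,
        meta={"source": "simulate_image"},
    )


def forward_project(
    phantom: VoxelPhantom,
    A: ResponseMatrix,
    electrons_per_pixel=(1000, 1000),
    background_eta: tuple[float, float] = (0.0, 0.0),
) -> DualEnergyStack:
    """Noiseless expected dual-energy counts from a stain phantom.

    Per pixel and cut c: ``B_m = J0_px[m] * (dz * sum_n A[m,n] S[cN+n]
    + background_eta[m])``; the pixel grid coincides with the phantom's
    lateral voxel grid.  Cuts beyond the deepest complete group of N
    layers are dropped.
    """
    dz = A.dz
    dx, dy, dzp = phantom.voxel_nm
    if abs(dzp - dz) > 1e-9:
        raise ValueError("phantom voxel dz must equal the response-matrix dz")
    if abs(dx - dy) > 1e-9:
        raise ValueError("pixels must be square (dx == dy)")
    N = A.n_layers
    nz = phantom.stain.shape[0]
    n_cuts = nz // N
    if n_cuts < 1:
        raise ValueError("phantom too shallow for one cut of N sub-slices")
    S = phantom.stain[: n_cuts * N].reshape(n_cuts, N, *phantom.stain.shape[1:])
    J = np.asarray(electrons_per_pixel, dtype=float)
    # eta[c, m] = dz * sum_n A[m, n] S[c, n]
    eta = dz * np.einsum("mn,cnyx->cmyx", A.A, S.astype(float))
    eta = eta + np.asarray(background_eta, dtype=float)[None, :, None, None]
    counts = eta * J[None, :, None, None]
    return DualEnergyStack(
        counts=counts,
        energies=tuple(A.energies),
        electrons_per_pixel=tuple(J),
        pixel_nm=dx,
        cut_increment_nm=N * dz,
        background_subtracted=bool(
            background_eta[0] == 0.0 and background_eta[1] == 0.0
        ),
        scaled=True,  # simulated counts are already in consistent units
        meta={"source": "forward_project", "background_eta": list(background_eta)},
    )


def apply_shot_noise(
    stack: DualEnergyStack,
    rng: np.random.Generator,
    gaussian_sd: float = 0.0,
) -> DualEnergyStack:
    """Replace expected counts by Poisson draws (plus optional Gaussian
    detector noise with the given standard deviation in counts)."""
    if np.any(stack.counts < 0):
        raise ValueError("expected counts must be nonnegative before noising")
    out = stack.copy()
    out.counts = rng.poisson(stack.counts).astype(float)
    if gaussian_sd > 0:
        out.counts += rng.normal(0.0, gaussian_sd, out.counts.shape)
    out.background_subtracted = stack.background_subtracted
    out.meta["shot_noise"] = True
    return out


def subtract_background(
    image: BSEImage,
    method: str = "roi_mean",
    roi: tuple[slice, slice] | None = None,
    percentile: float | None = None,
) -> BSEImage:
    """Subtract a scalar background estimated from the image itself.

    ``roi_mean`` averages a stain-free region (``roi`` as (row-slice,
    col-slice)); ``percentile`` uses the given percentile of all pixels.
    The output may contain negatives; clipping happens later, on the
    reconstructed volume.
    """
    counts = np.asarray(image.counts, dtype=float)
    if method == "roi_mean":
        if roi is None:
            raise ValueError("roi_mean requires a roi")
        region = counts[roi]
        if region.size == 0:
            raise ValueError("empty background ROI")
        bg = float(region.mean())
    elif method == "percentile":
        if percentile is None or not (0.0 < percentile < 100.0):
            raise ValueError("percentile must lie in (0, 100)")
        bg = float(np.percentile(counts, percentile))
    else:
        raise ValueError(f"unknown background method {method!r}")
    return BSEImage(
        counts=counts - bg,
        energy_keV=image.energy_keV,
        electrons_per_pixel=image.electrons_per_pixel,
        pixel_nm=image.pixel_nm,
        meta={**image.meta, "background": bg, "background_method": method},
    )


def subtract_stack_background(
    stack: DualEnergyStack,
    method: str = "roi_mean",
    roi: tuple[slice, slice] | None = None,
    percentile: float | None = None,
) -> DualEnergyStack:
    """Apply :func:`subtract_background` to every image in a stack, one
    scalar background per (cut, energy)."""
    out = stack.copy()
    bgs = np.zeros(stack.counts.shape[:2])
    for c in range(stack.n_cuts):
        for m in range(2):
            img = BSEImage(
                counts=stack.counts[c, m],
                energy_keV=stack.energies[m],
                electrons_per_pixel=stack.electrons_per_pixel[m],
                pixel_nm=stack.pixel_nm,
            )
            sub = subtract_background(img, method, roi, percentile)
            out.counts[c, m] = sub.counts
            bgs[c, m] = sub.meta["background"]
    out.background_subtracted = True
    out.meta["backgrounds"] = bgs.tolist()
    return out


def scale_low_to_high(
    stack: DualEnergyStack,
    A: ResponseMatrix,
    homogeneous_roi: tuple[slice, slice],
) -> DualEnergyStack:
    """Put the E_low images on the same intensity scale as the E_high ones.

    For a structure extending homogeneously through all N sub-slices the
    physical intensity ratio low/high equals the response-matrix row-sum
    ratio r = sum_n A[1,n] / sum_n A[2,n]; the E_low images are multiplied
    so the ROI mean satisfies ``mean(low) = r * mean(high)`` in
    dose-normalized units.  On self-consistently simulated stacks the
    factor is ~1 by construction; on acquired data it absorbs detector
    gain differences between the two energy channels.
    """
    if not stack.background_subtracted:
        raise RuntimeError("subtract the background before scaling")
    r = A.scaling_ratio
    eta = stack.eta
    mean_low = float(eta[(slice(None), 0) + tuple(homogeneous_roi)].mean())
    mean_high = float(eta[(slice(None), 1) + tuple(homogeneous_roi)].mean())
    if abs(mean_low) < 1e-12 or abs(mean_high) < 1e-12:
        raise ValueError("homogeneous ROI mean is consistent with zero")
    factor = r * mean_high / mean_low
    out = stack.copy()
    out.counts[:, 0] *= factor
    out.scaled = True
    out.meta.update({"scale_factor": factor, "scaling_ratio": r})
    return out


def solve_subslices(
    stack: DualEnergyStack,
    A: ResponseMatrix,
    dz: float | None = None,
) -> SubSliceVolume:
    """Per-pixel inversion: ``S = A^-1 eta / dz`` for every cut.

    Requires a background-subtracted, scaled stack and an inverted matrix
    (the inverse is computed on the fly when absent).  Recovered sub-slice
    n of cut c lands at volume index ``c*N + n``.
    """
    if not stack.background_subtracted:
        raise RuntimeError("stack must be background-subtracted before inversion")
    if not stack.scaled:
        raise RuntimeError("stack must be intensity-scaled before inversion")
    if dz is None:
        dz = A.dz
    if A.A_inv is None:
        invert_response(A)
    if abs(stack.cut_increment_nm - A.n_layers * dz) > 1e-9:
        raise ValueError("cut increment does not equal N * dz of the matrix")
    eta = stack.eta  # (n_cuts, 2, ny, nx)
    S = np.einsum("nm,cmyx->cnyx", A.A_inv, eta) / dz
    n_cuts, N = S.shape[:2]
    data = S.reshape(n_cuts * N, *S.shape[2:])
    return SubSliceVolume(
        data=data,
        dz=dz,
        n_per_cut=N,
        provenance={
            "energies_keV": list(stack.energies),
            "electrons_per_pixel": list(stack.electrons_per_pixel),
            "A_nm2": A.A.tolist(),
            "scale_factor": stack.meta.get("scale_factor"),
        },
    )


def estimate_background_sd(
    volume: SubSliceVolume, roi: tuple[slice, slice] | None = None
) -> float:
    """Standard deviation of the stain-free background of a volume.

    With a stain-free ROI the sample SD of those voxels is used; otherwise
    a robust estimate from the negative tail (which can only be noise,
    since true densities are nonnegative): ``sd = median|negatives|/0.6745``.
    """
    if roi is not None:
        region = volume.data[(slice(None),) + tuple(roi)]
        if region.size == 0:
            raise ValueError("empty background ROI")
        return float(region.std())
    neg = volume.data[volume.data < 0]
    if neg.size < 10:
        return float(volume.data.std())
    return float(np.median(np.abs(neg)) / 0.6745)


def clip_noise(
    volume: SubSliceVolume,
    background_sd: float | None = None,
    roi: tuple[slice, slice] | None = None,
) -> SubSliceVolume:
    """Zero sub-threshold voxels: values below one background SD, and all
    negatives, are set to zero.  The clipped fraction is recorded."""
    sd = background_sd if background_sd is not None else estimate_background_sd(volume, roi)
    out = volume.copy()
    mask = out.data < sd
    out.data[mask] = 0.0
    out.provenance.update(
        {"clip_sd": sd, "clip_fraction": float(mask.mean())}
    )
    return out


def smooth_lower_subslice(volume: SubSliceVolume) -> SubSliceVolume:
    """Average each lower sub-slice with the mean of its neighboring upper
    sub-slices (the one above in the same cut and the one below in the
    next cut; the last cut has only the one above).

    Defined for two sub-slices per cut; reduces the noise variance of the
    lower sub-slice, which carries the larger inverse-matrix noise
    amplification.
    """
    if volume.n_per_cut != 2:
        raise ValueError("lower-sub-slice smoothing requires 2 sub-slices per cut")
    out = volume.copy()
    n_cuts = volume.n_cuts
    if n_cuts < 2:
        warnings.warn("fewer than 2 cuts: lower-sub-slice smoothing is a no-op",
                      stacklevel=2)
        return out
    data = volume.data
    for c in range(n_cuts):
        lower = data[2 * c + 1]
        uppers = [data[2 * c]]
        if c + 1 < n_cuts:
            uppers.append(data[2 * (c + 1)])
        out.data[2 * c + 1] = 0.5 * (lower + np.mean(uppers, axis=0))
    out.provenance["lower_subslice_smoothed"] = True
    return out


def evaluate_recovery(
    volume: SubSliceVolume,
    truth: VoxelPhantom,
    regions: dict[str, np.ndarray] | None = None,
) -> dict:
    """Compare a reconstruction against the generating phantom.

    Regions default to one mask per distinct planted density (plus the
    unstained background).  For each region the record holds the planted
    density, recovered mean/median, a histogram peak, and the separation
    of that peak from the background peak.
    """
    nz = volume.data.shape[0]
    truth_grid = truth.stain[:nz].astype(float)
    if truth_grid.shape != volume.data.shape:
        raise ValueError(
            f"volume shape {volume.data.shape} does not match truth {truth_grid.shape}"
        )
    if regions is None:
        regions = {}
        for v in np.unique(truth_grid):
            if v > 0:
                regions[f"density_{v:g}"] = truth_grid == v
    bg_mask = truth_grid == 0

    def _peak(values: np.ndarray) -> float:
        if values.size < 10 or np.ptp(values) <= 1e-12 * (1 + abs(values[0])):
            return float(np.median(values))
        hist, edges = np.histogram(values, bins=max(10, min(100, values.size // 20)))
        k = int(np.argmax(hist))
        return float(0.5 * (edges[k] + edges[k + 1]))

    bg_vals = volume.data[bg_mask]
    record: dict = {
        "background": {
            "n_voxels": int(bg_mask.sum()),
            "mean": float(bg_vals.mean()),
            "sd": float(bg_vals.std()),
            "peak": _peak(bg_vals),
        }
    }
    for name, mask in regions.items():
        vals = volume.data[mask]
        planted = float(truth_grid[mask].mean()) if mask.any() else 0.0
        record[name] = {
            "n_voxels": int(mask.sum()),
            "planted": planted,
            "mean": float(vals.mean()),
            "median": float(np.median(vals)),
            "peak": _peak(vals),
            "separation": _peak(vals) - record["background"]["peak"],
        }
    return record
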