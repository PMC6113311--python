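"""File formats: image stacks, sub-slice volumes, matrices, run configs.

Stacks travel as multi-page grayscale TIFF (or MRC when the optional
``mrcfile`` dependency is installed) with a JSON/YAML metadata sidecar;
acquisition order is alternating pages (low energy then high energy for
each cut), matching how dual-energy stacks come off the microscope.
Pixel data round-trip losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .calibration import ResponseMatrix
from .reconstruct import DualEnergyStack, SubSliceVolume

__all__ = [
    "interleave",
    "deinterleave",
    "write_stack",
    "read_stack",
    "write_volume",
    "read_volume",
    "save_response_matrix",
    "load_response_matrix",
]

REQUIRED_SIDECAR_FIELDS = (
    "energies_keV",
    "cut_increment_nm",
    "pixel_nm",
    "electrons_per_pixel",
)

PAGE_ORDER = "interleaved_low_first"


def interleave(low: np.ndarray, high: np.ndarray) -> np.ndarray:
    """Merge per-cut low/high image arrays (n_cuts, ny, nx) into the
    acquisition page order: low0, high0, low1, high1, ..."""
    if low.shape != high.shape:
        raise ValueError("low and high stacks must share a shape")
    pages = np.empty((2 * low.shape[0],) + low.shape[1:], dtype=low.dtype)
    pages[0::2] = low
    pages[1::2] = high
    return pages


def deinterleave(pages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`interleave`."""
    if pages.shape[0] % 2:
        raise ValueError("interleaved stack must have an even number of pages")
    return pages[0::2], pages[1::2]


def _write_pages(path: Path, pages: np.ndarray) -> None:
    if path.suffix.lower() == ".mrc":
        try:
            import mrcfile
        except ImportError as err:  # pragma: no cover - optional dependency
            raise ImportError(
                "MRC support requires the optional 'mrcfile' package; "
                "install subslice[mrc] or write TIFF instead"
            ) from err
        with mrcfile.new(str(path), overwrite=True) as f:
            f.set_data(pages.astype(np.float32))
    else:
        import tifffile

        tifffile.imwrite(path, pages, photometric="minisblack")


def _read_pages(path: Path) -> np.ndarray:
    if path.suffix.lower() == ".mrc":
        try:
            import mrcfile
        except ImportError as err:  # pragma: no cover - optional dependency
            raise ImportError(
                "MRC support requires the optional 'mrcfile' package"
            ) from err
        with mrcfile.open(str(path)) as f:
            return np.asarray(f.data)
    import tifffile

    return tifffile.imread(path)


def _sidecar_path(path: Path, sidecar: str | Path | None) -> Path:
    return Path(sidecar) if sidecar is not None else path.with_suffix(".json")


def _load_sidecar(path: Path) -> dict:
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        return yaml.safe_load(text)
    return json.loads(text)


def write_stack(
    stack: DualEnergyStack, path: str | Path, sidecar: str | Path | None = None
) -> Path:
    """Write a dual-energy stack as interleaved pages plus a sidecar."""
    path = Path(path)
    pages = interleave(stack.counts[:, 0].astype(np.float32),
                       stack.counts[:, 1].astype(np.float32))
    _write_pages(path, pages)
    meta = {
        "page_order": PAGE_ORDER,
        "energies_keV": list(stack.energies),
        "cut_increment_nm": stack.cut_increment_nm,
        "pixel_nm": stack.pixel_nm,
        "electrons_per_pixel": list(stack.electrons_per_pixel),
        "background_subtracted": stack.background_subtracted,
        "scaled": stack.scaled,
        "meta": _jsonable(stack.meta),
    }
    sc = _sidecar_path(path, sidecar)
    sc.write_text(json.dumps(meta, indent=1))
    return path


def read_stack(path: str | Path, sidecar: str | Path | None = None) -> DualEnergyStack:
    """Read a stack written by :func:`write_stack` (or acquired data laid
    out the same way).  Missing sidecar fields raise a validation error
    naming every absent field."""
    path = Path(path)
    sc = _sidecar_path(path, sidecar)
    if not sc.exists():
        raise FileNotFoundError(f"metadata sidecar not found: {sc}")
    meta = _load_sidecar(sc)
    missing = [k for k in REQUIRED_SIDECAR_FIELDS if k not in meta]
    if missing:
        raise ValueError(f"sidecar {sc} is missing required fields: {missing}")
    order = meta.get("page_order", PAGE_ORDER)
    if order != PAGE_ORDER:
        raise ValueError(f"unsupported page order {order!r}")
    pages = _read_pages(path)
    if pages.ndim == 2:
        pages = pages[None]
    low, high = deinterleave(pages)
    counts = np.stack([low, high], axis=1).astype(float)
    return DualEnergyStack(
        counts=counts,
        energies=tuple(meta["energies_keV"]),
        electrons_per_pixel=tuple(meta["electrons_per_pixel"]),
        pixel_nm=meta["pixel_nm"],
        cut_increment_nm=meta["cut_increment_nm"],
        background_subtracted=bool(meta.get("background_subtracted", False)),
        scaled=bool(meta.get("scaled", False)),
        meta=meta.get("meta", {}),
    )


def write_volume(volume: SubSliceVolume, path: str | Path) -> Path:
    """Write a sub-slice volume (pages = sub-slices, surface first) plus a
    provenance sidecar."""
    path = Path(path)
    _write_pages(path, volume.data.astype(np.float32))
    meta = {
        "dz_nm": volume.dz,
        "n_per_cut": volume.n_per_cut,
        "provenance": _jsonable(volume.provenance),
    }
    _sidecar_path(path, None).write_text(json.dumps(meta, indent=1))
    return path


def read_volume(path: str | Path) -> SubSliceVolume:
    path = Path(path)
    meta = _load_sidecar(_sidecar_path(path, None))
    data = _read_pages(path)
    return SubSliceVolume(
        data=np.asarray(data, dtype=float),
        dz=meta["dz_nm"],
        n_per_cut=meta["n_per_cut"],
        provenance=meta.get("provenance", {}),
    )


def save_response_matrix(A: ResponseMatrix, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(A.to_dict(), indent=1))
    return path


def load_response_matrix(path: str | Path) -> ResponseMatrix:
    return ResponseMatrix.from_dict(json.loads(Path(path).read_text()))


def _jsonable(obj):
    """Best-effort conversion of metadata values to JSON-safe types."""
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
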