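"""Segmented voxel volumes: data model, I/O and synthetic phantom generation.

A segmented volume is the discretized sample model produced by tomographic
reconstruction and (upstream, manual) segmentation: a 3D grid of small integer
labels, one per voxel, where label 0 is vacuum/background and further labels
name the sample materials (crystal, mother liquor, loop, aggregate, ...).

Conventions used throughout the package
---------------------------------------
* Array axis order is ``labels[z, y, x]`` with ``z`` the tomography rotation
  axis.  Model-frame Cartesian coordinates are right-handed ``(x, y, z)`` in
  micrometres with the origin at the geometric centre of the grid; voxel
  ``(iz, iy, ix)`` has its centre at
  ``((ix + 0.5 - nx/2) h, (iy + 0.5 - ny/2) h, (iz + 0.5 - nz/2) h)``
  for voxel edge ``h``.
* Voxels are isotropic (a single edge length in µm).
* Shape generators use voxel-centre membership: a voxel carries the material
  label iff its centre lies strictly inside the ideal solid.

On-disk format: a multi-page 8-bit grayscale TIFF stack (or a raw ``.npy``
integer array) plus a JSON sidecar ``{voxel_size_um, label_names, axis_order}``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile

__all__ = [
    "SegmentedVolume",
    "MaterialCoefficients",
    "Placement",
    "read_volume",
    "write_volume",
    "generate_shape",
    "generate_composite_sample",
]

_AXIS_ORDER = "zyx"


@dataclass
class SegmentedVolume:
    """A labelled 3D voxel grid with isotropic voxel size.

    Parameters
    ----------
    labels
        3D integer array, axis order ``(z, y, x)``.  Values must all appear as
        keys of `label_names`; 0 is reserved for vacuum/background.
    voxel_size_um
        Edge length of the (isotropic) cubic voxel, µm.
    label_names
        Mapping label value -> material name.  Must contain 0 ("vacuum" by
        convention).  A label named ``"crystal"`` marks the diffracting
        material.
    """

    labels: np.ndarray
    voxel_size_um: float
    label_names: Mapping[int, str] = field(default_factory=lambda: {0: "vacuum"})

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 3 or min(arr.shape) < 1:
            raise ValueError(f"labels must be a non-empty 3D array, got shape {arr.shape}")
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError(f"labels must be integer-valued, got dtype {arr.dtype}")
        if arr.min() < 0:
            raise ValueError("negative voxel labels are not allowed")
        if arr.max() > 255:
            raise ValueError("labels above 255 are not supported")
        self.labels = arr
        self.label_names = {int(k): str(v) for k, v in dict(self.label_names).items()}
        if 0 not in self.label_names:
            self.label_names[0] = "vacuum"
        present = set(np.unique(arr).tolist())
        unknown = present - set(self.label_names)
        if unknown:
            raise ValueError(
                f"voxel labels {sorted(unknown)} missing from label_names "
                f"{sorted(self.label_names)}"
            )
        self.voxel_size_um = float(self.voxel_size_um)
        if not self.voxel_size_um > 0:
            raise ValueError("voxel_size_um must be positive")
        self._labels_u8: np.ndarray | None = None

    # -- derived views ------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.labels.shape)  # type: ignore[return-value]

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical grid extent ``(Lz, Ly, Lx)`` in µm."""
        nz, ny, nx = self.labels.shape
        h = self.voxel_size_um
        return (nz * h, ny * h, nx * h)

    @property
    def crystal_label(self) -> int:
        """Label whose name is ``"crystal"`` (case-insensitive)."""
        for lab, name in self.label_names.items():
            if name.lower() == "crystal":
                return lab
        raise KeyError(
            "volume has no material named 'crystal'; a crystal label is required "
            "for diffraction correction"
        )

    @property
    def max_label(self) -> int:
        return int(max(self.label_names))

    def labels_u8(self) -> np.ndarray:
        """Contiguous uint8 view of the label grid (cached, for the kernels)."""
        if self._labels_u8 is None:
            self._labels_u8 = np.ascontiguousarray(self.labels, dtype=np.uint8)
        return self._labels_u8

    def voxel_center_um(self, indices: np.ndarray) -> np.ndarray:
        """Model-frame ``(x, y, z)`` centres (µm) of voxels given as ``(n, 3)``
        array-order ``(iz, iy, ix)`` index triples."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        nz, ny, nx = self.labels.shape
        h = self.voxel_size_um
        out = np.empty_like(idx)
        out[:, 0] = (idx[:, 2] + 0.5 - nx / 2.0) * h
        out[:, 1] = (idx[:, 1] + 0.5 - ny / 2.0) * h
        out[:, 2] = (idx[:, 0] + 0.5 - nz / 2.0) * h
        return out

    def point_to_grid(self, xyz_um: np.ndarray) -> np.ndarray:
        """Convert model-frame ``(x, y, z)`` µm points to continuous array-order
        ``(z, y, x)`` coordinates in voxel units (voxel ``i`` spans ``[i, i+1)``)."""
        p = np.atleast_2d(np.asarray(xyz_um, dtype=float))
        nz, ny, nx = self.labels.shape
        h = self.voxel_size_um
        out = np.empty_like(p)
        out[:, 0] = p[:, 2] / h + nz / 2.0
        out[:, 1] = p[:, 1] / h + ny / 2.0
        out[:, 2] = p[:, 0] / h + nx / 2.0
        return out

    def count(self, label: int) -> int:
        return int(np.count_nonzero(self.labels == label))


@dataclass
class MaterialCoefficients:
    """Linear absorption coefficients per material label, in µm⁻¹.

    ``mu[0]`` (vacuum) is always 0; a missing vacuum entry is added.  The
    optional ``wavelength_A`` tags the wavelength the coefficients refer to and
    enables the cubic-wavelength rescaling `rescaled_to_wavelength`.
    """

    mu: Mapping[int, float]
    wavelength_A: float | None = None

    def __post_init__(self) -> None:
        mu = {int(k): float(v) for k, v in dict(self.mu).items()}
        mu.setdefault(0, 0.0)
        if mu[0] != 0.0:
            raise ValueError("mu[0] (vacuum) must be exactly 0")
        for lab, val in mu.items():
            if val < 0 or not math.isfinite(val):
                raise ValueError(f"mu[{lab}] = {val} must be finite and >= 0")
        self.mu = mu
        if self.wavelength_A is not None:
            self.wavelength_A = float(self.wavelength_A)
            if not self.wavelength_A > 0:
                raise ValueError("wavelength_A must be positive")

    def mu_array(self, max_label: int, fill: float = math.nan) -> np.ndarray:
        """Vector of coefficients indexed by label, ``fill`` for unknown labels."""
        out = np.full(max_label + 1, fill, dtype=float)
        for lab, val in self.mu.items():
            if lab <= max_label:
                out[lab] = val
        return out

    def rescaled_to_wavelength(self, wavelength_A: float) -> "MaterialCoefficients":
        """Coefficients extrapolated to another wavelength via the cubic law.

        Away from absorption edges the linear absorption coefficient scales
        approximately as the cube of the wavelength, so
        ``mu' = mu * (lambda' / lambda)**3``.
        """
        if self.wavelength_A is None:
            raise ValueError("cannot rescale: wavelength_A is not set")
        ratio = (float(wavelength_A) / self.wavelength_A) ** 3
        return MaterialCoefficients(
            {lab: val * ratio for lab, val in self.mu.items()},
            wavelength_A=float(wavelength_A),
        )


# ---------------------------------------------------------------------------
# I/O: label stack + JSON sidecar
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_volume(vol: SegmentedVolume, path: str | Path) -> None:
    """Write a volume as a TIFF stack (``.tif``/``.tiff``) or raw ``.npy`` array,
    with a JSON sidecar carrying voxel size, label names and axis order.

    The round trip ``read_volume(write_volume(vol))`` is lossless for labels
    and metadata.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, vol.labels.astype(np.uint8))
    elif suffix == ".npy":
        np.save(path, vol.labels)
    else:
        raise ValueError(f"unsupported volume format '{suffix}' (use .tif/.tiff/.npy)")
    sidecar = {
        "voxel_size_um": vol.voxel_size_um,
        "label_names": {str(k): v for k, v in vol.label_names.items()},
        "axis_order": _AXIS_ORDER,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_volume(path: str | Path, sidecar: str | Path | None = None) -> SegmentedVolume:
    """Read a volume written by `write_volume` (TIFF stack or ``.npy`` + sidecar)."""
    path = Path(path)
    sidecar_path = Path(sidecar) if sidecar is not None else _sidecar_path(path)
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar descriptor {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    for key in ("voxel_size_um", "label_names"):
        if key not in meta:
            raise ValueError(f"sidecar {sidecar_path} missing required field '{key}'")
    if meta.get("axis_order", _AXIS_ORDER) != _AXIS_ORDER:
        raise ValueError(f"unsupported axis_order {meta.get('axis_order')!r}")

    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    elif suffix == ".npy":
        arr = np.load(path)
    else:
        raise ValueError(f"unsupported volume format '{suffix}'")
    arr = np.asarray(arr)
    if arr.ndim == 2:  # single-page stack
        arr = arr[None, ...]
    if not np.issubdtype(arr.dtype, np.integer):
        if np.issubdtype(arr.dtype, np.floating) and np.all(arr == np.round(arr)):
            arr = arr.astype(np.uint8)
        else:
            raise ValueError("volume pixel values are not integers")
    names = {int(k): str(v) for k, v in meta["label_names"].items()}
    return SegmentedVolume(arr, float(meta["voxel_size_um"]), names)


# ---------------------------------------------------------------------------
# Synthetic phantoms
# ---------------------------------------------------------------------------

def _centered_coords(n: int, h: float) -> np.ndarray:
    # voxel-centre coordinates relative to the grid centre
    return (np.arange(n) + 0.5 - n / 2.0) * h


def generate_shape(
    shape: str,
    size_um: float,
    voxel_size_um: float,
    label: int = 1,
    *,
    height_um: float | None = None,
    pad_voxels: int = 1,
    label_name: str = "crystal",
) -> SegmentedVolume:
    """Voxelize an ideal solid consisting of crystal material only.

    Parameters
    ----------
    shape
        ``"cube"``, ``"cylinder"`` or ``"sphere"``.
    size_um
        Characteristic dimension: the full edge for a cube, the *radius* for a
        sphere or cylinder.
    voxel_size_um
        Isotropic voxel edge, µm.
    height_um
        Cylinder height (axis along z); defaults to the diameter.
    pad_voxels
        Vacuum padding added on every face (≥ 1 so rays always exit into
        vacuum before leaving the grid).

    A voxel is labelled iff its centre lies strictly inside the ideal solid.
    """
    if size_um <= 0 or voxel_size_um <= 0:
        raise ValueError("sizes must be positive")
    if size_um < 2 * voxel_size_um:
        raise ValueError("shape must span at least two voxels")
    if pad_voxels < 1:
        raise ValueError("pad_voxels must be >= 1")
    h = float(voxel_size_um)
    names = {0: "vacuum", int(label): label_name}

    if shape == "cube":
        n = round(size_um / h)
        ntot = n + 2 * pad_voxels
        c = _centered_coords(ntot, h)
        inside1d = np.abs(c) < size_um / 2.0
        mask = inside1d[:, None, None] & inside1d[None, :, None] & inside1d[None, None, :]
    elif shape == "sphere":
        r = size_um
        n = math.ceil(2 * r / h)
        ntot = n + 2 * pad_voxels
        c = _centered_coords(ntot, h)
        mask = (c[:, None, None] ** 2 + c[None, :, None] ** 2 + c[None, None, :] ** 2) < r * r
    elif shape == "cylinder":
        r = size_um
        hgt = float(height_um) if height_um is not None else 2 * r
        if hgt <= 0:
            raise ValueError("height_um must be positive")
        nxy = math.ceil(2 * r / h) + 2 * pad_voxels
        nz = math.ceil(hgt / h) + 2 * pad_voxels
        cz = _centered_coords(nz, h)
        cxy = _centered_coords(nxy, h)
        radial = (cxy[:, None] ** 2 + cxy[None, :] ** 2) < r * r
        axial = np.abs(cz) < hgt / 2.0
        mask = axial[:, None, None] & radial[None, :, :]
    else:
        raise ValueError(f"unknown shape {shape!r} (use cube/cylinder/sphere)")

    labels = np.where(mask, np.uint8(label), np.uint8(0))
    return SegmentedVolume(labels, h, names)


@dataclass(frozen=True)
class Placement:
    """One solid to paint into a composite sample.

    ``kind`` is ``"sphere"`` (``size_um`` = radius), ``"cylinder"``
    (``size_um`` = radius, ``height_um``, axis along z) or ``"box"``
    (``dims_um`` = full edge lengths ``(x, y, z)``).  ``center_um`` places the
    solid's centre in model-frame coordinates.  Later placements overwrite
    earlier labels.
    """

    kind: str
    label: int
    center_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    size_um: float | None = None
    height_um: float | None = None
    dims_um: tuple[float, float, float] | None = None


def generate_composite_sample(
    entries: Sequence[Placement],
    grid_shape: tuple[int, int, int],
    voxel_size_um: float,
    label_names: Mapping[int, str],
) -> SegmentedVolume:
    """Paint a list of placed solids into a fresh vacuum grid.

    Deterministic: entries are applied in order and later entries overwrite
    earlier labels where they overlap (e.g. a crystal painted inside a larger
    liquor drop).  Raises if any solid extends outside the grid.
    """
    nz, ny, nx = grid_shape
    h = float(voxel_size_um)
    labels = np.zeros(grid_shape, dtype=np.uint8)
    cz = _centered_coords(nz, h)[:, None, None]
    cy = _centered_coords(ny, h)[None, :, None]
    cx = _centered_coords(nx, h)[None, None, :]
    half_ext = np.array([nx, ny, nz]) * h / 2.0

    for ent in entries:
        x0, y0, z0 = ent.center_um
        if ent.kind == "sphere":
            if ent.size_um is None:
                raise ValueError("sphere placement needs size_um (radius)")
            reach = np.array([ent.size_um] * 3)
            mask = ((cx - x0) ** 2 + (cy - y0) ** 2 + (cz - z0) ** 2) < ent.size_um**2
        elif ent.kind == "cylinder":
            if ent.size_um is None or ent.height_um is None:
                raise ValueError("cylinder placement needs size_um (radius) and height_um")
            reach = np.array([ent.size_um, ent.size_um, ent.height_um / 2.0])
            mask = (((cx - x0) ** 2 + (cy - y0) ** 2) < ent.size_um**2) & (
                np.abs(cz - z0) < ent.height_um / 2.0
            )
        elif ent.kind == "box":
            if ent.dims_um is None:
                raise ValueError("box placement needs dims_um")
            dx, dy, dz = ent.dims_um
            reach = np.array([dx, dy, dz]) / 2.0
            mask = (
                (np.abs(cx - x0) < dx / 2.0)
                & (np.abs(cy - y0) < dy / 2.0)
                & (np.abs(cz - z0) < dz / 2.0)
            )
        else:
            raise ValueError(f"unknown placement kind {ent.kind!r}")
        center = np.array([x0, y0, z0])
        if np.any(np.abs(center) + reach > half_ext + 1e-9):
            raise ValueError(f"placement {ent} extends outside the grid")
        labels[mask] = np.uint8(ent.label)

    names = {0: "vacuum", **{int(k): str(v) for k, v in dict(label_names).items()}}
    return SegmentedVolume(labels, h, names)
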