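"""Estimation of linear absorption coefficients from projection images.

Flat-field-corrected projection images give, pixel by pixel, the ratio of
transmitted to incident intensity.  Combined with per-material path-length
images obtained by forward-projecting the segmented model along the same
viewing direction, Beer-Lambert's law yields a per-pixel coefficient
estimate; the material coefficient is the median over a robustly selected
pixel set:

* pixels near material boundaries (phase-contrast fringes in propagation-based
  imaging) are excluded by morphological shrinking of the material mask;
* for the mother liquor, only solvent-only pixels with the 50% longest chords
  are used (long chords give the best-conditioned estimates);
* once the liquor coefficient is known, the coefficients of materials that
  only ever appear together with known materials (crystal, aggregate, ...)
  follow by subtracting the known contributions from the optical depth.

Loop coefficients are normally supplied from a per-beamline library rather
than estimated (empty-loop tomography is upstream of this package).

Projection geometry: parallel beam along +x at stage angle 0, rotation axis
z.  At stage angle theta the sample is rotated by +theta about z, which is
implemented by rotating the ray direction by -theta in the static model
frame.  Detector rows are z slices, columns the in-plane transverse
coordinate, pixel pitch equal to the voxel size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .raytrace import trace_from_points
from .volume import MaterialCoefficients, SegmentedVolume

__all__ = [
    "ProjectionImage",
    "InsufficientPixelsError",
    "forward_project",
    "exclude_phase_contrast",
    "estimate_liquor_mu",
    "estimate_material_mu",
    "synthesize_projection",
]

DEFAULT_SHRINK_PX = 3


class InsufficientPixelsError(ValueError):
    """No qualifying pixels survive masking/erosion for a coefficient estimate."""


@dataclass
class ProjectionImage:
    """A flat-field-corrected transmission image at one stage angle.

    ``transmission`` holds I/I0 per pixel (ideally in (0, 1]; values slightly
    above 1 occur where phase contrast or noise dominates and are tolerated —
    they are excluded from estimation by the masks).
    """

    transmission: np.ndarray
    pixel_size_um: float
    rotation_angle_deg: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.transmission, dtype=float)
        if arr.ndim != 2:
            raise ValueError("transmission must be a 2D image")
        if not np.isfinite(arr).all():
            raise ValueError("transmission contains non-finite values")
        self.transmission = arr
        self.pixel_size_um = float(self.pixel_size_um)
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")


def _projection_geometry(vol: SegmentedVolume, angle_deg: float):
    """Ray starts (grid units), direction (xyz) and image shape for one angle."""
    nz, ny, nx = vol.labels.shape
    h = vol.voxel_size_um
    theta = math.radians(angle_deg)
    # sample rotated by +theta about z  <=>  rays rotated by -theta
    d = np.array([math.cos(theta), -math.sin(theta), 0.0])
    u = np.array([math.sin(theta), math.cos(theta), 0.0])  # detector column axis
    # snap residual ~1e-17 components at multiples of 90 deg to exact zero so
    # axis-aligned views do not crawl along voxel boundaries
    for vec in (d, u):
        vec[np.abs(vec) < 1e-12] = 0.0
        vec /= np.linalg.norm(vec)
    ncols = math.ceil(math.hypot(nx, ny)) + 2
    back = (math.hypot(nx, ny) / 2.0 + 2.0) * h  # start upstream of the grid

    rows = (np.arange(nz) + 0.5 - nz / 2.0) * h
    cols = (np.arange(ncols) + 0.5 - ncols / 2.0) * h
    cc, rr = np.meshgrid(cols, rows)  # (nz, ncols)
    starts_xyz = np.empty((nz * ncols, 3))
    starts_xyz[:, 0] = (cc * u[0] - back * d[0]).ravel()
    starts_xyz[:, 1] = (cc * u[1] - back * d[1]).ravel()
    starts_xyz[:, 2] = rr.ravel()
    return vol.point_to_grid(starts_xyz), d, (nz, ncols)


def forward_project(vol: SegmentedVolume, angle_deg: float = 0.0) -> dict[int, np.ndarray]:
    """Parallel-beam line integrals of every material label.

    Returns one image per label (including vacuum) whose pixel value is the
    path length (µm) of that material along the ray hitting that pixel,
    computed with the exact voxel ray tracer.  The per-pixel sum over labels
    equals the total chord through the grid bounding box.
    """
    starts, d, shape = _projection_geometry(vol, angle_deg)
    lengths = trace_from_points(vol, starts, d)  # (npix, nlab)
    return {lab: lengths[:, lab].reshape(shape) for lab in range(lengths.shape[1])}


def exclude_phase_contrast(mask: np.ndarray, shrink_px: int) -> np.ndarray:
    """Morphological shrinking of an in-material pixel mask.

    Binary erosion with a square structuring element of radius ``shrink_px``
    removes the boundary band where propagation-based phase contrast distorts
    transmission values.  ``shrink_px = 0`` is the identity; the result is
    always a subset of the input.
    """
    mask = np.asarray(mask, dtype=bool)
    if shrink_px < 0:
        raise ValueError("shrink_px must be >= 0")
    if shrink_px == 0:
        return mask.copy()
    structure = np.ones((2 * shrink_px + 1, 2 * shrink_px + 1), dtype=bool)
    return ndimage.binary_erosion(mask, structure=structure)


def _solvent_only_mask(liquor_path: np.ndarray, other_paths) -> np.ndarray:
    mask = np.asarray(liquor_path) > 0.0
    for other in other_paths:
        mask &= np.asarray(other) <= 0.0
    return mask


def estimate_liquor_mu(
    proj: ProjectionImage,
    liquor_path_img: np.ndarray,
    other_paths,
    shrink_px: int = DEFAULT_SHRINK_PX,
) -> float:
    """Mother-liquor coefficient from solvent-only pixels.

    Pixels where only solvent is in the beam (positive liquor chord, zero
    chord through every other material) survive phase-contrast erosion; of
    those, the ones with the 50% longest liquor chords are kept.
    Beer-Lambert is applied per pixel, ``mu = -ln(T) / L``, and the estimate
    is the median — robust to residual fringes and outliers.

    ``other_paths`` is an iterable of the path-length images of every
    non-vacuum, non-liquor material.
    """
    mask = _solvent_only_mask(liquor_path_img, other_paths)
    mask = exclude_phase_contrast(mask, shrink_px)
    if not mask.any():
        raise InsufficientPixelsError("no solvent-only pixels survive erosion")
    lengths = np.asarray(liquor_path_img)[mask]
    threshold = np.percentile(lengths, 50.0)
    keep = lengths >= threshold  # ties included
    lengths = lengths[keep]
    trans = proj.transmission[mask][keep]
    if np.any(trans <= 0.0):
        raise ValueError("non-positive transmission among selected solvent pixels")
    return float(np.median(-np.log(trans) / lengths))


def estimate_material_mu(
    proj: ProjectionImage,
    target_label: int,
    known_mus: MaterialCoefficients,
    path_imgs: dict[int, np.ndarray],
    shrink_px: int = DEFAULT_SHRINK_PX,
) -> float:
    """Coefficient of one more material, given the already-known ones.

    Qualifying pixels have a positive chord through the target material while
    every *other* material with a positive chord already has a known
    coefficient.  Per pixel,

        mu_target = (-ln T - sum_known mu_m L_m) / L_target,

    and the estimate is the median over the eroded qualifying set.  A
    negative *median* numerator flags inconsistent inputs (isolated negative
    numerators are expected under noise for short chords and are tolerated).
    """
    if target_label not in path_imgs:
        raise KeyError(f"no path image for target label {target_label}")
    target_path = np.asarray(path_imgs[target_label], dtype=float)
    if not (target_path > 0.0).any():
        raise InsufficientPixelsError(f"target label {target_label} is never in the beam")

    mask = target_path > 0.0
    for lab, img in path_imgs.items():
        if lab == target_label or lab == 0:
            continue
        if lab not in known_mus.mu:
            mask &= np.asarray(img) <= 0.0  # unknown material in the beam: pixel unusable
    mask = exclude_phase_contrast(mask, shrink_px)
    if not mask.any():
        raise InsufficientPixelsError(
            f"no qualifying pixels for target label {target_label} after erosion"
        )

    trans = proj.transmission[mask]
    if np.any(trans <= 0.0):
        raise ValueError("non-positive transmission among selected pixels")
    numerator = -np.log(trans)
    for lab, img in path_imgs.items():
        if lab in (0, target_label):
            continue
        if lab in known_mus.mu:
            numerator -= known_mus.mu[lab] * np.asarray(img, dtype=float)[mask]
    values = numerator / target_path[mask]
    med = float(np.median(values))
    if med < 0.0:
        raise ValueError(
            f"median numerator negative for label {target_label}: known coefficients "
            "and transmissions are inconsistent"
        )
    return med


def synthesize_projection(
    vol: SegmentedVolume,
    coeffs: MaterialCoefficients,
    angle_deg: float = 0.0,
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> ProjectionImage:
    """Generate an ideal (optionally noisy) transmission image from the model.

    Inverts the estimation pipeline: ``T = exp(-sum_m mu_m L_m)`` per pixel,
    with the same forward projector used for estimation, plus optional
    multiplicative Gaussian noise ``T * (1 + sigma * N(0, 1))`` emulating
    flat-field-corrected counting noise.  Deterministic given ``seed``.
    """
    paths = forward_project(vol, angle_deg)
    depth = np.zeros(next(iter(paths.values())).shape, dtype=float)
    for lab, img in paths.items():
        if lab == 0:
            continue
        if lab not in coeffs.mu:
            if img.any():
                raise KeyError(f"no coefficient for label {lab}")
            continue
        depth += coeffs.mu[lab] * img
    trans = np.exp(-depth)
    if noise_sigma > 0.0:
        rng = np.random.default_rng(seed)
        trans = trans * (1.0 + noise_sigma * rng.standard_normal(trans.shape))
        trans = np.clip(trans, 1e-12, None)
    return ProjectionImage(trans, vol.voxel_size_um, angle_deg)
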