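"""Goniometer and beam geometry.

The diffraction experiment rotates the sample on a multi-axis (kappa)
goniometer while the tomographic model is acquired at a single fixed setting
(kappa = 0, phi = 0).  Rather than rotating the whole voxel model for every
reflection, the incident and diffracted beam directions are rotated *into* the
model frame by the inverse of the composed goniometer matrix; the ray tracer
then works on the static volume.

Lab frame (defaults, configurable)
----------------------------------
* Beam propagates along +z.
* Scan (omega) axis is the vertical +y axis.
* Kappa axis is tilted 50 degrees from the omega axis in the y-z plane,
  phi axis is parallel to omega at kappa = 0 (a generic kappa geometry).
* Rotations are active, right-handed; the composed setting matrix is
  ``M = R_omega @ R_kappa @ R_phi`` (outermost scan rotation, innermost phi),
  so the model-frame direction of a lab vector v is ``M.T @ v``.

Angles are degrees at every interface, radians internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Reflection",
    "GoniometerModel",
    "BeamModel",
    "rotation_about_axis",
    "beam_vectors_in_model_frame",
    "beam_footprint_test",
]

_UNIT_TOL = 1e-6


def _as_unit(v, name: str, tol: float = _UNIT_TOL) -> np.ndarray:
    v = np.asarray(v, dtype=float).reshape(3)
    n = float(np.linalg.norm(v))
    if n == 0.0:
        raise ValueError(f"{name} must be a non-zero vector")
    if abs(n - 1.0) > tol:
        raise ValueError(f"{name} must be unit length (|v| = {n:.9g})")
    return v / n


def rotation_about_axis(axis, angle_deg: float) -> np.ndarray:
    """Proper rotation matrix for a right-handed rotation about ``axis``.

    The axis must be (close to) unit length; the result is orthonormal with
    determinant +1 to better than 1e-10.
    """
    ax = _as_unit(axis, "rotation axis")
    return Rotation.from_rotvec(ax * math.radians(angle_deg)).as_matrix()


@dataclass
class Reflection:
    """One observed reflection: beam directions and goniometer setting.

    ``s0`` is the incident-beam unit direction (source toward sample) and
    ``s1`` the diffracted-beam unit direction (sample toward detector), both
    in the lab frame.  ``scan_angle_deg`` is the omega rotation at which the
    reflection was observed; ``kappa_deg``/``phi_deg`` are the setting angles
    of the data set.
    """

    id: str
    s0: np.ndarray
    s1: np.ndarray
    scan_angle_deg: float = 0.0
    kappa_deg: float = 0.0
    phi_deg: float = 0.0

    def __post_init__(self) -> None:
        self.s0 = _as_unit(self.s0, "s0")
        self.s1 = _as_unit(self.s1, "s1")

    @property
    def two_theta_deg(self) -> float:
        return math.degrees(math.acos(float(np.clip(self.s0 @ self.s1, -1.0, 1.0))))


_DEFAULT_KAPPA_ALPHA_DEG = 50.0


def _default_kappa_axis() -> np.ndarray:
    a = math.radians(_DEFAULT_KAPPA_ALPHA_DEG)
    return np.array([0.0, math.cos(a), -math.sin(a)])


@dataclass
class GoniometerModel:
    """Multi-axis goniometer: omega (scan), kappa and phi axes in the lab frame.

    Composition order is outermost-to-innermost omega, kappa, phi:
    ``setting_matrix = R(omega) @ R(kappa) @ R(phi)``.
    """

    omega_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    kappa_axis: np.ndarray = field(default_factory=_default_kappa_axis)
    phi_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))

    def __post_init__(self) -> None:
        self.omega_axis = _as_unit(self.omega_axis, "omega_axis")
        self.kappa_axis = _as_unit(self.kappa_axis, "kappa_axis")
        self.phi_axis = _as_unit(self.phi_axis, "phi_axis")

    def setting_matrix(
        self, scan_angle_deg: float, kappa_deg: float = 0.0, phi_deg: float = 0.0
    ) -> np.ndarray:
        """Composed goniometer rotation for one setting (model -> lab)."""
        return (
            rotation_about_axis(self.omega_axis, scan_angle_deg)
            @ rotation_about_axis(self.kappa_axis, kappa_deg)
            @ rotation_about_axis(self.phi_axis, phi_deg)
        )


def beam_vectors_in_model_frame(
    refl: Reflection, gonio: GoniometerModel
) -> tuple[np.ndarray, np.ndarray]:
    """Rotate the incident and diffracted beam directions into the model frame.

    The tomogram is acquired at kappa = 0, phi = 0 (and serves as omega = 0
    reference), so a lab-frame direction v maps to the model frame as
    ``M(omega, kappa, phi).T @ v`` with M the composed setting matrix.  Both
    returned directions are unit length; applying the forward matrix recovers
    the lab vectors.
    """
    m = gonio.setting_matrix(refl.scan_angle_deg, refl.kappa_deg, refl.phi_deg)
    s0_m = m.T @ refl.s0
    s1_m = m.T @ refl.s1
    # rotation preserves norms; renormalize only to shed accumulated rounding
    return s0_m / np.linalg.norm(s0_m), s1_m / np.linalg.norm(s1_m)


@dataclass
class BeamModel:
    """Idealized top-hat beam: uniform inside a rectangular footprint, zero outside.

    ``direction`` is the propagation direction (lab frame); ``width_um`` /
    ``height_um`` are the full footprint dimensions along the two
    ``footprint_axes`` spanning the plane perpendicular to the beam.  If the
    axes are omitted they are constructed as (horizontal, vertical-ish)
    vectors orthonormal to the direction.
    """

    width_um: float
    height_um: float
    direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    footprint_axes: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if not (self.width_um > 0 and self.height_um > 0):
            raise ValueError("beam footprint dimensions must be positive")
        self.direction = _as_unit(self.direction, "beam direction")
        if self.footprint_axes is None:
            ref = np.array([0.0, 1.0, 0.0])
            if abs(self.direction @ ref) > 0.99:
                ref = np.array([1.0, 0.0, 0.0])
            u = np.cross(ref, self.direction)
            u /= np.linalg.norm(u)
            v = np.cross(self.direction, u)
            self.footprint_axes = (u, v)
        else:
            u = _as_unit(self.footprint_axes[0], "footprint axis 0")
            v = _as_unit(self.footprint_axes[1], "footprint axis 1")
            for w, nm in ((u, "axis 0"), (v, "axis 1")):
                if abs(w @ self.direction) > _UNIT_TOL:
                    raise ValueError(f"footprint {nm} not perpendicular to the beam")
            if abs(u @ v) > _UNIT_TOL:
                raise ValueError("footprint axes are not orthogonal")
            self.footprint_axes = (u, v)


def beam_footprint_test(point_um: np.ndarray, beam: BeamModel) -> np.ndarray | bool:
    """Top-hat discriminator: is a lab-frame point inside the beam footprint?

    The beam axis passes through the lab origin (the rotation centre, which
    coincides with the model-grid centre).  A point is illuminated iff its
    perpendicular offsets from the axis are within half-width and half-height.
    Accepts a single point or an ``(n, 3)`` array.
    """
    p = np.asarray(point_um, dtype=float)
    single = p.ndim == 1
    p = np.atleast_2d(p)
    u, v = beam.footprint_axes  # type: ignore[misc]
    ok = (np.abs(p @ u) <= beam.width_um / 2.0) & (np.abs(p @ v) <= beam.height_um / 2.0)
    return bool(ok[0]) if single else ok
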