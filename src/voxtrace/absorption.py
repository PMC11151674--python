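"""Per-voxel and per-reflection absorption factors and their export.

For one crystal voxel the transmission is ``exp(-sum_m mu_m (L1^m + L2^m))``
with per-material incident/diffracted path lengths from the ray tracer; the
per-reflection absorption factor A_h is the mean of that quantity over the
crystal voxels illuminated by the beam.  Measured intensities are divided by
A_h downstream, so A_h is in (0, 1] and equals 1 exactly when all
coefficients vanish.

Crystal-voxel selection follows the discretized model: crystal voxels are
sorted lexicographically by (z, y, x) index, filtered by the top-hat beam
discriminator evaluated for the reflection's goniometer setting, and then
systematically subsampled (every ``interval``-th entry, default 2000).
Systematic sampling of the sorted list is self-weighting, so the factor is
the unweighted mean over the selected voxels.
"""

from __future__ import annotations

import hashlib
import io
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import BeamModel, GoniometerModel, Reflection, beam_footprint_test, beam_vectors_in_model_frame
from .raytrace import PathSegments, path_lengths_batch
from .volume import MaterialCoefficients, SegmentedVolume

__all__ = [
    "SamplingPlan",
    "CorrectionTable",
    "ReflectionOutsideBeamError",
    "voxel_factor",
    "select_crystal_voxels",
    "reflection_factor",
    "correct_intensities",
    "write_corrections",
    "read_corrections",
]


class ReflectionOutsideBeamError(ValueError):
    """No crystal voxel is illuminated by the beam for this reflection."""


@dataclass(frozen=True)
class SamplingPlan:
    """Systematic sampling over the sorted crystal-voxel list.

    Every ``interval``-th voxel (starting at index 0) of the lexicographically
    (z, y, x)-sorted, beam-filtered crystal voxels is used.  ``interval=1``
    means full enumeration.
    """

    interval: int = 2000

    def __post_init__(self) -> None:
        if int(self.interval) < 1:
            raise ValueError("sampling interval must be >= 1")
        object.__setattr__(self, "interval", int(self.interval))


def voxel_factor(l1: PathSegments, l2: PathSegments, coeffs: MaterialCoefficients) -> float:
    """Transmission of one crystal voxel: ``exp(-sum_m mu_m (L1^m + L2^m))``.

    Every label traversed with positive length must have a coefficient
    (vacuum is implicitly 0).
    """
    exponent = 0.0
    for seg in (l1, l2):
        for lab, length in seg.lengths.items():
            if length <= 0.0:
                continue
            if lab not in coeffs.mu:
                raise KeyError(f"material label {lab} traversed but missing from coefficients")
            exponent += coeffs.mu[lab] * length
    return math.exp(-exponent)


def select_crystal_voxels(
    vol: SegmentedVolume,
    beam: BeamModel,
    refl: Reflection,
    plan: SamplingPlan,
    gonio: GoniometerModel | None = None,
) -> np.ndarray:
    """Ordered crystal-voxel indices to evaluate for one reflection.

    Crystal voxels (sorted lexicographically by array index) are mapped to
    the lab frame with the forward goniometer matrix for this reflection's
    setting and kept if the top-hat discriminator places them inside the beam
    footprint; every ``plan.interval``-th survivor is returned.  Raises
    `ReflectionOutsideBeamError` if nothing is illuminated — an explicit
    failure, never a silent A_h.
    """
    gonio = gonio if gonio is not None else GoniometerModel()
    idx = np.argwhere(vol.labels == vol.crystal_label)  # lexicographic (z, y, x)
    if idx.shape[0] == 0:
        raise ValueError("volume contains no crystal voxels")
    pos_model = vol.voxel_center_um(idx)
    m = gonio.setting_matrix(refl.scan_angle_deg, refl.kappa_deg, refl.phi_deg)
    pos_lab = pos_model @ m.T
    keep = beam_footprint_test(pos_lab, beam)
    idx = idx[keep]
    if idx.shape[0] == 0:
        raise ReflectionOutsideBeamError(
            f"reflection {refl.id}: no crystal voxel inside the beam footprint"
        )
    return idx[:: plan.interval]


def _mu_vector(coeffs: MaterialCoefficients, lengths: np.ndarray) -> np.ndarray:
    """Coefficient vector aligned with a per-label length matrix; errors if a
    traversed label has no coefficient."""
    mu = coeffs.mu_array(lengths.shape[1] - 1, fill=math.nan)
    missing = np.flatnonzero(np.isnan(mu) & (lengths.sum(axis=0) > 0))
    if missing.size:
        raise KeyError(
            f"material labels {missing.tolist()} traversed but missing from coefficients"
        )
    return np.nan_to_num(mu)


def reflection_factor(
    vol: SegmentedVolume,
    coeffs: MaterialCoefficients,
    refl: Reflection,
    gonio: GoniometerModel | None = None,
    beam: BeamModel | None = None,
    plan: SamplingPlan | None = None,
) -> tuple[float, int]:
    """Absorption correction factor A_h for one reflection.

    Beam directions are rotated into the model frame by the inverse
    goniometer composition; the incident path is traced anti-parallel to the
    incident direction.  Returns ``(A_h, n_voxels_used)`` where A_h is the
    mean voxel transmission over the selected crystal voxels.  Deterministic
    for fixed inputs.

    ``beam=None`` means an effectively infinite footprint (whole crystal
    illuminated); ``plan=None`` uses the default interval of 2000.
    """
    gonio = gonio if gonio is not None else GoniometerModel()
    plan = plan if plan is not None else SamplingPlan()
    if beam is None:
        beam = BeamModel(width_um=1e12, height_um=1e12, direction=refl.s0)
    s0_m, s1_m = beam_vectors_in_model_frame(refl, gonio)
    sel = select_crystal_voxels(vol, beam, refl, plan, gonio)
    l1 = path_lengths_batch(vol, sel, -s0_m)
    l2 = path_lengths_batch(vol, sel, s1_m)
    tot = l1 + l2
    mu = _mu_vector(coeffs, tot)
    a_h = float(np.mean(np.exp(-(tot @ mu))))
    return a_h, int(sel.shape[0])


@dataclass
class CorrectionTable:
    """Per-reflection absorption factors ready for export to a scaling program.

    ``data`` has columns ``id``, ``A_h``, ``n_voxels_used``; ``provenance``
    records how the factors were produced (config hash, sampling interval,
    coefficient map, ...).
    """

    data: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"id", "A_h", "n_voxels_used"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"correction table missing columns {sorted(missing)}")
        a = self.data["A_h"].to_numpy(dtype=float)
        if a.size and not ((a > 0.0) & (a <= 1.0)).all():
            bad = self.data["id"][(a <= 0.0) | (a > 1.0)].tolist()
            raise ValueError(f"A_h outside (0, 1] for reflections {bad}")

    def __len__(self) -> int:
        return len(self.data)


def correct_intensities(intensities: pd.DataFrame, table: CorrectionTable) -> pd.DataFrame:
    """Divide observed intensities (and sigmas) by the absorption factor.

    ``intensities`` needs columns ``id``, ``intensity`` and optionally
    ``sigma``; every row must have a matching correction.  ``A_h = 1`` leaves
    a row unchanged and relative errors sigma/I are preserved.
    """
    merged = intensities.merge(table.data[["id", "A_h"]], on="id", how="left", validate="m:1")
    unmatched = merged["id"][merged["A_h"].isna()].tolist()
    if unmatched:
        raise KeyError(f"no absorption factor for reflections {unmatched}")
    out = intensities.copy()
    out["intensity"] = merged["intensity"] / merged["A_h"]
    if "sigma" in out.columns:
        out["sigma"] = merged["sigma"] / merged["A_h"]
    return out


def config_hash(payload: dict) -> str:
    """Stable short hash of a JSON-serializable provenance payload."""
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_corrections(table: CorrectionTable, path: str | Path) -> None:
    """Write a correction table as CSV with ``#``-prefixed provenance header.

    Values are serialized with 17 significant digits so the round trip through
    `read_corrections` is bit-exact.
    """
    path = Path(path)
    buf = io.StringIO()
    buf.write("# voxtrace corrections v1\n")
    buf.write(f"# provenance: {json.dumps(table.provenance, sort_keys=True, default=str)}\n")
    table.data.to_csv(buf, index=False, float_format="%.17g")
    path.write_text(buf.getvalue())


def read_corrections(path: str | Path) -> CorrectionTable:
    """Read a correction table written by `write_corrections`."""
    path = Path(path)
    provenance: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            stripped = line[1:].strip()
            if stripped.startswith("provenance:"):
                provenance = json.loads(stripped[len("provenance:") :])
    df = pd.read_csv(path, comment="#", dtype={"id": str}, float_precision="round_trip")
    if "A_h" not in df.columns:
        raise ValueError(f"{path} is not a corrections file (missing A_h column)")
    return CorrectionTable(df, provenance)
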