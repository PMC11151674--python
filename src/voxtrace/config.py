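"""Run configuration, batch correction driver, and reflection-table I/O.

The canonical reflection exchange format is a CSV with a header row and
columns ``id, s0x, s0y, s0z, s1x, s1y, s1z, omega_deg, kappa_deg, phi_deg``
(unit beam vectors in the lab frame, goniometer angles in degrees).  The run
configuration is a flat YAML/JSON key-value file naming the input files and
the geometry:

.. code-block:: yaml

    volume: model.tif
    reflections: refl.csv
    coefficients: coeffs.json          # or an inline {label: mu} map
    beam: {width_um: 240.0, height_um: 150.0, direction: [0, 0, 1]}
    goniometer: {omega_axis: [0, 1, 0]}
    sampling_interval: 2000
    workers: 1
    output: corrections.csv

Corrections are computed per reflection, optionally in parallel over
reflections; the output is deterministic and byte-identical regardless of the
worker count (results are reduced in input order).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from multiprocessing import get_context
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .absorption import CorrectionTable, SamplingPlan, config_hash, reflection_factor
from .geometry import BeamModel, GoniometerModel, Reflection
from .volume import MaterialCoefficients, SegmentedVolume, read_volume

__all__ = ["RunConfig", "run_correct", "load_reflections", "write_reflections"]

log = logging.getLogger("voxtrace")

_REFL_COLUMNS = ["id", "s0x", "s0y", "s0z", "s1x", "s1y", "s1z", "omega_deg", "kappa_deg", "phi_deg"]


def load_reflections(path: str | Path) -> list[Reflection]:
    """Read the canonical reflection CSV into `Reflection` records."""
    df = pd.read_csv(path, dtype={"id": str})
    missing = set(_REFL_COLUMNS[:7]) - set(df.columns)
    if missing:
        raise ValueError(f"reflection table {path} missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            Reflection(
                id=str(row.id),
                s0=np.array([row.s0x, row.s0y, row.s0z]),
                s1=np.array([row.s1x, row.s1y, row.s1z]),
                scan_angle_deg=float(getattr(row, "omega_deg", 0.0)),
                kappa_deg=float(getattr(row, "kappa_deg", 0.0)),
                phi_deg=float(getattr(row, "phi_deg", 0.0)),
            )
        )
    return out


def write_reflections(refls: list[Reflection], path: str | Path) -> None:
    rows = [
        {
            "id": r.id,
            "s0x": r.s0[0], "s0y": r.s0[1], "s0z": r.s0[2],
            "s1x": r.s1[0], "s1y": r.s1[1], "s1z": r.s1[2],
            "omega_deg": r.scan_angle_deg,
            "kappa_deg": r.kappa_deg,
            "phi_deg": r.phi_deg,
        }
        for r in refls
    ]
    pd.DataFrame(rows, columns=_REFL_COLUMNS).to_csv(path, index=False)


@dataclass
class RunConfig:
    """Everything needed to compute a correction table for one data set."""

    volume: str | Path
    reflections: str | Path
    coefficients: str | Path | dict
    beam: dict = field(default_factory=lambda: {"width_um": 1e9, "height_um": 1e9})
    goniometer: dict = field(default_factory=dict)
    sampling_interval: int = 2000
    workers: int = 1
    seed: int | None = None
    output: str | Path | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        if not isinstance(raw, dict):
            raise ValueError(f"config {path} is not a key-value mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        cfg = cls(**raw)
        # resolve relative paths against the config file location
        base = path.parent
        cfg.volume = base / cfg.volume
        cfg.reflections = base / cfg.reflections
        if not isinstance(cfg.coefficients, dict):
            cfg.coefficients = base / cfg.coefficients
        if cfg.output is not None:
            cfg.output = base / cfg.output
        return cfg

    def load_coefficients(self) -> MaterialCoefficients:
        if isinstance(self.coefficients, dict):
            payload = dict(self.coefficients)
        else:
            payload = json.loads(Path(self.coefficients).read_text())
        wavelength = payload.pop("wavelength_A", None)
        mu = payload.pop("mu", payload)
        return MaterialCoefficients({int(k): float(v) for k, v in mu.items()}, wavelength)

    def build_goniometer(self) -> GoniometerModel:
        kwargs = {k: np.asarray(v, dtype=float) for k, v in self.goniometer.items()}
        return GoniometerModel(**kwargs)

    def build_beam(self) -> BeamModel:
        kwargs = dict(self.beam)
        if "direction" in kwargs:
            kwargs["direction"] = np.asarray(kwargs["direction"], dtype=float)
        return BeamModel(**kwargs)


# -- parallel workers --------------------------------------------------------

_STATE: dict = {}


def _init_worker(vol: SegmentedVolume, coeffs, gonio, beam, plan) -> None:
    _STATE["args"] = (vol, coeffs, gonio, beam, plan)


def _compute_one(refl: Reflection):
    vol, coeffs, gonio, beam, plan = _STATE["args"]
    try:
        a_h, n_used = reflection_factor(vol, coeffs, refl, gonio, beam, plan)
        return (refl.id, a_h, n_used, None)
    except Exception as exc:  # aggregated and re-raised by the driver
        return (refl.id, float("nan"), 0, f"{type(exc).__name__}: {exc}")


def run_correct(cfg: RunConfig) -> CorrectionTable:
    """Compute the correction table described by a run configuration.

    Deterministic: identical configs give identical tables regardless of
    ``workers``.  Per-reflection failures are aggregated and raised together,
    reported by reflection id.  An empty reflection table yields an empty
    (valid) correction table.
    """
    t0 = time.perf_counter()
    vol = read_volume(cfg.volume)
    coeffs = cfg.load_coefficients()
    gonio = cfg.build_goniometer()
    beam = cfg.build_beam()
    plan = SamplingPlan(cfg.sampling_interval)
    refls = load_reflections(cfg.reflections)
    log.info(
        "loaded volume %s (%d crystal voxels), %d reflections",
        cfg.volume, vol.count(vol.crystal_label), len(refls),
    )

    if cfg.workers > 1 and len(refls) > 1:
        ctx = get_context("fork")
        with ctx.Pool(
            cfg.workers, initializer=_init_worker, initargs=(vol, coeffs, gonio, beam, plan)
        ) as pool:
            results = pool.map(_compute_one, refls)
    else:
        _init_worker(vol, coeffs, gonio, beam, plan)
        results = [_compute_one(r) for r in refls]

    failures = [(rid, err) for rid, _, _, err in results if err is not None]
    if failures:
        detail = "; ".join(f"{rid}: {err}" for rid, err in failures[:10])
        raise RuntimeError(f"{len(failures)} reflection(s) failed ({detail})")

    df = pd.DataFrame(
        [(rid, a, n) for rid, a, n, _ in results], columns=["id", "A_h", "n_voxels_used"]
    )
    provenance = {
        "sampling_interval": cfg.sampling_interval,
        "coefficients": {str(k): v for k, v in coeffs.mu.items()},
        "wavelength_A": coeffs.wavelength_A,
        "beam": {k: (list(v) if isinstance(v, (list, tuple, np.ndarray)) else v) for k, v in cfg.beam.items()},
        "n_reflections": len(refls),
    }
    provenance["config_hash"] = config_hash(provenance)
    log.info("corrected %d reflections in %.2f s", len(refls), time.perf_counter() - t0)
    return CorrectionTable(df, provenance)
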