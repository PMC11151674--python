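"""Shared fixtures: synthetic samples and material coefficient sets."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from voxtrace import (
    MaterialCoefficients,
    Placement,
    generate_composite_sample,
    generate_shape,
)

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


# Linear absorption coefficients (um^-1) of the two study samples: a
# membrane-protein (porin) crystal measured at 3.54 A and a chlorite
# dismutase crystal at 4.13 A.
OMP_MU = {"crystal": 0.01053, "liquor": 0.01208, "loop": 0.00931, "aggregate": 0.0322}
OMP_WAVELENGTH_A = 3.54
CLD_MU = {"crystal": 0.0160, "liquor": 0.01856, "loop": 0.01724}
CLD_WAVELENGTH_A = 4.13

CRYSTAL, LIQUOR, AGGREGATE = 1, 2, 3


@pytest.fixture(scope="session")
def omp_coeffs() -> MaterialCoefficients:
    return MaterialCoefficients(
        {CRYSTAL: OMP_MU["crystal"], LIQUOR: OMP_MU["liquor"], AGGREGATE: OMP_MU["aggregate"]},
        wavelength_A=OMP_WAVELENGTH_A,
    )


@pytest.fixture(scope="session")
def cld_coeffs() -> MaterialCoefficients:
    return MaterialCoefficients(
        {CRYSTAL: CLD_MU["crystal"], LIQUOR: CLD_MU["liquor"]},
        wavelength_A=CLD_WAVELENGTH_A,
    )


@pytest.fixture(scope="session")
def droplet_omp():
    """Porin-like sample: crystal rod + aggregate blob inside a liquor drop.

    0.5 um voxels; the aggregate is laterally offset so face-on rays never
    cross both crystal and aggregate (each material has clean pixels).
    """
    entries = [
        Placement("sphere", LIQUOR, (0.0, 0.0, 0.0), size_um=40.0),
        Placement("box", CRYSTAL, (0.0, 0.0, 0.0), dims_um=(14.0, 14.0, 50.0)),
        Placement("sphere", AGGREGATE, (0.0, 20.0, 0.0), size_um=8.0),
    ]
    return generate_composite_sample(
        entries, (176, 176, 176), 0.5,
        {CRYSTAL: "crystal", LIQUOR: "liquor", AGGREGATE: "aggregate"},
    )


@pytest.fixture(scope="session")
def droplet_cld():
    """Blocky crystal inside a liquor drop (two materials only)."""
    entries = [
        Placement("sphere", LIQUOR, (0.0, 0.0, 0.0), size_um=40.0),
        Placement("box", CRYSTAL, (0.0, 0.0, 0.0), dims_um=(30.0, 30.0, 50.0)),
    ]
    return generate_composite_sample(
        entries, (176, 176, 176), 0.5, {CRYSTAL: "crystal", LIQUOR: "liquor"}
    )


@pytest.fixture(scope="session")
def sphere_in_shell():
    """Crystal sphere (R = 5 um) centred in a liquor sphere (R = 8 um), 0.5 um voxels."""
    entries = [
        Placement("sphere", LIQUOR, (0.0, 0.0, 0.0), size_um=8.0),
        Placement("sphere", CRYSTAL, (0.0, 0.0, 0.0), size_um=5.0),
    ]
    return generate_composite_sample(
        entries, (36, 36, 36), 0.5, {CRYSTAL: "crystal", LIQUOR: "liquor"}
    )


@pytest.fixture(scope="session")
def crystal_cube():
    """Homogeneous crystal cube, 10 um edge at 0.5 um voxels (20 voxels across)."""
    return generate_shape("cube", 10.0, 0.5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
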