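"""Per-voxel and per-reflection absorption factors, selection and export."""

import math

import numpy as np
import pandas as pd
import pytest

from voxtrace import (
    BeamModel,
    CorrectionTable,
    GoniometerModel,
    MaterialCoefficients,
    Placement,
    Reflection,
    ReflectionOutsideBeamError,
    SamplingPlan,
    SegmentedVolume,
    correct_intensities,
    generate_composite_sample,
    read_corrections,
    reflection_factor,
    select_crystal_voxels,
    trace_pair,
    voxel_factor,
    write_corrections,
)
from voxtrace.raytrace import PathSegments


class TestVoxelFactor:
    def test_zero_mu_gives_unity(self):
        l1 = PathSegments({1: 10.0})
        l2 = PathSegments({1: 5.0, 0: 2.0})
        assert voxel_factor(l1, l2, MaterialCoefficients({1: 0.0})) == 1.0

    def test_crystal_only_path(self):
        # a porin crystal coefficient with 100 um of total path
        l1 = PathSegments({1: 60.0})
        l2 = PathSegments({1: 40.0})
        coeffs = MaterialCoefficients({1: 0.01053})
        assert voxel_factor(l1, l2, coeffs) == pytest.approx(math.exp(-1.053), rel=1e-12)

    def test_equal_exponents_equal_factors(self):
        c = MaterialCoefficients({1: 0.02, 2: 0.02})
        a = voxel_factor(PathSegments({1: 30.0}), PathSegments({2: 20.0}), c)
        b = voxel_factor(PathSegments({1: 50.0}), PathSegments({}), c)
        assert a == pytest.approx(b, rel=1e-12)

    def test_missing_coefficient_raises(self):
        with pytest.raises(KeyError, match="label 2"):
            voxel_factor(PathSegments({2: 1.0}), PathSegments({}), MaterialCoefficients({1: 0.1}))


def _box_volume(n_crystal=10000):
    # 10 x 10 x 100 voxel crystal rod: exactly 10000 crystal voxels
    return generate_composite_sample(
        [Placement("box", 1, dims_um=(10.0, 10.0, 100.0))],
        (104, 14, 14), 1.0, {1: "crystal"},
    )


class TestSelectCrystalVoxels:
    def test_interval_one_with_wide_beam_selects_all(self, sphere_in_shell):
        refl = Reflection("r", [0, 0, 1], [1, 0, 0])
        beam = BeamModel(width_um=1e9, height_um=1e9)
        sel = select_crystal_voxels(sphere_in_shell, beam, refl, SamplingPlan(1))
        assert len(sel) == sphere_in_shell.count(1)

    def test_every_2000th_of_sorted_list(self):
        vol = _box_volume()
        assert vol.count(1) == 10000
        refl = Reflection("r", [0, 0, 1], [1, 0, 0])
        beam = BeamModel(width_um=1e9, height_um=1e9)
        sel = select_crystal_voxels(vol, beam, refl, SamplingPlan(2000))
        assert len(sel) == 5
        full = np.argwhere(vol.labels == 1)
        assert np.array_equal(sel, full[[0, 2000, 4000, 6000, 8000]])

    def test_lexicographic_ordering(self, sphere_in_shell):
        refl = Reflection("r", [0, 0, 1], [1, 0, 0])
        beam = BeamModel(width_um=1e9, height_um=1e9)
        sel = select_crystal_voxels(sphere_in_shell, beam, refl, SamplingPlan(1))
        flat = np.ravel_multi_index(sel.T, sphere_in_shell.labels.shape)
        assert np.all(np.diff(flat) > 0)

    def test_beam_missing_crystal_raises(self):
        # crystal sits at x = +8 um; a 2 um beam footprint centred on the
        # rotation axis never illuminates it -> explicit error, no silent A_h
        vol = generate_composite_sample(
            [Placement("sphere", 1, (8.0, 0.0, 0.0), size_um=3.0)],
            (30, 30, 30), 1.0, {1: "crystal"},
        )
        beam = BeamModel(width_um=2.0, height_um=2.0, direction=[0, 0, 1],
                         footprint_axes=(np.array([1.0, 0, 0]), np.array([0, 1.0, 0])))
        refl = Reflection("r", [0, 0, 1], [1, 0, 0])
        with pytest.raises(ReflectionOutsideBeamError):
            select_crystal_voxels(vol, beam, refl, SamplingPlan(1))

    def test_beam_filter_uses_rotated_positions(self):
        # crystal off-axis: a half-turn about z brings it into a beam that
        # only covers the opposite side
        vol = generate_composite_sample(
            [Placement("sphere", 1, (8.0, 0.0, 0.0), size_um=3.0)],
            (30, 30, 30), 1.0, {1: "crystal"},
        )
        gonio = GoniometerModel(omega_axis=[0, 0, 1])
        beam = BeamModel(width_um=6.0, height_um=6.0, direction=[0, 1, 0],
                         footprint_axes=(np.array([0, 0, 1.0]), np.array([1.0, 0, 0])))
        # footprint centred on the axis: at omega=0 the crystal sits at x=+8
        refl0 = Reflection("r", [0, 1, 0], [0, 0, 1], scan_angle_deg=0.0)
        with pytest.raises(ReflectionOutsideBeamError):
            select_crystal_voxels(vol, beam, refl0, SamplingPlan(1), gonio)
        # a quarter turn about z carries the crystal onto the beam axis
        refl90 = Reflection("r", [0, 1, 0], [0, 0, 1], scan_angle_deg=90.0)
        sel = select_crystal_voxels(vol, beam, refl90, SamplingPlan(1), gonio)
        assert len(sel) == vol.count(1)


class TestReflectionFactor:
    def test_unity_for_zero_absorption(self, sphere_in_shell):
        coeffs = MaterialCoefficients({1: 0.0, 2: 0.0})
        refl = Reflection("r", [0, 0, 1], [1, 0, 0])
        a, n = reflection_factor(sphere_in_shell, coeffs, refl, plan=SamplingPlan(10))
        assert a == 1.0
        assert n > 0

    def test_in_unit_interval_and_monotone_in_mu(self, sphere_in_shell):
        refl = Reflection("r", [0, 0, 1], [math.sin(0.5), 0, math.cos(0.5)])
        values = []
        for mu in (0.005, 0.01, 0.02, 0.04):
            coeffs = MaterialCoefficients({1: mu, 2: 0.01})
            a, _ = reflection_factor(sphere_in_shell, coeffs, refl, plan=SamplingPlan(7))
            assert 0.0 < a <= 1.0
            values.append(a)
        assert all(x > y for x, y in zip(values, values[1:]))

    def test_mu_length_scale_invariance(self, sphere_in_shell):
        # mu -> c mu, lengths -> lengths / c leaves the factor unchanged
        refl = Reflection("r", [0, 0, 1], [0, 1, 0])
        c = 3.0
        small = SegmentedVolume(
            sphere_in_shell.labels, sphere_in_shell.voxel_size_um / c,
            sphere_in_shell.label_names,
        )
        a1, _ = reflection_factor(
            sphere_in_shell, MaterialCoefficients({1: 0.02, 2: 0.01}), refl,
            plan=SamplingPlan(11),
        )
        a2, _ = reflection_factor(
            small, MaterialCoefficients({1: 0.02 * c, 2: 0.01 * c}), refl,
            plan=SamplingPlan(11),
        )
        assert a1 == pytest.approx(a2, rel=1e-12)

    def test_same_mu_relabelling_invariance(self):
        # splitting the liquor shell into two labels with equal mu must not
        # change the factor
        entries = [
            Placement("sphere", 2, (0.0, 0.0, 0.0), size_um=8.0),
            Placement("sphere", 1, (0.0, 0.0, 0.0), size_um=5.0),
        ]
        merged = generate_composite_sample(entries, (36, 36, 36), 0.5,
                                           {1: "crystal", 2: "liquor"})
        labels = merged.labels.copy()
        half = labels.shape[2] // 2
        upper = labels[:, :, half:] == 2
        labels[:, :, half:][upper] = 3
        split = SegmentedVolume(labels, 0.5, {1: "crystal", 2: "liquor", 3: "liquor2"})
        refl = Reflection("r", [0, 0, 1], [0.6, 0, 0.8])
        a1, _ = reflection_factor(merged, MaterialCoefficients({1: 0.02, 2: 0.013}), refl,
                                  plan=SamplingPlan(5))
        a2, _ = reflection_factor(split, MaterialCoefficients({1: 0.02, 2: 0.013, 3: 0.013}),
                                  refl, plan=SamplingPlan(5))
        assert a1 == pytest.approx(a2, rel=1e-12)

    def test_missing_traversed_coefficient_raises(self, sphere_in_shell):
        refl = Reflection("r", [0, 0, 1], [1, 0, 0])
        with pytest.raises(KeyError):
            reflection_factor(sphere_in_shell, MaterialCoefficients({1: 0.01}), refl,
                              plan=SamplingPlan(10))


class TestTracePairConsistency:
    def test_voxel_factor_matches_reflection_factor_at_interval_one(self, sphere_in_shell):
        coeffs = MaterialCoefficients({1: 0.02, 2: 0.01})
        refl = Reflection("r", [0, 0, 1], [0, 0.6, 0.8])
        a, n = reflection_factor(sphere_in_shell, coeffs, refl, plan=SamplingPlan(1))
        idx = np.argwhere(sphere_in_shell.labels == 1)
        factors = []
        for voxel in idx[:: max(1, len(idx) // 40)]:
            l1, l2 = trace_pair(sphere_in_shell, voxel, refl.s0, refl.s1)
            factors.append(voxel_factor(l1, l2, coeffs))
        assert n == len(idx)
        assert 0 < a <= 1
        assert min(factors) <= a <= max(factors)


class TestCorrectionsIO:
    def _table(self, rng, n=1000):
        df = pd.DataFrame({
            "id": [f"h{i}" for i in range(n)],
            "A_h": rng.uniform(0.05, 1.0, n),
            "n_voxels_used": rng.integers(1, 5000, n),
        })
        return CorrectionTable(df, {"sampling_interval": 2000, "config_hash": "abc"})

    def test_roundtrip_bit_exact(self, tmp_path, rng):
        table = self._table(rng)
        path = tmp_path / "corr.csv"
        write_corrections(table, path)
        back = read_corrections(path)
        assert np.array_equal(back.data["A_h"].to_numpy(), table.data["A_h"].to_numpy())
        assert back.provenance["sampling_interval"] == 2000

    def test_invalid_factor_rejected(self):
        df = pd.DataFrame({"id": ["a"], "A_h": [1.5], "n_voxels_used": [1]})
        with pytest.raises(ValueError, match="outside"):
            CorrectionTable(df)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("id,value\na,0.5\n")
        with pytest.raises(ValueError, match="A_h"):
            read_corrections(path)


class TestCorrectIntensities:
    def test_identity_and_scaling(self, rng):
        table = CorrectionTable(pd.DataFrame({
            "id": ["a", "b"], "A_h": [1.0, 0.5], "n_voxels_used": [10, 10],
        }))
        obs = pd.DataFrame({"id": ["a", "b"], "intensity": [100.0, 100.0],
                            "sigma": [10.0, 10.0]})
        out = correct_intensities(obs, table)
        assert out.loc[0, "intensity"] == 100.0 and out.loc[0, "sigma"] == 10.0
        assert out.loc[1, "intensity"] == 200.0 and out.loc[1, "sigma"] == 20.0
        # relative uncertainties are preserved
        assert np.allclose(out["sigma"] / out["intensity"], 0.1)

    def test_unmatched_reflection_raises(self):
        table = CorrectionTable(pd.DataFrame({
            "id": ["a"], "A_h": [0.9], "n_voxels_used": [1],
        }))
        obs = pd.DataFrame({"id": ["a", "zz"], "intensity": [1.0, 2.0], "sigma": [0.1, 0.1]})
        with pytest.raises(KeyError, match="zz"):
            correct_intensities(obs, table)
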