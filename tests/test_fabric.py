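"""Unit and property tests for MIL sampling and fabric-tensor fitting."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fibrefab.fabric import (
    DegenerateFabricError,
    DirectionSet,
    FabricFitError,
    MILProfile,
    anisotropy_index,
    canonicalize_axial,
    compute_mil,
    fit_fabric_tensor,
    sample_directions,
)

from _oracles import naive_mil


def _axis_direction_set():
    """Six directions: the three axes plus three diagonals (full-rank fit)."""
    d = np.array([
        [1, 0, 0], [0, 1, 0], [0, 0, 1],
        [1, 1, 0], [1, 0, 1], [0, 1, 1],
    ], dtype=float)
    return DirectionSet(d / np.linalg.norm(d, axis=1)[:, None])


def _synthesize_profile(directions, lam, axes=np.eye(3)):
    m = axes @ np.diag(1.0 / np.asarray(lam, dtype=float) ** 2) @ axes.T
    d = directions.directions
    mil = 1.0 / np.sqrt(np.einsum("ni,ij,nj->n", d, m, d))
    return MILProfile(mil_um=mil, intercept_count=np.ones(directions.n, int),
                      total_material_length_um=mil)


class TestSampleDirections:
    def test_contract_and_hemisphere(self):
        ds = sample_directions(6)
        assert ds.n == 6
        assert np.all(ds.directions[:, 2] >= 0)
        assert np.allclose(np.linalg.norm(ds.directions, axis=1), 1, atol=1e-12)

    def test_uniform_coverage_at_128(self):
        d = sample_directions(128).directions
        second_moment = np.einsum("ni,nj->ij", d, d) / d.shape[0]
        assert np.abs(second_moment - np.eye(3) / 3).max() < 0.02

    def test_too_few_directions_rejected(self):
        with pytest.raises(ValueError):
            sample_directions(5)


class TestCanonicalizeAxial:
    @pytest.mark.parametrize("v,expected", [
        ((-0.9, 0.3, 0.1), (0.9, -0.3, -0.1)),
        ((0.0, -1.0, 0.0), (0.0, 1.0, 0.0)),
        ((-0.7071, 0.7071, 0.0), (0.7071, -0.7071, 0.0)),  # tie -> X decides
    ])
    def test_sign_rule(self, v, expected):
        assert np.allclose(canonicalize_axial(np.array(v)), expected)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            canonicalize_axial(np.zeros(3))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-1, 1, allow_nan=False), min_size=3, max_size=3))
    def test_axial_idempotence_and_flip_invariance(self, comps):
        v = np.asarray(comps)
        if np.linalg.norm(v) < 1e-6:
            return
        v = v / np.linalg.norm(v)
        c1 = canonicalize_axial(v)
        assert np.allclose(c1, canonicalize_axial(-v))
        assert np.allclose(c1, canonicalize_axial(c1))
        assert c1[np.argmax(np.abs(c1))] > 0


class TestComputeMIL:
    def test_solid_cube_axis_chord(self):
        mask = np.ones((32, 32, 32), dtype=bool)
        prof = compute_mil(mask, 1.0, _axis_direction_set(), 2.0)
        # axis-aligned lines have one intercept each, spanning the cube
        assert prof.mil_um[0] == pytest.approx(32.0, abs=1e-9)
        assert prof.mil_um[1] == pytest.approx(32.0, abs=1e-9)

    def test_periodic_slabs(self):
        mask = np.zeros((128, 128, 128), dtype=bool)
        z = np.arange(128)
        mask[:, :, (z // 8) % 2 == 0] = True
        prof = compute_mil(mask, 1.0, _axis_direction_set(), 2.0)
        mil_x, mil_z = prof.mil_um[0], prof.mil_um[2]
        assert 7.0 <= mil_z <= 9.0
        assert mil_x >= 10 * mil_z

    def test_parallel_cylinders(self):
        # non-overlapping cylinders along Z, radius 6, on a 20-voxel grid
        mask = np.zeros((60, 60, 64), dtype=bool)
        xy = np.indices((60, 60))
        for cx in (10, 30, 50):
            for cy in (10, 30, 50):
                disk = (xy[0] - cx) ** 2 + (xy[1] - cy) ** 2 <= 36
                mask[disk, :] = True
        prof = compute_mil(mask, 1.0, _axis_direction_set(), 2.0)
        mil_x, mil_z = prof.mil_um[0], prof.mil_um[2]
        mean_chord = np.pi * 6 / 2
        assert mil_z >= 5 * mil_x
        assert 0.8 * mean_chord <= mil_x <= 1.2 * mean_chord

    def test_all_void_profile_undefined(self):
        prof = compute_mil(np.zeros((16, 16, 16), bool), 1.0,
                           sample_directions(8), 2.0)
        assert np.all(prof.intercept_count == 0)
        assert np.all(np.isnan(prof.mil_um))

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_naive_per_line_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((16, 16, 16)) < 0.4
        ds = sample_directions(8)
        prof = compute_mil(mask, 1.3, ds, 2.0)
        mil, counts, totals = naive_mil(mask, 1.3, ds, 2.0)
        assert np.array_equal(counts, prof.intercept_count)
        assert np.max(np.abs(totals - prof.total_material_length_um)) < 1e-9


class TestFabricFit:
    def test_isotropic_profile(self, directions64):
        c = 7.5
        mil = np.full(directions64.n, c)
        prof = MILProfile(mil_um=mil, intercept_count=np.ones(64, int),
                          total_material_length_um=mil)
        tensor = fit_fabric_tensor(prof, directions64)
        assert np.allclose(tensor.eigenvalues_um, c, rtol=1e-9)
        assert anisotropy_index(tensor) == pytest.approx(0.0, abs=1e-9)

    def test_exact_round_trip(self, directions128):
        lam = (10.0, 5.0, 2.0)
        prof = _synthesize_profile(directions128, lam)
        tensor = fit_fabric_tensor(prof, directions128)
        assert np.allclose(tensor.eigenvalues_um, lam, rtol=1e-9)
        angle = np.arccos(min(1.0, abs(tensor.primary_eigenvector @ [1, 0, 0])))
        assert angle < 1e-6
        assert anisotropy_index(tensor) == pytest.approx(0.8, abs=1e-12)

    def test_round_trip_with_noise(self, directions128):
        lam = (10.0, 5.0, 2.0)
        prof = _synthesize_profile(directions128, lam)
        rng = np.random.default_rng(42)
        noisy = prof.mil_um * (1 + 0.01 * rng.standard_normal(directions128.n))
        prof2 = MILProfile(mil_um=noisy,
                           intercept_count=np.ones(directions128.n, int),
                           total_material_length_um=noisy)
        tensor = fit_fabric_tensor(prof2, directions128)
        angle = np.degrees(
            np.arccos(min(1.0, abs(tensor.primary_eigenvector @ [1, 0, 0]))))
        assert angle < 2.0

    def test_too_few_defined_directions(self, directions32):
        mil = np.full(32, np.nan)
        mil[:5] = 10.0
        counts = np.zeros(32, int)
        counts[:5] = 1
        prof = MILProfile(mil_um=mil, intercept_count=counts,
                          total_material_length_um=np.where(counts, 10.0, 0.0))
        with pytest.raises(FabricFitError):
            fit_fabric_tensor(prof, directions32)

    def test_coplanar_directions_rank_deficient(self):
        theta = np.linspace(0.1, np.pi - 0.1, 8)
        d = np.column_stack([np.cos(theta), np.sin(theta), np.zeros(8)])
        ds = DirectionSet(d)
        mil = np.full(8, 5.0)
        prof = MILProfile(mil_um=mil, intercept_count=np.ones(8, int),
                          total_material_length_um=mil)
        with pytest.raises(FabricFitError):
            fit_fabric_tensor(prof, ds)

    def test_non_positive_definite_fit_degenerate(self):
        # directions away from the Z pole keep the indefinite quadratic form
        # positive on the samples while the fitted tensor has a negative
        # eigenvalue
        rng = np.random.default_rng(3)
        d = rng.standard_normal((12, 3))
        d[:, 2] = np.abs(d[:, 2]) * 0.3
        d /= np.linalg.norm(d, axis=1)[:, None]
        ds = DirectionSet(d)
        m = np.diag([1.0, 1.0, -0.1])
        q = np.einsum("ni,ij,nj->n", d, m, d)
        assert np.all(q > 0)
        mil = 1.0 / np.sqrt(q)
        prof = MILProfile(mil_um=mil, intercept_count=np.ones(12, int),
                          total_material_length_um=mil)
        with pytest.raises(DegenerateFabricError) as err:
            fit_fabric_tensor(prof, ds)
        assert err.value.tensor.shape == (3, 3)

    def test_anisotropy_scale_invariance(self, directions64):
        for scale in (1.0, 3.5):
            prof = _synthesize_profile(directions64,
                                       scale * np.array([8.0, 6.0, 3.0]))
            tensor = fit_fabric_tensor(prof, directions64)
            assert anisotropy_index(tensor) == pytest.approx(1 - 3 / 8, rel=1e-9)


class TestGeometricProperties:
    def test_scale_covariance(self, directions64):
        rng = np.random.default_rng(5)
        mask = rng.random((24, 24, 24)) < 0.35
        t1 = fit_fabric_tensor(compute_mil(mask, 1.0, directions64), directions64)
        t2 = fit_fabric_tensor(compute_mil(mask, 2.0, directions64), directions64)
        assert np.allclose(t2.eigenvalues_um, 2 * t1.eigenvalues_um, rtol=1e-9)
        assert np.allclose(t2.eigenvectors, t1.eigenvectors, atol=1e-9)
        assert anisotropy_index(t2) == pytest.approx(anisotropy_index(t1),
                                                     abs=1e-12)

    def test_prolate_vs_oblate_fabric(self, directions64):
        # rods: parallel cylinders -> lambda1 >> lambda2 ~ lambda3
        rods = np.zeros((48, 48, 48), dtype=bool)
        xy = np.indices((48, 48))
        for cx in (8, 24, 40):
            for cy in (8, 24, 40):
                rods[(xy[0] - cx) ** 2 + (xy[1] - cy) ** 2 <= 16, :] = True
        t_rod = fit_fabric_tensor(compute_mil(rods, 1.0, directions64),
                                  directions64)
        l1, l2, l3 = t_rod.eigenvalues_um
        assert l1 >= 2 * l2
        assert l2 <= 2 * l3
        # plates: slabs -> lambda1 ~ lambda2 >> lambda3
        plates = np.zeros((48, 48, 48), dtype=bool)
        z = np.arange(48)
        plates[:, :, (z // 6) % 2 == 0] = True
        t_plate = fit_fabric_tensor(compute_mil(plates, 1.0, directions64),
                                    directions64)
        l1, l2, l3 = t_plate.eigenvalues_um
        assert l2 >= 2 * l3
        assert l1 <= 2 * l2
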