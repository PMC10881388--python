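import numpy as np
import pytest

from trsfx.models import AtomicModel
from trsfx.scattering import (ReflectionSet, ScalingError, hemisphere_indices,
                              mix_states, peak_height, scale_light_to_dark,
                              structure_factors, synthesize_map)


def small_model(xyz, elements=None, b=None, cell=(10.0, 9.0, 8.0)):
    n = len(xyz)
    elements = elements or ["C"] * n
    return AtomicModel(
        atom_id=np.array([f"A{i}" for i in range(n)], dtype=object),
        element=np.array(elements, dtype=object),
        res_name=np.array(["ALA"] * n, dtype=object),
        res_seq=np.arange(1, n + 1),
        xyz=np.asarray(xyz, dtype=float),
        b=np.asarray(b if b is not None else [12.0] * n, dtype=float),
        occ=np.ones(n), cell=cell)


class TestStructureFactors:
    def test_single_atom_at_origin_zero_b(self):
        m = small_model([[0, 0, 0]], elements=["N"], b=[1e-9])
        rs = structure_factors(m, d_min=2.0)
        assert np.allclose(rs.f, 7.0, atol=1e-6)        # F(h) = Z everywhere
        phases = np.angle(rs.complex_f(), deg=True)
        assert np.allclose(np.abs(np.exp(1j * np.deg2rad(phases)) - 1.0), 0, atol=1e-6)

    def test_friedel_symmetry(self):
        rng = np.random.default_rng(1)
        m = small_model(rng.uniform(1, 7, size=(4, 3)))
        hkl = np.array([[1, 2, 3], [2, -1, 1], [3, 0, -2]])
        plus = structure_factors(m, hkl=hkl)
        minus = structure_factors(m, hkl=-hkl)
        assert np.allclose(plus.f, minus.f, rtol=1e-12)
        assert np.allclose(plus.complex_f(), np.conj(minus.complex_f()), rtol=1e-12)

    def test_amplitudes_match_quadrature_fourier_oracle(self):
        """Direct summation vs numerical FT of the real-space Gaussian density."""
        rng = np.random.default_rng(7)
        cell = (10.0, 9.0, 8.0)
        m = small_model(rng.uniform(2.5, 5.5, size=(5, 3)),
                        elements=["C", "N", "O", "C", "N"],
                        b=[10.0, 15.0, 20.0, 12.0, 18.0], cell=cell)
        rs = structure_factors(m, d_min=2.0)
        # brute-force oracle: sample the Gaussian-atom density (with periodic
        # images) on a fine grid and take its discrete Fourier transform
        shape = (80, 72, 64)
        axes = [np.arange(n) * c / n for n, c in zip(shape, cell)]
        X, Y, Z = np.meshgrid(*axes, indexing="ij")
        rho = np.zeros(shape)
        for i in range(m.n_atoms):
            a = 4.0 * np.pi ** 2 / m.b[i]
            z_el = m.electrons[i]
            for sx in (-1, 0, 1):
                for sy in (-1, 0, 1):
                    for sz in (-1, 0, 1):
                        dx = X - (m.xyz[i, 0] + sx * cell[0])
                        dy = Y - (m.xyz[i, 1] + sy * cell[1])
                        dz = Z - (m.xyz[i, 2] + sz * cell[2])
                        rho += z_el * (a / np.pi) ** 1.5 * np.exp(
                            -a * (dx ** 2 + dy ** 2 + dz ** 2))
        vol = np.prod(cell)
        f_grid = np.fft.ifftn(rho) * vol   # F(h) = V * <rho e^{2pi i h.x}>
        h, k, l = rs.hkl.T
        oracle = np.abs(f_grid[h % shape[0], k % shape[1], l % shape[2]])
        assert np.max(np.abs(rs.f - oracle) / np.maximum(oracle, 1e-3)) < 0.005

    def test_invalid_resolution_rejected(self):
        m = small_model([[1, 1, 1]])
        with pytest.raises(ValueError):
            structure_factors(m, d_min=-1.0)


class TestMixStates:
    def test_endpoint_identities(self, dark_sf, excited_sf):
        assert np.allclose(mix_states(dark_sf, excited_sf, 0.0).complex_f(),
                           dark_sf.complex_f())
        assert np.allclose(mix_states(dark_sf, excited_sf, 1.0).complex_f(),
                           excited_sf.complex_f())

    def test_antiphase_cancellation(self):
        cell = (10.0, 9.0, 8.0)
        hkl = np.array([[1, 0, 0]])
        a = ReflectionSet(cell, hkl, [5.0], [0.0], [0.0], 2.0)
        b = ReflectionSet(cell, hkl, [5.0], [180.0], [0.0], 2.0)
        assert mix_states(a, b, 0.5).f[0] == pytest.approx(0.0, abs=1e-12)

    def test_index_mismatch_rejected(self, dark_sf):
        other = dark_sf.copy()
        other.hkl = other.hkl[::-1].copy()
        with pytest.raises(ValueError, match="index"):
            mix_states(dark_sf, other, 0.5)


class TestScaling:
    def test_identity(self, dark_sf):
        _, k, b = scale_light_to_dark(dark_sf, dark_sf)
        assert k == pytest.approx(1.0, abs=1e-9)
        assert b == pytest.approx(0.0, abs=1e-9)

    def test_pure_scale(self, dark_sf):
        doubled = dark_sf.with_f(2.0 * dark_sf.f)
        scaled, k, b = scale_light_to_dark(doubled, dark_sf)
        assert k == pytest.approx(0.5, abs=1e-9)
        assert b == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(scaled.f, dark_sf.f)

    def test_recovers_synthetic_b_law(self, dark_sf):
        s2 = dark_sf.s2()
        light = dark_sf.with_f(dark_sf.f * np.exp(-5.0 * s2 / 4.0))
        _, k, b = scale_light_to_dark(light, dark_sf)
        assert b == pytest.approx(-5.0, abs=1e-6)
        assert k == pytest.approx(1.0, abs=1e-6)

    def test_idempotent(self, dark_sf):
        s2 = dark_sf.s2()
        light = dark_sf.with_f(1.7 * dark_sf.f * np.exp(-3.0 * s2 / 4.0))
        scaled, _, _ = scale_light_to_dark(light, dark_sf)
        _, k2, b2 = scale_light_to_dark(scaled, dark_sf)
        assert k2 == pytest.approx(1.0, abs=1e-8)
        assert b2 == pytest.approx(0.0, abs=1e-8)

    def test_degenerate_single_shell_rejected(self):
        cell = (10.0, 10.0, 10.0)
        hkl = np.array([[4, 0, 0], [0, 4, 0], [0, 0, 4]]).repeat(7, axis=0)
        rs = ReflectionSet(cell, hkl, np.ones(21), None, np.zeros(21), 2.0)
        with pytest.raises(ScalingError, match="B_rel"):
            scale_light_to_dark(rs, rs)


class TestMapSynthesis:
    def test_peak_at_atom_position(self):
        m = small_model([[4.0, 3.5, 3.0]], elements=["FE"])
        rs = structure_factors(m, d_min=1.5)
        grid = synthesize_map(rs)
        idx = np.unravel_index(np.argmax(grid.values), grid.shape)
        peak_xyz = np.array(idx) * np.array(grid.cell) / np.array(grid.shape)
        assert np.all(np.abs(peak_xyz - m.xyz[0]) <= np.array(grid.spacing))

    def test_all_zero_amplitudes_give_zero_map(self, dark_sf):
        zero = dark_sf.with_f(np.zeros(dark_sf.n_reflections))
        assert np.allclose(synthesize_map(zero).values, 0.0)

    def test_linearity_of_synthesis(self, dark_sf, excited_sf):
        diff = dark_sf.with_complex(excited_sf.complex_f() - dark_sf.complex_f())
        shape = (48, 45, 40)
        lhs = synthesize_map(diff, shape).values
        rhs = synthesize_map(excited_sf, shape).values \
            - synthesize_map(dark_sf, shape).values
        assert np.allclose(lhs, rhs, atol=1e-8)

    def test_difference_map_is_zero_mean(self, dark_sf, excited_sf):
        diff = dark_sf.with_complex(excited_sf.complex_f() - dark_sf.complex_f())
        grid = synthesize_map(diff)
        assert abs(grid.values.mean()) < 1e-12

    def test_missing_phases_rejected(self, dark_sf):
        amp_only = dark_sf.copy()
        amp_only.phase = None
        with pytest.raises(ValueError, match="phase"):
            synthesize_map(amp_only)

    def test_parseval_identity(self):
        """Band-limited map: mean(rho^2) V^2 equals the coefficient power."""
        m = small_model([[3, 3, 3], [5, 4, 4]], elements=["N", "O"])
        rs = structure_factors(m, d_min=2.0)
        grid = synthesize_map(rs)
        vol = np.prod(m.cell)
        power_coeff = 2.0 * np.sum(rs.f ** 2)  # hemisphere + Friedel mates
        assert np.mean(grid.values ** 2) * vol \
            == pytest.approx(power_coeff / vol, rel=1e-10)


class TestPeakHeight:
    def test_node_value_and_uniform_map(self):
        from trsfx.scattering import DensityGrid
        rng = np.random.default_rng(3)
        grid = DensityGrid((6.0, 6.0, 6.0), rng.normal(size=(12, 12, 12)))
        pos = np.array([2, 7, 4]) * 0.5   # grid spacing is 0.5 A -> node (2, 7, 4)
        node = grid.values[2, 7, 4]
        assert peak_height(grid, pos) == pytest.approx(node, rel=1e-12)
        uniform = DensityGrid((6.0, 6.0, 6.0), np.full((10, 10, 10), 3.3))
        assert peak_height(grid=uniform, position=[1.234, 5.0, 0.2]) \
            == pytest.approx(3.3)

    def test_local_max_matches_oversampled_oracle(self, dark_sf, excited_sf,
                                                  system):
        """Peak readout vs brute-force 4x-oversampled synthesis at the CO* site."""
        diff = dark_sf.with_complex(
            0.6 * (excited_sf.complex_f() - dark_sf.complex_f()))
        grid = synthesize_map(diff, provenance="difference map")
        site = system.excited.position("C", 155)
        ours = peak_height(grid, site, search_radius=0.8)
        fine = synthesize_map(diff, shape=tuple(4 * s for s in grid.shape))
        # oracle: max over fine-grid nodes within the search sphere
        shape = np.array(fine.shape)
        cell = np.array(fine.cell)
        center = site / cell * shape
        rad = np.ceil(0.8 / (cell / shape)).astype(int)
        best = -np.inf
        for i in range(int(center[0]) - rad[0], int(center[0]) + rad[0] + 1):
            for j in range(int(center[1]) - rad[1], int(center[1]) + rad[1] + 1):
                for k in range(int(center[2]) - rad[2], int(center[2]) + rad[2] + 1):
                    xyz = np.array([i, j, k]) * cell / shape
                    if np.sum((xyz - site) ** 2) <= 0.64:
                        best = max(best, fine.values[i % shape[0], j % shape[1],
                                                     k % shape[2]])
        assert ours == pytest.approx(best, rel=0.02)


def test_hemisphere_excludes_friedel_mates_and_f000():
    hkl = hemisphere_indices((10.0, 9.0, 8.0), d_min=2.5)
    assert not any((tuple(-h) in {tuple(x) for x in hkl}) for h in hkl)
    assert [0, 0, 0] not in hkl.tolist()
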