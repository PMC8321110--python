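"""Forward solver: operators, analytic oracles, reciprocity, noise."""

import numpy as np
import pytest
from scipy import special

from mwi3d import (PermittivityVolume, ProbeArray, VoxelGrid, add_noise,
                   measurement_count, scattering_operators, solve_forward)
from mwi3d.forward import (FieldDataSet, ScatteringOperators, _solve_masked,
                           cell_kernel, greens_point, plane_wave, ring_probes,
                           wavenumber)


@pytest.mark.parametrize("n,expected", [(24, 552), (2, 2), (10, 90)])
def test_measurement_count(n, expected):
    assert measurement_count(n) == expected


def test_measurement_count_rejects_single_probe():
    with pytest.raises(ValueError):
        measurement_count(1)


class TestKernels:
    @pytest.mark.parametrize("ndim", [2, 3])
    def test_self_term_matches_quadrature(self, ndim):
        """Closed-form cell self-integrals vs numerical quadrature."""
        from scipy import integrate
        from mwi3d.forward import _equal_measure_radius, _kernel_self
        k = 27.0 - 0.01j
        a = _equal_measure_radius(3.3e-3, ndim)
        if ndim == 2:
            f = lambda r: -0.25j * special.hankel2(0, k * r) * 2 * np.pi * r
        else:
            f = lambda r: np.exp(-1j * k * r) * r
        num = integrate.quad(lambda r: f(r).real, 0, a)[0] \
            + 1j * integrate.quad(lambda r: f(r).imag, 0, a)[0]
        assert abs(_kernel_self(k, a, ndim) - num) < 1e-6 * abs(num)

    @pytest.mark.parametrize("ndim", [2, 3])
    def test_off_center_approaches_point_kernel(self, ndim):
        """Cell smoothing converges to g(R) x cell measure away from 0."""
        k, h = 27.0, 3.3e-3
        r = np.array([10 * h])
        kk = cell_kernel(k, r, h, ndim)[0]
        ref = greens_point(k, r[0], ndim) * h ** ndim
        assert abs(kk / ref - 1) < 1e-3


class TestOperators:
    def test_zero_input_zero_output(self, grid2d, probes2d):
        ops = ScatteringOperators(grid2d, probes2d, 1.3e9)
        out = ops.apply_gd(np.zeros(grid2d.shape, dtype=complex))
        assert np.all(out == 0)

    def test_point_source_reproduces_greens_function(self, grid2d, probes2d):
        """G_D applied to a unit voxel source samples k^2 V g(r - r0)."""
        ops = ScatteringOperators(grid2d, probes2d, 1.3e9)
        u = np.zeros(grid2d.shape, dtype=complex)
        u[8, 8] = 1.0
        out = ops.apply_gd(u)
        coords = grid2d.coords()
        r0 = coords[8, 8]
        far = np.sqrt(((coords - r0) ** 2).sum(-1)) > 8 * grid2d.spacing
        expected = ops.k_b ** 2 * grid2d.cell_volume * greens_point(
            ops.k_b, np.sqrt(((coords - r0) ** 2).sum(-1))[far], 2)
        assert np.allclose(out[far], expected, rtol=2e-3)

    def test_adjoint_consistency(self, grid2d, probes2d):
        """<G_D x, y> == <x, G_D^H y> to 1e-10 relative."""
        ops = ScatteringOperators(grid2d, probes2d, 1.3e9)
        rng = np.random.default_rng(0)
        x = rng.normal(size=grid2d.shape) + 1j * rng.normal(size=grid2d.shape)
        y = rng.normal(size=grid2d.shape) + 1j * rng.normal(size=grid2d.shape)
        lhs = np.vdot(y, ops.apply_gd(x))
        rhs = np.vdot(ops.apply_gd_adjoint(y), x)
        assert abs(lhs - rhs) < 1e-10 * abs(lhs)

    def test_dense_matches_fft_path(self, grid2d, probes2d):
        ops = ScatteringOperators(grid2d, probes2d, 1.3e9)
        rng = np.random.default_rng(1)
        mask = np.zeros(grid2d.shape, dtype=bool)
        mask[10:20, 12:22] = True
        u = np.zeros(grid2d.shape, dtype=complex)
        u[mask] = rng.normal(size=mask.sum()) + 1j * rng.normal(size=mask.sum())
        dense = ops.dense_gd(mask) @ u[mask]
        fft = ops.apply_gd(u)[mask]
        assert np.allclose(dense, fft, rtol=1e-10, atol=1e-12)

    def test_under_resolved_grid_warns(self, probes2d):
        coarse = VoxelGrid((32, 32), spacing=0.02)
        with pytest.warns(RuntimeWarning, match="points per"):
            ScatteringOperators(coarse, probes2d, 10e9)

    def test_under_resolved_tissue_warns(self, grid2d, probes2d, phantom2d):
        """Tumor permittivity at 3 GHz drops below 8 voxels/wavelength."""
        from mwi3d import assign_permittivity
        eps = assign_permittivity(phantom2d)
        air = PermittivityVolume(grid2d, np.full(grid2d.shape, 1 - 0.001j),
                                 check_floor=False)
        with pytest.warns(RuntimeWarning, match="densest tissue"):
            solve_forward(eps, air, probes2d, 3e9)


def _cylinder_oracle(f, eps_cyl, a_cyl, probe_pos, n_max=30):
    """Partial-wave series for a dielectric cylinder, TM plane wave e^{-jkx}."""
    k0 = wavenumber(f, 1.0)
    k1 = wavenumber(f, eps_cyl)
    r = np.linalg.norm(probe_pos, axis=1)
    phi = np.arctan2(probe_pos[:, 1], probe_pos[:, 0])
    out = np.zeros(len(probe_pos), dtype=complex)
    for n in range(-n_max, n_max + 1):
        m = np.array([
            [special.hankel2(n, k0 * a_cyl), -special.jv(n, k1 * a_cyl)],
            [k0 * special.h2vp(n, k0 * a_cyl), -k1 * special.jvp(n, k1 * a_cyl)],
        ])
        rhs = -np.array([special.jv(n, k0 * a_cyl),
                         k0 * special.jvp(n, k0 * a_cyl)])
        bn, _ = np.linalg.solve(m, rhs)
        out += (-1j) ** n * bn * special.hankel2(n, k0 * r) * np.exp(1j * n * phi)
    return out


class TestForwardSolution:
    def test_zero_contrast_scatters_nothing(self, grid2d, probes2d):
        air = PermittivityVolume(grid2d, np.full(grid2d.shape, 1 - 0.001j),
                                 check_floor=False)
        d = solve_forward(air, air, probes2d, 1.3e9)
        assert np.max(np.abs(d.matrix)) <= 1e-8

    def test_cylinder_partial_wave_oracle(self, probes2d):
        """Low-contrast cylinder vs the analytic series, <2% relative RMS."""
        grid = VoxelGrid((64, 64), spacing=1.65e-3)
        f, eps_c, a_c = 1.3e9, 1.2, 0.025
        fill = _superellipse_fill(grid, a_c)
        chi = (eps_c - 1.0) * fill
        mask = chi != 0
        ops = ScatteringOperators(grid, probes2d, f, 1.0)
        e_inc = plane_wave(grid, ops.k_b, [1, 0])[mask][:, None]
        e = _solve_masked(ops, chi[mask], mask, e_inc, 1e-6, 2000, 10000)
        d = (ops.gs_matrix(mask) @ (chi[mask][:, None] * e))[:, 0]
        ref = _cylinder_oracle(f, eps_c, a_c, probes2d.positions)
        assert np.linalg.norm(d - ref) / np.linalg.norm(ref) < 0.02

    def test_reciprocity(self, grid2d, probes2d, phantom2d):
        from mwi3d import assign_permittivity
        eps = assign_permittivity(phantom2d)
        air = PermittivityVolume(grid2d, np.full(grid2d.shape, 1 - 0.001j),
                                 check_floor=False)
        d = solve_forward(eps, air, probes2d, 1.3e9)
        assert np.allclose(d.matrix, d.matrix.T, rtol=1e-8, atol=1e-12)

    def test_born_linearity_at_small_contrast(self, grid2d, probes2d):
        """Halving a 1e-3 contrast halves the data to first order (<1%)."""
        c = grid2d.coords()
        blob = (c[..., 0] ** 2 + c[..., 1] ** 2) < 0.02 ** 2
        air = PermittivityVolume(grid2d, np.ones(grid2d.shape))
        data = []
        for chi in (1e-3, 5e-4):
            v = np.ones(grid2d.shape, dtype=complex)
            v[blob] = 1 + chi
            d = solve_forward(PermittivityVolume(grid2d, v), air, probes2d,
                              1.3e9, embedding_eps=1.0)
            data.append(d.matrix)
        ratio = np.linalg.norm(data[0] - 2 * data[1]) / np.linalg.norm(data[0])
        assert ratio < 0.01


def _superellipse_fill(grid, radius, ss=3):
    """Anti-aliased disc indicator via subsampling."""
    coords = grid.coords()
    offs = (np.arange(ss) + 0.5) / ss - 0.5
    fill = np.zeros(grid.shape)
    for ox in offs:
        for oy in offs:
            pt = coords + np.array([ox, oy]) * grid.spacing
            fill += (pt[..., 0] ** 2 + pt[..., 1] ** 2 <= radius ** 2)
    return fill / ss ** 2


class TestNoise:
    def test_zero_level_is_identity(self, probes2d):
        rng = np.random.default_rng(0)
        m = rng.normal(size=(24, 24)) + 1j * rng.normal(size=(24, 24))
        d = FieldDataSet(1.3e9, m)
        out = add_noise(d, 0.0, rng)
        assert np.array_equal(out.matrix, d.matrix)

    def test_noise_norm_ratio_near_level(self):
        rng = np.random.default_rng(2)
        m = rng.normal(size=(24, 24)) + 1j * rng.normal(size=(24, 24))
        d = FieldDataSet(1.3e9, m)
        noisy = add_noise(d, 0.05, np.random.default_rng(7))
        ratio = np.linalg.norm(noisy.offdiag() - d.offdiag()) \
            / np.linalg.norm(d.offdiag())
        # chi-square: 3 sigma on the norm of 1104 standard normals
        assert abs(ratio - 0.05) < 0.05 * 3 / np.sqrt(2 * 552)

    def test_seeded_noise_reproducible(self):
        m = np.ones((24, 24), dtype=complex)
        d = FieldDataSet(1.3e9, m)
        a = add_noise(d, 0.05, np.random.default_rng(3))
        b = add_noise(d, 0.05, np.random.default_rng(3))
        assert np.array_equal(a.matrix, b.matrix)

    def test_negative_level_rejected(self):
        d = FieldDataSet(1.3e9, np.ones((4, 4), dtype=complex))
        with pytest.raises(ValueError):
            add_noise(d, -0.1, np.random.default_rng(0))
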