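"""Forward field model: kernels, analytic geometries, tensor consistency."""

import numpy as np
import pytest

import wmchi as w

from conftest import sphere_mask


class TestLarmorScale:
    def test_value_at_7t(self):
        # 42.577 MHz/T * 7 T -> 298.039 Hz/ppm; 0.01 ppm ~ 3 Hz
        assert w.larmor_scale(7.0) == pytest.approx(298.039)
        assert 0.01 * w.larmor_scale(7.0) == pytest.approx(2.980, abs=0.01)

    @pytest.mark.parametrize("bad", [0.0, -3.0])
    def test_rejects_nonpositive_field(self, bad):
        with pytest.raises(ValueError):
            w.larmor_scale(bad)


class TestIsoKernel:
    def test_special_directions(self, ctx):
        grid = w.GridSpec((16, 16, 16), (1.0, 1.0, 1.0), 1.0)
        D = w.iso_kernel(grid, ctx)  # B0 along z
        assert D[0, 0, 1] == pytest.approx(-2.0 / 3.0)  # k parallel to B0
        assert D[1, 0, 0] == pytest.approx(1.0 / 3.0)  # k perpendicular
        assert D[0, 0, 0] == 0.0  # mean-referenced

    def test_magic_angle_zero(self):
        # (k.h)^2/|k|^2 = 1/3 at the magic angle
        grid = w.GridSpec((16, 16, 16), (1.0, 1.0, 1.0), 1.0)
        h = np.array([np.sqrt(2.0 / 3.0), 0.0, np.sqrt(1.0 / 3.0)])
        ctx = w.FieldContext(tuple(h))
        D = w.iso_kernel(grid, ctx)
        assert D[0, 0, 1] == pytest.approx(0.0, abs=1e-12)


class TestSimulateIsoField:
    def test_zero_chi_gives_zero_field(self, small_grid, ctx):
        chi = w.ScalarVolume(np.zeros(small_grid.shape), small_grid, "ppm")
        f = w.simulate_iso_field(chi, ctx)
        assert np.all(f.data == 0)

    def test_rejects_wrong_units(self, small_grid, ctx):
        f = w.ScalarVolume(np.zeros(small_grid.shape), small_grid, "Hz")
        with pytest.raises(ValueError):
            w.simulate_iso_field(f, ctx)

    def test_sphere_lorentz_identity(self, small_grid, ctx):
        # uniform sphere: internal mean shift vanishes (sphere-of-Lorentz)
        sph = sphere_mask(small_grid, 10.0)
        chi = w.ScalarVolume(0.1 * sph, small_grid, "ppm")
        f = w.simulate_iso_field(chi, ctx)
        scale = 0.1 * ctx.larmor_scale
        assert abs(f.data[sph].mean()) < 0.01 * scale

    def test_sphere_external_point_dipole(self, ctx):
        grid = w.GridSpec((48, 48, 48), (1.0, 1.0, 1.0), 2.0)
        r_sph = 8.0
        sph = sphere_mask(grid, r_sph)
        chi_val = 0.1
        chi = w.ScalarVolume(chi_val * sph, grid, "ppm")
        f = w.simulate_iso_field(chi, ctx)
        x, y, z = grid.coords()
        r = np.sqrt(np.broadcast_to(x**2 + y**2 + z**2, grid.shape))
        outside = (r >= 2 * r_sph) & (r <= 20.0)
        # analytic: dV*chi*f0/(4 pi r^3) * (3 cos^2 - 1), dV = true sphere volume
        vol = sph.sum()  # discrete volume actually simulated
        cos2 = np.broadcast_to(z**2, grid.shape)[outside] / r[outside] ** 2
        pred = (
            chi_val * ctx.larmor_scale * vol / (4 * np.pi * r[outside] ** 3)
        ) * (3 * cos2 - 1)
        err = np.sqrt(np.mean((f.data[outside] - pred) ** 2))
        assert err < 0.05 * np.sqrt(np.mean(pred**2))

    @pytest.mark.parametrize("theta_deg", [0.0, 30.0, 54.7356103, 90.0])
    def test_infinite_cylinder_internal_shift(self, theta_deg):
        # axis-periodic cylinder, no padding: internal shift (3cos^2-1)/6 * chi f0
        grid = w.GridSpec((64, 64, 64), (1.0, 1.0, 1.0), 1.0)
        x, y, z = grid.coords()
        cyl = np.broadcast_to((x**2 + y**2) <= 6.0**2, grid.shape)
        chi_val = 0.1
        chi = w.ScalarVolume(chi_val * cyl, grid, "ppm")
        th = np.deg2rad(theta_deg)
        ctx = w.FieldContext((np.sin(th), 0.0, np.cos(th)))
        f = w.simulate_iso_field(chi, ctx)
        inner = np.broadcast_to((x**2 + y**2) <= 3.0**2, grid.shape)
        scale = chi_val * ctx.larmor_scale
        pred = scale * (3 * np.cos(th) ** 2 - 1) / 6.0
        tol = 0.005 * scale if abs(theta_deg - 54.7356103) < 0.1 else 0.02 * scale
        assert abs(f.data[inner].mean() - pred) < tol

    def test_linearity(self, small_grid, ctx):
        rng = np.random.default_rng(3)
        a, b = 2.0, -0.7
        c1 = rng.normal(0, 0.05, small_grid.shape)
        c2 = rng.normal(0, 0.05, small_grid.shape)
        f1 = w.simulate_iso_field(w.ScalarVolume(c1, small_grid, "ppm"), ctx)
        f2 = w.simulate_iso_field(w.ScalarVolume(c2, small_grid, "ppm"), ctx)
        f12 = w.simulate_iso_field(
            w.ScalarVolume(a * c1 + b * c2, small_grid, "ppm"), ctx
        )
        combo = a * f1.data + b * f2.data
        rel = np.sqrt(np.mean((f12.data - combo) ** 2) / np.mean(combo**2))
        assert rel < 1e-9

    def test_padding_sufficiency(self, ctx):
        # doubling the pad factor changes the masked field by < 0.5% RMS
        base = w.GridSpec((32, 32, 32), (1.0, 1.0, 1.0), 2.0)
        sph = sphere_mask(base, 8.0)
        chi2 = w.ScalarVolume(0.1 * sph, base, "ppm")
        chi4 = w.ScalarVolume(0.1 * sph, base.with_pad(4.0), "ppm")
        f2 = w.simulate_iso_field(chi2, ctx)
        f4 = w.simulate_iso_field(chi4, ctx)
        diff = np.sqrt(np.mean((f2.data[sph] - f4.data[sph]) ** 2))
        assert diff < 0.005 * np.sqrt(np.mean(f4.data**2))


class TestTensorForward:
    def test_isotropic_reduction(self, small_grid, ctx):
        rng = np.random.default_rng(0)
        chi = 0.1 * (rng.random(small_grid.shape) < 0.1)
        f_scalar = w.simulate_iso_field(w.ScalarVolume(chi, small_grid, "ppm"), ctx)
        f_tensor = w.tensor_forward(
            w.SymmetricTensorVolume.isotropic(chi, small_grid), ctx
        )
        assert np.abs(f_scalar.data - f_tensor.data).max() < 1e-10

    def test_zero_tensor(self, small_grid, ctx):
        f = w.tensor_forward(w.SymmetricTensorVolume.zeros(small_grid), ctx)
        assert np.all(f.data == 0)

    def test_cylsym_equivalence(self, small_grid):
        rng = np.random.default_rng(1)
        ctx = w.FieldContext((0.3, 0.4, np.sqrt(1 - 0.09 - 0.16)))
        mask = rng.random(small_grid.shape) < 0.1
        chi_a = w.ScalarVolume(0.05 * mask, small_grid, "ppm")
        n = np.array([1.0, 2.0, 2.0]) / 3.0
        f_cyl = w.cylsym_aniso_field(chi_a, n, ctx)
        T = w.cylsym_tensor(0.0, 1.0, n)
        mats = 0.05 * mask[..., None, None] * T
        X = w.SymmetricTensorVolume.from_matrix_field(mats, small_grid)
        f_ten = w.tensor_forward(X, ctx)
        rel = np.sqrt(
            np.mean((f_cyl.data - f_ten.data) ** 2) / np.mean(f_ten.data**2)
        )
        assert rel < 1e-10

    def test_zero_trace_decomposition(self, small_grid, ctx):
        # traceless part + isotropic part of the trace reproduces the full field
        rng = np.random.default_rng(2)
        X = w.SymmetricTensorVolume(
            rng.normal(0, 0.05, small_grid.shape + (6,)), small_grid
        )
        f_full = w.tensor_forward(X, ctx)
        f_tl = w.tensor_forward(X.traceless_part(), ctx)
        f_tr = w.simulate_iso_field(
            w.ScalarVolume(X.trace() / 3.0, small_grid, "ppm"), ctx
        )
        combo = f_tl.data + f_tr.data
        rel = np.sqrt(np.mean((f_full.data - combo) ** 2) / np.mean(combo**2))
        assert rel < 1e-9

    def test_uniform_sphere_zero_trace_no_internal_shift(self, small_grid, ctx):
        sph = sphere_mask(small_grid, 10.0)
        chi_a = w.ScalarVolume(0.1 * sph, small_grid, "ppm")
        n = np.array([1.0, 2.0, 2.0]) / 3.0
        f = w.cylsym_aniso_field(chi_a, n, ctx)
        assert abs(f.data[sph].mean()) < 0.005 * 0.1 * ctx.larmor_scale

    def test_compact_source_matches_real_space_dipole_tensor_sum(self, ctx):
        # O(N^2) oracle: sum the continuum point-tensor response
        # (3(h.r)(r.Xh) - h.Xh) / (4 pi r^3) over all source voxels
        from conftest import real_space_tensor_oracle, smooth_tensor_blob

        grid = w.GridSpec((24, 24, 24), (1.0, 1.0, 1.0), 2.0)
        X = smooth_tensor_blob(grid, seed=4)
        f = w.tensor_forward(X, ctx)
        pred, shell = real_space_tensor_oracle(X, ctx, r_min=7.0, r_max=11.0)
        num = np.sqrt(np.mean((f.data[shell] - pred[shell]) ** 2))
        den = np.sqrt(np.mean(pred[shell] ** 2))
        assert num / den < 0.10

    def test_cylsym_rejects_non_unit_axis(self, small_grid, ctx):
        chi_a = w.ScalarVolume(np.zeros(small_grid.shape), small_grid, "ppm")
        with pytest.raises(ValueError):
            w.cylsym_aniso_field(chi_a, np.array([1.0, 1.0, 0.0]), ctx)


class TestDualEchoMaps:
    def test_frequency_from_phase_evolution(self, ctx):
        grid = w.GridSpec((8, 8, 8), (1.0, 1.0, 1.0), 1.0)
        e1 = np.ones(grid.shape, dtype=complex)
        e2 = np.exp(1.3j) * np.ones(grid.shape, dtype=complex)
        freq, r2s = w.dual_echo_maps(e1, e2, ctx, grid)
        assert freq.data[0, 0, 0] == pytest.approx(1.3 / (2 * np.pi * 0.013))
        assert freq.data[0, 0, 0] == pytest.approx(15.915, abs=1e-3)
        assert np.all(r2s.data == pytest.approx(0.0))  # equal magnitudes

    def test_r2star_from_log_decay(self, ctx):
        grid = w.GridSpec((8, 8, 8), (1.0, 1.0, 1.0), 1.0)
        e1 = np.ones(grid.shape, dtype=complex)
        e2 = np.exp(-1.0) * np.ones(grid.shape, dtype=complex)
        _, r2s = w.dual_echo_maps(e1, e2, ctx, grid)
        assert r2s.data[0, 0, 0] == pytest.approx(1.0 / 0.013)
        assert r2s.data[0, 0, 0] == pytest.approx(76.92, abs=0.01)

    def test_zero_magnitude_flagged_not_infinite(self, ctx):
        grid = w.GridSpec((8, 8, 8), (1.0, 1.0, 1.0), 1.0)
        e1 = np.ones(grid.shape, dtype=complex)
        e2 = np.ones(grid.shape, dtype=complex)
        e2[0, 0, 0] = 0.0
        freq, r2s = w.dual_echo_maps(e1, e2, ctx, grid)
        assert not freq.mask[0, 0, 0]
        assert np.all(np.isfinite(freq.data)) and np.all(np.isfinite(r2s.data))


class TestOrientationHandling:
    def test_axis_from_polar_angles(self, ctx):
        n0 = w.axis_from_polar(0.0, 0.0, ctx)
        assert np.allclose(n0, ctx.h)
        n90 = w.axis_from_polar(90.0, 0.0, ctx)
        assert abs(np.dot(n90, ctx.h)) < 1e-12
        assert np.linalg.norm(n90) == pytest.approx(1.0)
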