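"""External-field bulk fitting and the sin^2 residual orientation model."""

import numpy as np
import pytest
from scipy import ndimage, stats

import wmchi as w

from conftest import sphere_mask


@pytest.fixture(scope="module")
def grid():
    return w.GridSpec((32, 32, 32), (1.0, 1.0, 1.0), 2.0)


def brute_force_dilate(mask, r):
    """Oracle: voxels within Euclidean distance r of the set."""
    out = np.zeros_like(mask)
    pts = np.argwhere(mask)
    idx = np.indices(mask.shape).reshape(3, -1).T
    for v in idx:
        d2 = ((pts - v) ** 2).sum(axis=1).min()
        if d2 <= r**2 + 1e-9:
            out[tuple(v)] = True
    return out


class TestShellMask:
    def test_single_voxel_matches_brute_force(self):
        mask = np.zeros((24, 24, 24), dtype=bool)
        mask[12, 12, 12] = True
        shell = w.shell_mask(mask, dilate_out=5, dilate_in=2)
        oracle = brute_force_dilate(mask, 5) & ~brute_force_dilate(mask, 2)
        assert np.array_equal(shell, oracle)

    def test_equal_dilations_give_empty_shell(self):
        mask = np.zeros((16, 16, 16), dtype=bool)
        mask[8, 8, 8] = True
        assert not w.shell_mask(mask, dilate_out=3, dilate_in=3).any()

    def test_disjoint_from_inner_dilation(self, grid):
        mask = sphere_mask(grid, 4.0)
        shell = w.shell_mask(mask, 8, 1)
        inner = w.shell_mask(mask, 1, 0) | mask
        assert not (shell & inner).any()

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            w.shell_mask(np.zeros((16, 16, 16), dtype=bool))


class TestFitQualify:
    def test_threshold_rule(self, grid):
        shell = sphere_mask(grid, 6.0)
        rng = np.random.default_rng(0)
        r2s_data = rng.uniform(0, 30, grid.shape)
        r2s = w.ScalarVolume(r2s_data, grid, "s^-1")
        out = w.fit_qualify(shell, r2s, 15.0)
        assert np.array_equal(out, shell & (r2s_data < 15.0))
        # all-zero R2* keeps the shell; uniform 20/s empties it
        zeros = w.ScalarVolume(np.zeros(grid.shape), grid, "s^-1")
        assert np.array_equal(w.fit_qualify(shell, zeros), shell)
        high = w.ScalarVolume(np.full(grid.shape, 20.0), grid, "s^-1")
        assert not w.fit_qualify(shell, high).any()


class TestBulkFit:
    def make_data(self, grid, chi_i, chi_a, n_orient=4, internal_offset=0.0):
        mask = sphere_mask(grid, 4.0)
        x, y, z = grid.coords()
        cyl = mask  # compact blob sample; geometry is irrelevant to consistency
        meas, iso, aniso = [], [], []
        axis = np.array([0.0, 0.0, 1.0])
        for k in range(n_orient):
            th = np.deg2rad(k * 30.0)
            ctx = w.FieldContext((np.sin(th), 0.0, np.cos(th)))
            ui = w.simulate_iso_field(w.ScalarVolume(cyl * 1.0, grid, "ppm"), ctx)
            ua = w.cylsym_aniso_field(w.ScalarVolume(cyl * 1.0, grid, "ppm"), axis, ctx)
            m = chi_i * ui.data + chi_a * ua.data + internal_offset * cyl
            meas.append(w.ScalarVolume(m, grid, "Hz"))
            iso.append(ui.with_data(ui.data, "Hz/ppm"))
            aniso.append(ua.with_data(ua.data, "Hz/ppm"))
        shell = w.shell_mask(mask, 8, 1)
        return meas, iso, aniso, shell, mask

    def test_exact_recovery_noiseless(self, grid):
        meas, iso, aniso, shell, _ = self.make_data(grid, -0.08, 0.011)
        res = w.BulkSusceptometry(meas, iso, aniso, shell).fit()
        assert res.chi_iso == pytest.approx(-0.08, abs=1e-10)
        assert res.chi_aniso == pytest.approx(0.011, abs=1e-10)
        assert abs(res.param_correlation) <= 1.0

    def test_internal_offsets_do_not_bias_fit(self, grid):
        meas0, iso, aniso, shell, _ = self.make_data(grid, -0.08, 0.011)
        meas1, *_ = self.make_data(grid, -0.08, 0.011, internal_offset=7.0)
        r0 = w.BulkSusceptometry(meas0, iso, aniso, shell).fit()
        r1 = w.BulkSusceptometry(meas1, iso, aniso, shell).fit()
        assert r1.chi_iso == pytest.approx(r0.chi_iso, abs=1e-10)
        assert r1.chi_aniso == pytest.approx(r0.chi_aniso, abs=1e-10)

    def test_modifying_interior_leaves_fit_unchanged(self, grid):
        meas, iso, aniso, shell, mask = self.make_data(grid, -0.08, 0.011)
        r0 = w.BulkSusceptometry(meas, iso, aniso, shell).fit()
        from wmchi.morphology import dilate

        interior = dilate(mask, 1)
        for m in meas:
            m.data[interior] += 100.0
        r1 = w.BulkSusceptometry(meas, iso, aniso, shell).fit()
        assert r1.chi_iso == r0.chi_iso and r1.chi_aniso == r0.chi_aniso

    def test_isotropic_only_flag_and_f_test(self, grid):
        meas, iso, aniso, shell, _ = self.make_data(grid, -0.08, 0.011)
        rng = np.random.default_rng(1)
        for m in meas:  # noise so the F statistic is finite
            m.data += rng.normal(0, 0.05, m.data.shape)
        model = w.BulkSusceptometry(meas, iso, aniso, shell)
        full = model.fit()
        red = model.fit(isotropic_only=True)
        assert red.chi_aniso == 0.0
        assert red.rss >= full.rss
        f_stat, p = full.compare_f_test(red)
        assert f_stat > 0 and p < 0.001  # real anisotropy detected

    def test_noisy_replicates_recover_truth_within_errors(self, grid):
        # parameter recovery with sigma = 0.5 Hz shell noise
        meas, iso, aniso, shell, _ = self.make_data(grid, -0.08152, 0.01128)
        rng = np.random.default_rng(7)
        chis_i, chis_a, ses_i, ses_a = [], [], [], []
        for _ in range(30):
            noisy = [
                w.ScalarVolume(m.data + rng.normal(0, 0.5, m.data.shape), grid, "Hz")
                for m in meas
            ]
            r = w.BulkSusceptometry(noisy, iso, aniso, shell).fit()
            chis_i.append(r.chi_iso)
            chis_a.append(r.chi_aniso)
            ses_i.append(r.bse["chi_iso"])
            ses_a.append(r.bse["chi_aniso"])
        n = len(chis_i)
        assert abs(np.mean(chis_i) + 0.08152) < 2 * np.std(chis_i) / np.sqrt(n) + 1e-4
        assert abs(np.mean(chis_a) - 0.01128) < 2 * np.std(chis_a) / np.sqrt(n) + 1e-4
        # reported SE consistent with the empirical scatter
        assert 1 / 1.5 < np.mean(ses_i) / np.std(chis_i) < 1.5
        assert 1 / 1.5 < np.mean(ses_a) / np.std(chis_a) < 1.5

    def test_rank_deficient_design_raises(self, grid):
        mask = sphere_mask(grid, 4.0)
        shell = w.shell_mask(mask, 6, 1)
        ctx = w.FieldContext()
        ui = w.simulate_iso_field(w.ScalarVolume(mask * 1.0, grid, "ppm"), ctx)
        ui = ui.with_data(ui.data, "Hz/ppm")
        # anisotropic column identical to the isotropic one -> collinear
        with pytest.raises(np.linalg.LinAlgError):
            w.BulkSusceptometry([ui.with_data(ui.data, "Hz")], [ui], [ui], shell).fit()

    def test_summary_mentions_estimates(self, grid):
        meas, iso, aniso, shell, _ = self.make_data(grid, -0.08, 0.011)
        res = w.BulkSusceptometry(meas, iso, aniso, shell).fit()
        text = res.summary()
        assert "chi_iso" in text and "chi_aniso" in text


class TestResidualOps:
    def test_residual_map_is_subtraction(self, grid):
        rng = np.random.default_rng(0)
        a = w.ScalarVolume(rng.normal(size=grid.shape), grid, "Hz")
        b = w.ScalarVolume(rng.normal(size=grid.shape), grid, "Hz")
        r = w.residual_map(a, b)
        assert np.array_equal(r.data, a.data - b.data)
        assert np.all(w.residual_map(a, a).data == 0)

    def test_roi_mean_residual_constant_field(self, grid):
        mask = sphere_mask(grid, 6.0)
        f = w.ScalarVolume(np.full(grid.shape, 3.25), grid, "Hz")
        mu, sd = w.roi_mean_residual(f, mask, erode_vox=1)
        assert mu == pytest.approx(3.25)
        assert sd == pytest.approx(0.0)

    def test_roi_erosion_matches_brute_force(self):
        mask = np.zeros((20, 20, 20), dtype=bool)
        mask[6:14, 6:14, 6:14] = True
        from wmchi.morphology import erode

        eroded = erode(mask, 1)
        dist = ndimage.distance_transform_edt(mask)
        assert np.array_equal(eroded, dist > 1 + 1e-9)
        assert eroded.sum() == 6**3

    def test_empty_erosion_raises(self, grid):
        mask = np.zeros(grid.shape, dtype=bool)
        mask[16, 16, 16] = True
        f = w.ScalarVolume(np.zeros(grid.shape), grid, "Hz")
        with pytest.raises(ValueError):
            w.roi_mean_residual(f, mask, erode_vox=1)


class TestOrientationModel:
    def test_exact_recovery_of_generating_coefficients(self):
        thetas = w.ten_orientation_angles()
        a_true, b_true = -5.59, 4.88
        y = a_true * np.sin(np.deg2rad(thetas)) ** 2 + b_true
        res = w.OrientationResidualModel(thetas, y).fit()
        assert res.amplitude == pytest.approx(a_true, abs=1e-12)
        assert res.offset == pytest.approx(b_true, abs=1e-12)
        assert res.rss == pytest.approx(0.0, abs=1e-20)

    def test_constant_data_gives_zero_amplitude(self):
        thetas = np.array([0.0, 30.0, 60.0, 90.0])
        res = w.OrientationResidualModel(thetas, np.full(4, 2.5)).fit()
        assert res.amplitude == pytest.approx(0.0, abs=1e-12)
        assert res.offset == pytest.approx(2.5)

    def test_two_point_design_is_exact_interpolation(self):
        res = w.OrientationResidualModel([0.0, 90.0], [4.88, -0.71]).fit()
        assert res.offset == pytest.approx(4.88)
        assert res.amplitude == pytest.approx(-0.71 - 4.88)
        assert np.allclose(res.fittedvalues, [4.88, -0.71])

    def test_identical_angles_raise(self):
        with pytest.raises(np.linalg.LinAlgError):
            w.OrientationResidualModel([45.0, 45.0, 135.0], [1.0, 2.0, 3.0])

    def test_axial_symmetry_of_design(self):
        # theta and 180 - theta produce identical predictions
        y = [1.0, 2.0, 3.0]
        r1 = w.OrientationResidualModel([10.0, 50.0, 90.0], y).fit()
        r2 = w.OrientationResidualModel([170.0, 130.0, 90.0], y).fit()
        assert r1.amplitude == pytest.approx(r2.amplitude)
        assert r1.offset == pytest.approx(r2.offset)


class TestNestedFTest:
    def test_equal_rss_gives_f_zero_p_one(self):
        f_stat, p = w.nested_f_test(5.0, 1, 5.0, 2, 20)
        assert f_stat == 0.0
        assert p == pytest.approx(1.0)

    def test_f_one_tail_probability(self):
        # F = 1 with df (1, 10): upper tail ~ 0.341
        rss_full, df = 10.0, (1, 10)
        rss_red = rss_full + rss_full / 10.0
        f_stat, p = w.nested_f_test(rss_red, 1, rss_full, 2, 12)
        assert f_stat == pytest.approx(1.0)
        assert p == pytest.approx(stats.f.sf(1.0, 1, 10), abs=1e-12)
        assert p == pytest.approx(0.341, abs=0.002)

    def test_invalid_degrees_of_freedom(self):
        with pytest.raises(ValueError):
            w.nested_f_test(5.0, 2, 4.0, 2, 20)
        with pytest.raises(ValueError):
            w.nested_f_test(5.0, 1, 4.0, 2, 2)
        with pytest.raises(ValueError):
            w.nested_f_test(3.0, 1, 4.0, 2, 20)
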