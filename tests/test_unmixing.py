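"""Optical density conversion and non-negative least-squares unmixing."""

import numpy as np
import pytest

import spectracell as sc
from spectracell.cube import MultispectralCube
from spectracell.synthetic import EndmemberSet
from spectracell.unmixing import nnls_batch, reconstruction_residual


def grid_oracle_sse(S, y, lo=0.0, hi=1.0, step=1e-3):
    """Brute-force SSE minimum over a ≥ 0 grid (2 endmembers)."""
    grid = np.arange(lo, hi + step / 2, step)
    a1, a2 = np.meshgrid(grid, grid, indexing="ij")
    recon = a1[..., None] * S[0] + a2[..., None] * S[1]
    sse = ((recon - y) ** 2).sum(axis=-1)
    return sse.min()


class TestOpticalDensity:
    def _cube(self, values, i0=255.0):
        data = np.asarray(values, dtype=float).reshape(1, 1, -1)
        return MultispectralCube(data, np.arange(data.shape[2]) + 500.0,
                                 "brightfield", i0=i0)

    def test_tenth_of_i0_gives_od_1(self):
        od = sc.to_optical_density(self._cube([25.5]))
        assert od.data[0, 0, 0] == pytest.approx(1.0)

    def test_blank_pixel_gives_od_0(self):
        od = sc.to_optical_density(self._cube([255.0]))
        assert od.data[0, 0, 0] == pytest.approx(0.0)

    def test_zero_intensity_clamps_to_od_max(self):
        od = sc.to_optical_density(self._cube([0.0]))
        assert od.data[0, 0, 0] == pytest.approx(3.0)

    def test_nonpositive_i0_rejected(self):
        with pytest.raises(ValueError, match="i0"):
            sc.to_optical_density(self._cube([10.0]), i0=0.0)

    def test_fluorescence_cube_rejected(self):
        cube = MultispectralCube(np.ones((1, 1, 1)), [500.0], "fluorescence")
        with pytest.raises(ValueError, match="brightfield"):
            sc.to_optical_density(cube)


class TestUnmixPixel:
    def test_orthonormal_basis_reads_off_coefficients(self):
        S = np.eye(2)
        np.testing.assert_allclose(sc.unmix_pixel([0.3, 0.7], S), [0.3, 0.7])

    def test_consistent_system_solved_exactly(self):
        """e1=(1,0.5), e2=(0.2,1), y=(0.42,0.30) → a=(0.4,0.1)."""
        S = np.array([[1.0, 0.5], [0.2, 1.0]])
        y = np.array([0.42, 0.30])
        a = sc.unmix_pixel(y, S)
        np.testing.assert_allclose(a, [0.4, 0.1], atol=1e-10)
        # substitution check and grid-oracle check
        np.testing.assert_allclose(S.T @ a, y, atol=1e-10)
        sse = ((S.T @ a - y) ** 2).sum()
        assert sse <= grid_oracle_sse(S, y) + 1e-6

    def test_active_set_clamps_negative_component(self):
        """e1=(1,1), e2=(1,0), y=(0,0.5): NNLS → (0.25, 0)."""
        S = np.array([[1.0, 1.0], [1.0, 0.0]])
        y = np.array([0.0, 0.5])
        a = sc.unmix_pixel(y, S)
        np.testing.assert_allclose(a, [0.25, 0.0], atol=1e-10)
        sse = ((S.T @ a - y) ** 2).sum()
        assert sse <= grid_oracle_sse(S, y) + 1e-6

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            sc.unmix_pixel([np.nan, 1.0], np.eye(2))

    def test_nnls_beats_grid_oracle_on_random_pixels(self, rng):
        """NNLS SSE ≤ grid-oracle SSE on 100 random 2-endmember pixels."""
        S = np.abs(rng.random((2, 4))) + 0.1
        S = S / S.max(axis=1, keepdims=True)
        for _ in range(100):
            y = rng.random(4)
            a = sc.unmix_pixel(y, S)
            assert np.all(a >= 0)
            sse = ((S.T @ a - y) ** 2).sum()
            assert sse <= grid_oracle_sse(S, y, hi=2.0, step=2e-3) + 1e-6

    def test_scaling_equivariance_consistent_case(self):
        S = np.array([[1.0, 0.5, 0.1], [0.2, 1.0, 0.3]])
        a_true = np.array([0.3, 0.6])
        y = S.T @ a_true
        for c in (0.5, 2.0, 7.0):
            np.testing.assert_allclose(
                sc.unmix_pixel(c * y, S), c * a_true, atol=1e-9
            )


class TestBatchSolver:
    def test_matches_lawson_hanson_on_random_problems(self, rng):
        """Vectorized active-set enumeration equals scipy NNLS."""
        import scipy.optimize

        for k, b in [(2, 4), (3, 8), (4, 6)]:
            S = np.abs(rng.random((k, b))) + 0.05
            Y = rng.standard_normal((200, b)) * 0.5 + 0.3
            A, resid = nnls_batch(S, Y)
            assert np.all(A >= 0)
            for i in range(0, 200, 17):
                a_ref, r_ref = scipy.optimize.nnls(S.T, Y[i])
                sse = ((S.T @ A[i] - Y[i]) ** 2).sum()
                assert sse <= r_ref**2 + 1e-9
                assert resid[i] == pytest.approx(np.sqrt(sse), abs=1e-9)


class TestUnmixCube:
    def _scene(self, endmembers, noise, seed=6):
        config = sc.SceneConfig(image_shape=(128, 128), margin_px=8,
                                control_band_px=16, follicle_radius_px=30,
                                t_zone_width_px=16, noise_sd_frac=noise, seed=seed)
        return sc.generate_scene(config, endmembers)

    def test_background_cube_gives_zero_abundance(self, endmembers):
        od = sc.ODCube(np.zeros((4, 4, endmembers.n_bands)),
                       endmembers.wavelengths_nm, i0=255.0)
        amap = sc.unmix_cube(od, endmembers)
        np.testing.assert_array_equal(amap.data, 0.0)
        np.testing.assert_array_equal(amap.residual, 0.0)

    def test_wavelength_mismatch_rejected(self, endmembers):
        od = sc.ODCube(np.zeros((2, 2, endmembers.n_bands)),
                       endmembers.wavelengths_nm + 3.0, i0=255.0)
        with pytest.raises(ValueError, match="wavelength"):
            sc.unmix_cube(od, endmembers)

    def test_noisy_recovery_within_propagated_bound(self, endmembers):
        """Abundance RMSE stays below 5× the least-squares noise bound.

        For OD noise ~ N(0, σ²) i.i.d. per band, the LS estimator error
        covariance is σ²(S Sᵀ)⁻¹; the bound is the RMS of its diagonal.
        """
        truth, cube = self._scene(endmembers, noise=0.01)
        od = sc.to_optical_density(cube)
        amap = sc.unmix_cube(od, endmembers)
        # OD noise sd at intensity I: σ_I/(I ln10); use background level I0
        sigma_od = 0.01 / np.log(10)
        S = endmembers.spectra
        cov = sigma_od**2 * np.linalg.inv(S @ S.T)
        bound = float(np.sqrt(np.mean(np.diag(cov))))
        err = amap.data - truth.abundances
        # restrict to pixels where the linear OD approximation holds
        mask = truth.abundances.sum(axis=2) < 1.0
        rmse = float(np.sqrt(np.mean(err[mask] ** 2)))
        assert rmse < 5 * bound

    def test_residual_monotone_in_noise(self, endmembers):
        means = []
        for noise in (0.01, 0.02):
            truth, cube = self._scene(endmembers, noise=noise)
            od = sc.to_optical_density(cube)
            amap = sc.unmix_cube(od, endmembers)
            means.append(reconstruction_residual(amap, od).mean)
        assert means[1] > means[0]

    def test_near_collinear_library_warns(self, endmembers):
        theta = np.radians(1.0)
        spectra = np.vstack([[1.0, 0.0], [np.cos(theta), np.sin(theta)]])
        em = EndmemberSet(["a", "b"], [500, 600],
                          spectra / spectra.max(axis=1, keepdims=True))
        lib = sc.SpectralLibrary(endmembers=em)
        od = sc.ODCube(np.zeros((2, 2, 2)), np.array([500.0, 600.0]), i0=255.0)
        with pytest.warns(UserWarning, match="collinear"):
            sc.unmix_cube(od, lib)


class TestSpectralUnmixer:
    def test_fit_from_single_stains_and_transform(self, endmembers):
        stains = [
            (name, sc.single_stain_cube(name, endmembers, seed=40 + i))
            for i, name in enumerate(endmembers.names)
        ]
        unmixer = sc.SpectralUnmixer(i0=255.0).fit(stains)
        assert sorted(unmixer.library_.names) == sorted(endmembers.names)
        config = sc.SceneConfig(image_shape=(128, 128), margin_px=8,
                                control_band_px=16, follicle_radius_px=30,
                                t_zone_width_px=16, seed=8)
        truth, cube = sc.generate_scene(config, endmembers)
        amap = unmixer.transform(cube)
        assert amap.data.shape == (128, 128, 3)
        assert np.all(amap.data >= 0)
        # built library is close enough to truth for faithful recovery
        err = np.abs(amap.data - truth.abundances[..., [
            endmembers.index(n) for n in amap.endmember_names]])
        assert np.median(err) < 0.02

    def test_unfitted_transform_rejected(self, endmembers):
        cube = sc.MultispectralCube(np.full((2, 2, endmembers.n_bands), 255.0),
                                    endmembers.wavelengths_nm, "brightfield", i0=255.0)
        with pytest.raises(RuntimeError, match="not fitted"):
            sc.SpectralUnmixer().transform(cube)

    def test_get_set_params(self):
        unmixer = sc.SpectralUnmixer(i0=200.0)
        assert unmixer.get_params()["i0"] == 200.0
        unmixer.set_params(od_max=2.5)
        assert unmixer.od_max == 2.5
        with pytest.raises(ValueError, match="invalid parameter"):
            unmixer.set_params(bogus=1)


class TestReconstructionResidual:
    def test_orthogonal_spectrum_residual_is_norm(self):
        em = EndmemberSet(["a"], [500, 600], np.array([[1.0, 0.0]]))
        y = np.array([0.0, 0.5])
        od = sc.ODCube(y.reshape(1, 1, 2), np.array([500.0, 600.0]), i0=255.0)
        amap = sc.unmix_cube(od, em)
        assert amap.data[0, 0, 0] == 0.0
        assert amap.residual[0, 0] == pytest.approx(0.5)
        summary = reconstruction_residual(amap, od)
        assert summary.mean == pytest.approx(0.5)

    def test_exact_data_residual_near_zero(self, endmembers):
        a_true = np.array([0.3, 0.2, 0.5])
        od_vals = (a_true @ endmembers.spectra).reshape(1, 1, -1)
        od = sc.ODCube(np.tile(od_vals, (6, 6, 1)), endmembers.wavelengths_nm, i0=255.0)
        amap = sc.unmix_cube(od, endmembers)
        summary = reconstruction_residual(amap, od)
        assert summary.mean < 1e-9
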