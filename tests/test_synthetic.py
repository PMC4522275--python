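"""Synthetic scene generator: spectra, layout, forward model, determinism."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

import spectracell as sc
from spectracell.synthetic import (
    REGION_CODES,
    SceneError,
    spectral_angle_deg,
)


class TestEndmemberGeneration:
    def test_single_endmember_is_peak_normalized(self):
        em = sc.generate_endmember_set(8, ["a"], min_pair_angle_deg=20)
        assert em.spectra.shape == (1, 8)
        assert em.spectra.max() == pytest.approx(1.0, abs=1e-12)
        assert np.all(em.spectra >= 0)

    @pytest.mark.parametrize("angle", [5.0, 8.0, 15.0])
    def test_similar_pair_angle_is_honored(self, angle):
        em = sc.generate_endmember_set(
            16, ["a", "b", "c"], min_pair_angle_deg=25,
            similar_pair=("a", "b", angle), seed=3,
        )
        achieved = spectral_angle_deg(em.spectra[0], em.spectra[1])
        assert abs(achieved - angle) <= 0.5
        # the remaining pairs respect the floor
        angles = em.pairwise_angles_deg()
        assert angles[0, 2] >= 25 and angles[1, 2] >= 25

    def test_orthogonal_vectors_have_angle_90(self):
        a = np.array([1.0, 0.0, 0.0, 0.5])
        b = np.array([0.0, 1.0, 0.3, 0.0])
        assert spectral_angle_deg(a, b) == pytest.approx(90.0)

    def test_infeasible_request_reports_achieved_angles(self):
        with pytest.raises(SceneError, match="angles"):
            # 2 bands cannot hold 2 non-negative spectra 90° apart from a
            # third while keeping a 5° pair
            sc.generate_endmember_set(
                2, ["a", "b"], min_pair_angle_deg=90,
                similar_pair=None, seed=0, max_tries=5,
            )

    def test_more_endmembers_than_bands_rejected(self):
        with pytest.raises(SceneError):
            sc.generate_endmember_set(2, ["a", "b", "c"])

    def test_default_library_has_8_degree_red_pair(self, endmembers):
        angles = endmembers.pairwise_angles_deg()
        i = endmembers.index("nuclear_red")
        j = endmembers.index("warp_red")
        assert angles[i, j] == pytest.approx(8.0, abs=0.5)


class TestRenderCube:
    def test_single_pixel_brightfield_closed_form(self):
        """I = I0·10^−(a·s): a=1 on s=(0.5,1), I0=255 → (80.64, 25.5)."""
        em = sc.EndmemberSet(
            names=["x"], wavelengths_nm=[500, 600],
            spectra=np.array([[0.5, 1.0]]),
        )
        config = sc.SceneConfig(image_shape=(8, 8), margin_px=1, control_band_px=0,
                                n_follicles=0, noise_sd_frac=0.0,
                                cell_density={r: 0.0 for r in ("follicle", "t_zone", "stroma", "other")},
                                nuclear_channel="x", lineage_channel="x",
                                tetraspanin_channel="x")
        truth, _ = sc.generate_scene(config, em)
        truth.abundances[0, 0, 0] = 1.0
        cube = sc.render_cube(truth, em, config)
        np.testing.assert_allclose(
            cube.data[0, 0], [255 * 10**-0.5, 25.5], rtol=1e-6
        )

    def test_zero_absorbance_gives_white_reference(self, endmembers):
        config = sc.SceneConfig(
            image_shape=(16, 16), margin_px=2, control_band_px=0, n_follicles=0,
            noise_sd_frac=0.0,
            cell_density={r: 0.0 for r in ("follicle", "t_zone", "stroma", "other")},
        )
        truth, cube = sc.generate_scene(config, endmembers)
        assert truth.n_cells() == 0
        np.testing.assert_allclose(cube.data, config.i0)

    def test_fluorescence_is_linear_with_autofluorescence(self):
        em = sc.EndmemberSet(
            names=["s1", "s2"], wavelengths_nm=[500, 600, 700],
            spectra=np.array([[1.0, 0.5, 0.0], [0.0, 0.5, 1.0]]),
            mode="fluorescence",
        )
        config = sc.SceneConfig(image_shape=(4, 4), margin_px=0, control_band_px=0,
                                n_follicles=0, mode="fluorescence", noise_sd_frac=0.0,
                                af_amplitude=2.0,
                                cell_density={r: 0.0 for r in ("follicle", "t_zone", "stroma", "other")},
                                nuclear_channel="s1", lineage_channel="s1",
                                tetraspanin_channel="s2")
        truth, _ = sc.generate_scene(config, em)
        truth.abundances[0, 0] = [2.0, 3.0]
        cube = sc.render_cube(truth, em, config)
        af = 2.0 * sc.synthetic.autofluorescence_spectrum(em.wavelengths_nm)
        expected = 2.0 * em.spectra[0] + 3.0 * em.spectra[1] + af
        np.testing.assert_allclose(cube.data[0, 0], expected, rtol=1e-6)

    def test_mode_mismatch_rejected(self, endmembers):
        config = sc.SceneConfig(mode="fluorescence")
        with pytest.raises(ValueError, match="mode"):
            sc.generate_scene(config, endmembers)


class TestGenerateScene:
    def test_determinism_same_seed_bit_identical(self, endmembers):
        config = sc.SceneConfig(image_shape=(192, 192), margin_px=16,
                                control_band_px=32, follicle_radius_px=40,
                                t_zone_width_px=24, seed=9)
        t1, c1 = sc.generate_scene(config, endmembers)
        t2, c2 = sc.generate_scene(config, endmembers)
        pd.testing.assert_frame_equal(t1.cells, t2.cells)
        np.testing.assert_array_equal(c1.data, c2.data)
        np.testing.assert_array_equal(t1.region_mask, t2.region_mask)

    def test_bright_count_within_binomial_interval(self, default_scene):
        """Follicle bright count lies in the central 99% binomial interval."""
        truth, _ = default_scene
        follicle = truth.cells[truth.cells["region"] == "follicle"]
        n = len(follicle)
        k = int((follicle["tet_class"] == "bright").sum())
        lo, hi = scipy.stats.binom.interval(0.99, n, 0.85)
        assert lo <= k <= hi

    def test_region_composition_converges(self, endmembers):
        """Lineage-positive fractions approach the configured values as n
        grows (pooled over scenes so each region has ≥1500 cells)."""
        config = sc.SceneConfig(seed=0)
        cells = pd.concat(
            [
                sc.generate_scene(sc.SceneConfig(seed=s), endmembers)[0].cells
                for s in (100, 101, 102, 103, 104, 105)
            ],
            ignore_index=True,
        )
        for region in ("follicle", "t_zone", "stroma"):
            sub = cells[cells["region"] == region]
            assert len(sub) >= 1800
            frac = (sub["lineage_class"] == "lin_pos").mean()
            assert frac == pytest.approx(
                config.lineage_positive_fraction[region], abs=0.03
            )

    def test_cells_lie_in_their_region(self, default_scene):
        truth, _ = default_scene
        for row in truth.cells.sample(200, random_state=0).itertuples(index=False):
            assert truth.region_name_at(row.y, row.x) == row.region

    def test_region_mask_labels_complete(self, default_scene):
        truth, _ = default_scene
        assert set(np.unique(truth.region_mask)) == set(REGION_CODES.values())

    def test_infeasible_density_raises(self, endmembers):
        config = sc.SceneConfig(
            image_shape=(128, 128), margin_px=8, control_band_px=0,
            n_follicles=0,
            cell_density={"follicle": 0, "t_zone": 0, "stroma": 60.0, "other": 0},
        )
        with pytest.raises(SceneError, match="density"):
            sc.generate_scene(config, endmembers)

    def test_roundtrip_recovery_noise_free(self, endmembers):
        """Render → OD → unmix recovers true abundances to 1e-6."""
        config = sc.SceneConfig(image_shape=(128, 128), margin_px=8,
                                control_band_px=16, follicle_radius_px=30,
                                t_zone_width_px=16, noise_sd_frac=0.0, seed=2)
        truth, cube = sc.generate_scene(config, endmembers)
        od = sc.to_optical_density(cube)
        amap = sc.unmix_cube(od, endmembers)
        assert np.max(np.abs(amap.data - truth.abundances)) < 1e-6
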