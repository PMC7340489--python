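import math
from datetime import datetime, timezone

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_test_scene
from oracles import cov_corr_oracle, glcm_oracle, haralick_oracle, moments_oracle, vi_oracle
from parcelscope import field_stats as fs
from parcelscope.errors import DegeneracyError, SchemaError
from parcelscope.masks import Mask
from parcelscope.raster_io import FieldPolygon, SceneMetadata


def square_field(x0=3.0, y0=3.0, side=6.0, field_id="F1", crop="maize"):
    return FieldPolygon(
        field_id, crop, [(x0, y0), (x0 + side, y0), (x0 + side, y0 + side), (x0, y0 + side)]
    )


class TestBufferField:
    def test_zero_buffer_identity(self):
        poly = square_field()
        assert fs.buffer_field(poly, 0.0) is poly

    def test_square_shrinks_exactly(self):
        inner = fs.buffer_field(square_field(0, 0, 10), 2.0)
        assert inner is not None
        assert inner.shapely().area == pytest.approx(36.0)

    def test_full_collapse_returns_none(self):
        assert fs.buffer_field(square_field(0, 0, 10), 5.0) is None


class TestFieldPixels:
    def _scene(self):
        # 12x12 px, 1 m grid, origin (0, 12): pixel centres at 0.5 .. 11.5
        return make_test_scene(width=12, height=12, gsd=1.0, origin=(0.0, 12.0))

    def test_inner_square_pixel_count(self):
        total, used = fs.field_pixels(self._scene(), square_field(3, 3, 6))
        assert total.sum() == 36 and used.sum() == 36

    def test_buffered_10m_square_on_1m_grid_counts_36(self):
        scene = make_test_scene(width=14, height=14, gsd=1.0, origin=(0.0, 14.0))
        inner = fs.buffer_field(square_field(1, 1, 10), 2.0)
        total, _ = fs.field_pixels(scene, inner)
        assert total.sum() == 36

    def test_all_true_mask_empties_used(self):
        scene = self._scene()
        mask = Mask(np.ones((12, 12), dtype=bool), "cloud", "S")
        total, used = fs.field_pixels(scene, square_field(3, 3, 6), mask)
        assert total.sum() == 36 and used.sum() == 0

    def test_polygon_outside_scene_is_empty(self):
        total, used = fs.field_pixels(self._scene(), square_field(100, 100, 6))
        assert total.sum() == 0 and used.sum() == 0

    def test_crs_mismatch_rejected(self):
        with pytest.raises(SchemaError):
            fs.field_pixels(self._scene(), square_field(), poly_crs="EPSG:32636")


class TestSpectralMoments:
    def test_symmetric_triple(self):
        stats, _, _ = fs.spectral_moments({"red": np.array([0.1, 0.2, 0.3])})
        mean, var, skew = stats["red"]
        assert mean == pytest.approx(0.2)
        assert var == pytest.approx(0.00666667, abs=1e-7)
        assert skew == pytest.approx(0.0, abs=1e-12)

    def test_constant_band_skew_undefined(self):
        stats, _, _ = fs.spectral_moments({"red": np.full(10, 0.3)})
        mean, var, skew = stats["red"]
        assert var == 0.0 and math.isnan(skew)

    def test_empty_input_all_undefined(self):
        stats, corr, cov = fs.spectral_moments({"red": np.array([]), "nir1": np.array([])})
        assert all(math.isnan(v) for v in stats["red"])
        assert math.isnan(corr[("red", "nir1")])

    def test_ragged_lengths_rejected(self):
        with pytest.raises(SchemaError):
            fs.spectral_moments({"red": np.zeros(3), "nir1": np.zeros(4)})

    def test_matches_definition_oracle_on_random_bands(self):
        rng = np.random.default_rng(0)
        x, y = rng.uniform(0, 1, 1000), rng.uniform(0, 1, 1000)
        stats, corr, cov = fs.spectral_moments({"red": x, "nir1": y})
        for role, data in (("red", x), ("nir1", y)):
            em, ev, es = moments_oracle(data)
            m, v, s = stats[role]
            assert m == pytest.approx(em, abs=1e-12)
            assert v == pytest.approx(ev, abs=1e-12)
            assert s == pytest.approx(es, abs=1e-9)
        ecov, ecorr = cov_corr_oracle(x, y)
        assert cov[("red", "nir1")] == pytest.approx(ecov, abs=1e-12)
        assert corr[("red", "nir1")] == pytest.approx(ecorr, abs=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.permutations(list(range(20))))
    def test_permutation_invariance(self, perm):
        base = np.linspace(0.1, 0.9, 20)
        a = fs.spectral_moments({"red": base})[0]["red"]
        b = fs.spectral_moments({"red": base[perm]})[0]["red"]
        assert a == pytest.approx(b, abs=1e-12)


class TestVegetationIndices:
    def test_nir_equals_red_forces_zero_indices(self):
        out = fs.vegetation_indices(
            {"blue": np.array([0.05]), "green": np.array([0.1]),
             "red": np.array([0.2]), "nir1": np.array([0.2])}
        )
        assert out["ndvi"][0] == pytest.approx(0.0)
        assert out["simple_ratio"][0] == pytest.approx(1.0)
        assert out["msavi2"][0] == pytest.approx(0.0, abs=1e-12)

    def test_ndvi_direct_value(self):
        out = fs.vegetation_indices({"red": np.array([0.1]), "nir1": np.array([0.5])})
        assert out["ndvi"][0] == pytest.approx(2 / 3, abs=1e-9)

    def test_evi_worked_example(self):
        out = fs.vegetation_indices(
            {"blue": np.array([0.05]), "red": np.array([0.1]), "nir1": np.array([0.5])}
        )
        assert out["evi"][0] == pytest.approx(2.5 * 0.4 / (0.5 + 0.6 - 0.375 + 1), abs=1e-9)

    def test_absent_roles_skip_indices(self):
        out = fs.vegetation_indices({"red": np.array([0.1]), "nir1": np.array([0.5])})
        assert "tcari" not in out and "ndvi_nir2" not in out and "evi" not in out

    def test_division_by_zero_is_nan(self):
        out = fs.vegetation_indices({"red": np.array([0.0]), "nir1": np.array([0.0])})
        assert math.isnan(out["ndvi"][0])

    def test_matches_pixelwise_oracle(self):
        rng = np.random.default_rng(1)
        vals = {r: rng.uniform(0.01, 0.9, 50) for r in
                ("blue", "green", "red", "rededge", "nir1", "nir2")}
        out = fs.vegetation_indices(vals, fs.VIParams(L=0.5, gamma=1.0))
        for i in range(50):
            exp = vi_oracle(*(vals[r][i] for r in
                              ("blue", "green", "red", "rededge", "nir1", "nir2")))
            for name, e in exp.items():
                assert out[name][i] == pytest.approx(e, abs=1e-10), name


class TestFieldVISummary:
    def test_homogeneous_field_sd_zero(self):
        scene = make_test_scene(width=12, height=12, gsd=1.0, origin=(0.0, 12.0))
        out = fs.field_vi_summary(scene, square_field(3, 3, 6))
        for name, (mean, sd) in out.items():
            assert sd == pytest.approx(0.0, abs=1e-7), name

    def test_two_half_field(self):
        scene = make_test_scene(width=12, height=12, gsd=1.0, origin=(0.0, 12.0))
        red = scene.band_map["red"]
        nir = scene.band_map["nir1"]
        scene.bands[red] = 0.2
        scene.bands[nir], scene.bands[nir][:, 6:] = 0.3, 0.8  # NDVI 0.2 | 0.6
        out = fs.field_vi_summary(scene, square_field(3, 3, 6))
        mean, sd = out["ndvi"]
        assert mean == pytest.approx(0.4, abs=1e-6)
        assert sd == pytest.approx(0.2, abs=1e-6)


class TestGLCM:
    def test_hand_enumerated_2x2(self):
        P = fs.glcm(np.array([[0, 0], [1, 1]]), fs.GLCMSpec(2, 0, 1, True))
        np.testing.assert_allclose(P, [[0.5, 0.0], [0.0, 0.5]])

    def test_constant_grid_single_entry(self):
        P = fs.glcm(np.zeros((4, 4), dtype=int), fs.GLCMSpec(4, 0, 1, True))
        assert P[0, 0] == 1.0 and P.sum() == 1.0

    def test_normalization_and_symmetry(self):
        rng = np.random.default_rng(2)
        levels = rng.integers(0, 8, (10, 10))
        for angle in (0, 45, 90, 135):
            P = fs.glcm(levels, fs.GLCMSpec(8, angle, 1, True))
            assert P.sum() == pytest.approx(1.0, abs=1e-12)
            np.testing.assert_allclose(P, P.T, atol=1e-15)

    def test_irregular_support_matches_bruteforce(self):
        rng = np.random.default_rng(3)
        levels = rng.integers(0, 6, (12, 12))
        levels[rng.random((12, 12)) > 0.6] = -1  # holes
        for angle in (0, 45, 90, 135):
            P = fs.glcm(levels, fs.GLCMSpec(6, angle, 1, True))
            np.testing.assert_allclose(P, glcm_oracle(levels, 6, angle), atol=1e-12)

    def test_rectangular_support_matches_skimage(self):
        from skimage.feature import graycomatrix

        rng = np.random.default_rng(4)
        levels = rng.integers(0, 8, (16, 16))
        # skimage measures diagonal angles down-the-rows; under a symmetric
        # GLCM its pi/4 equals our 135 and its 3pi/4 our 45
        ref = graycomatrix(levels.astype(np.uint8), [1],
                           [0, 3 * np.pi / 4, np.pi / 2, np.pi / 4], levels=8,
                           symmetric=True, normed=True)
        for k, angle in enumerate((0, 45, 90, 135)):
            P = fs.glcm(levels, fs.GLCMSpec(8, angle, 1, True))
            np.testing.assert_allclose(P, ref[:, :, 0, k], atol=1e-12)

    def test_no_valid_pairs_degenerate(self):
        with pytest.raises(DegeneracyError):
            fs.glcm(np.full((3, 3), -1), fs.GLCMSpec(4, 0, 1, True))


class TestHaralick:
    def test_worked_micro_example(self):
        d = fs.haralick(np.array([[0.5, 0.0], [0.0, 0.5]]))
        assert d["f_asm"] == pytest.approx(0.5)
        assert d["f_contrast"] == pytest.approx(0.0)
        assert d["f_entropy"] == pytest.approx(1.0)  # one bit
        assert d["f_homogeneity"] == pytest.approx(1.0)

    def test_concentrated_matrix(self):
        P = np.zeros((4, 4))
        P[2, 2] = 1.0
        d = fs.haralick(P)
        assert d["f_asm"] == pytest.approx(1.0)
        assert d["f_entropy"] == 0.0
        assert d["f_sum_entropy"] == 0.0
        assert d["f_diff_entropy"] == 0.0

    def test_matches_bruteforce_oracle_on_random_matrices(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            P = rng.random((8, 8))
            P = (P + P.T) / 2
            P /= P.sum()
            got = fs.haralick(P)
            exp = haralick_oracle(P)
            for name, e in exp.items():
                assert got[name] == pytest.approx(e, abs=1e-10), name

    def test_unnormalized_rejected(self):
        with pytest.raises(SchemaError):
            fs.haralick(np.ones((3, 3)))

    def test_angle_symmetry_under_rotation(self):
        rng = np.random.default_rng(6)
        grid = rng.integers(0, 6, (9, 9))
        d0 = fs.haralick(fs.glcm(np.rot90(grid), fs.GLCMSpec(6, 0, 1, True)))
        d90 = fs.haralick(fs.glcm(grid, fs.GLCMSpec(6, 90, 1, True)))
        for name in d0:
            assert d0[name] == pytest.approx(d90[name], abs=1e-10, nan_ok=True), name


def _meta(scene_id="S1"):
    return SceneMetadata(
        scene_id=scene_id,
        acquisition_time=datetime(2015, 5, 18, 10, 46, tzinfo=timezone.utc),
        sun_elevation_deg=50.0,
        sun_azimuth_deg=120.0,
        sat_offnadir_deg=0.0,
        sat_azimuth_deg=90.0,
        cloud_cover_pct=0.0,
    )


class TestFieldTexture:
    def test_checkerboard_contrast_maximal(self):
        scene = make_test_scene(width=20, height=20, gsd=1.0, origin=(0.0, 20.0))
        nir = scene.band_map["nir1"]
        rr, cc = np.meshgrid(np.arange(20), np.arange(20), indexing="ij")
        scene.bands[nir] = np.where((rr + cc) % 2 == 0, 0.2, 0.8).astype(np.float32)
        params = fs.ExtractionParams(grey_levels=(64,), angles_deg=(0,))
        recs = fs.field_texture(scene, square_field(2, 2, 14), None, "S1", params)
        # every horizontal pair differs by G-1 levels
        assert recs[0].descriptors["f_contrast"] == pytest.approx(63.0**2)

    def test_constant_field_asm_one_for_all_records(self):
        scene = make_test_scene(width=20, height=20, gsd=1.0, origin=(0.0, 20.0))
        recs = fs.field_texture(scene, square_field(2, 2, 14), None, "S1")
        assert len(recs) == 8
        for rec in recs:
            assert rec.descriptors["f_asm"] == pytest.approx(1.0)

    def test_tiny_field_yields_undefined_descriptors(self):
        scene = make_test_scene(width=20, height=20, gsd=1.0, origin=(0.0, 20.0))
        recs = fs.field_texture(scene, square_field(2, 2, 1.2), None, "S1")
        assert len(recs) == 8
        assert all(rec.descriptors == {} for rec in recs)


class TestExtractAll:
    def _scene_fields(self):
        scene = make_test_scene(width=30, height=30, gsd=1.0, origin=(0.0, 30.0))
        fields = [
            square_field(1, 1, 8, "F1", "maize"),
            square_field(12, 2, 8, "F2", "peanut"),
            square_field(2, 15, 10, "F3", "cotton"),
        ]
        return scene, fields

    def test_record_cardinality(self):
        scene, fields = self._scene_fields()
        spectral, texture = fs.extract_all(scene, _meta(), fields, None)
        assert len(spectral) == 3
        assert len(texture) == 24  # 8 per field

    def test_constant_field_statistics_exact(self):
        scene, fields = self._scene_fields()
        scene.bands[scene.band_map["red"]] = 0.3
        spectral, _ = fs.extract_all(scene, _meta(), fields, None)
        for rec in spectral:
            mean, var, _ = rec.band_stats["red"]
            assert mean == pytest.approx(0.3, abs=1e-7)
            assert var == pytest.approx(0.0, abs=1e-12)

    def test_fully_masked_field_still_emits_record(self):
        scene, fields = self._scene_fields()
        mask = Mask(np.ones((30, 30), dtype=bool), "cloud", "S1")
        spectral, _ = fs.extract_all(scene, _meta(), fields, mask)
        assert len(spectral) == 3
        for rec in spectral:
            assert rec.n_used == 0 and rec.n_total > 0
            assert math.isnan(rec.band_stats["red"][0])

    def test_mask_monotonicity_in_n_used(self):
        scene, fields = self._scene_fields()
        rng = np.random.default_rng(7)
        small = rng.random((30, 30)) > 0.8
        large = small | (rng.random((30, 30)) > 0.8)
        rec_small, _ = fs.extract_all(scene, _meta(), fields, Mask(small, "cloud", "S1"))
        rec_large, _ = fs.extract_all(scene, _meta(), fields, Mask(large, "cloud", "S1"))
        for a, b in zip(rec_small, rec_large):
            assert b.n_used <= a.n_used
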