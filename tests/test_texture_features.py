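"""Texture descriptor families against closed forms and brute-force oracles."""

import math

import numpy as np
import pytest

from _oracles import (
    glcm_bruteforce,
    gradient_bruteforce,
    haralick_bruteforce,
    moments_bruteforce,
    rlm_bruteforce,
)
from echotexture.texture_features import (
    EQ1_FEATURES,
    GLCM_OFFSETS,
    RLM_DIRECTIONS,
    QuantizationConfig,
    ar_model,
    extract_all,
    feature_family,
    feature_registry,
    glcm,
    glcm_features,
    gradient_features,
    histogram_features,
    quantize,
    rlm_features,
    wavelet_features,
)
from echotexture.synthetic_data import simulate_ar_image
from echotexture.ultrasound_io import ROIPatch


def checkerboard(h=8, w=8, a=0, b=255):
    grid = np.fromfunction(lambda y, x: (x + y) % 2, (h, w)).astype(int)
    return np.where(grid == 0, a, b).astype(np.uint8)


class TestQuantize:
    def test_constant_patch_maps_to_zero(self):
        q = quantize(np.full((5, 5), 42, dtype=np.uint8), bits=6)
        assert np.all(q.grid == 0) and q.levels == 64

    def test_full_range_endpoints(self):
        q = quantize(np.array([[0, 255]], dtype=np.uint8), bits=6, mode="full-range")
        assert q.grid.tolist() == [[0, 63]]

    def test_minmax_matches_per_pixel_oracle(self, rng):
        px = rng.integers(0, 256, size=(8, 8))
        q = quantize(px, bits=4, mode="roi-minmax")
        lo, hi = px.min(), px.max()
        expected = np.rint((px - lo) * 15.0 / (hi - lo)).astype(int)
        assert np.array_equal(q.grid, expected)
        assert np.array_equal(
            np.bincount(q.grid.ravel(), minlength=16),
            np.bincount(expected.ravel(), minlength=16),
        )


class TestGLCM:
    def test_constant_patch_single_entry(self):
        q = quantize(np.full((2, 2), 9, dtype=np.uint8), bits=6)
        g = glcm(q, (1, 0))
        assert g.matrix[0, 0] == 1.0 and g.matrix.sum() == 1.0

    def test_alternating_line(self):
        q = quantize(np.array([[0, 255, 0, 255]], dtype=np.uint8), bits=1)
        g = glcm(q, (1, 0))
        assert g.matrix[0, 1] == pytest.approx(0.5)
        assert g.matrix[1, 0] == pytest.approx(0.5)

    def test_all_offsets_match_bruteforce(self, rng):
        q = quantize(rng.integers(0, 256, size=(16, 16)), bits=4)
        for off in GLCM_OFFSETS:
            got = glcm(q, off).matrix
            want = glcm_bruteforce(q.grid, q.levels, *off)
            np.testing.assert_allclose(got, want, atol=1e-14)

    def test_matches_skimage_graycomatrix(self, rng):
        """Cross-check against the independent scikit-image implementation."""
        from skimage.feature import graycomatrix

        q = quantize(rng.integers(0, 256, size=(24, 24)), bits=5)
        # skimage offset convention: (distance, angle); angle 0 is (dx=+d, dy=0)
        for d in range(1, 6):
            ours = glcm(q, (d, 0)).matrix
            theirs = graycomatrix(q.grid.astype(np.uint8), [d], [0],
                                  levels=q.levels, symmetric=True, normed=True)[:, :, 0, 0]
            np.testing.assert_allclose(ours, theirs, atol=1e-12)

    def test_offset_too_large_rejected(self, rng):
        q = quantize(rng.integers(0, 256, size=(4, 4)), bits=2)
        with pytest.raises(ValueError, match="not representable"):
            glcm(q, (4, 0))


class TestGLCMFeatures:
    def test_constant_image_closed_forms(self):
        q = quantize(np.full((4, 4), 7, dtype=np.uint8), bits=6)
        fv = glcm_features(glcm(q, (1, 0)))
        assert fv["S(1,0)Contrast"] == 0.0
        assert fv["S(1,0)InvDfMom"] == 1.0
        assert fv["S(1,0)DifEntrp"] == 0.0

    def test_checkerboard_closed_forms(self):
        q = quantize(checkerboard(), bits=6, mode="full-range")  # levels {0, 63}
        fv = glcm_features(glcm(q, (1, 0)))
        assert fv["S(1,0)Contrast"] == pytest.approx(63**2)
        assert fv["S(1,0)InvDfMom"] == pytest.approx(1 / 3970)
        assert fv["S(1,0)DifEntrp"] == pytest.approx(0.0, abs=1e-14)

    def test_every_feature_matches_literal_summation(self, rng):
        q = quantize(rng.integers(0, 256, size=(16, 16)), bits=4)
        for off in [(1, 0), (0, 2), (3, 3), (4, -4)]:
            g = glcm(q, off)
            fv = glcm_features(g)
            want = haralick_bruteforce(g.matrix)
            for name, v in want.items():
                key = f"S({off[0]},{off[1]}){name}"
                if math.isnan(v):
                    assert key in fv.undefined
                else:
                    assert fv[key] == pytest.approx(v, abs=1e-10)

    def test_invariant_bounds(self, rng):
        q = quantize(rng.integers(0, 256, size=(20, 20)), bits=6)
        for off in GLCM_OFFSETS:
            fv = glcm_features(glcm(q, off))
            pre = f"S({off[0]},{off[1]})"
            assert fv[pre + "Contrast"] >= 0
            assert 0 < fv[pre + "InvDfMom"] <= 1
            assert fv[pre + "DifEntrp"] >= 0


class TestRunLength:
    def test_constant_patch_horizontal(self):
        q = quantize(np.full((4, 4), 3, dtype=np.uint8), bits=4)
        fv = rlm_features(q, "Horzl")
        assert fv["Horzl_ShrtREmp"] == pytest.approx(0.0625)
        assert fv["Horzl_Fraction"] == pytest.approx(4 / 16)

    def test_checkerboard_run_structure(self):
        # axis-aligned scans see alternating levels (all runs length 1);
        # diagonal scans see constant lines (one maximal run per line)
        q = quantize(checkerboard(), bits=4, mode="full-range")
        for direction in ("Horzl", "Vertl"):
            fv = rlm_features(q, direction)
            assert fv[f"{direction}_ShrtREmp"] == pytest.approx(1.0)
            assert fv[f"{direction}_Fraction"] == pytest.approx(1.0)
        for direction in ("45dgr", "135dr"):
            fv = rlm_features(q, direction)
            assert fv[f"{direction}_Fraction"] == pytest.approx(15 / 64)  # 15 lines

    def test_all_directions_match_line_scanning_oracle(self, rng):
        q = quantize(rng.integers(0, 256, size=(12, 12)), bits=2)
        for direction in RLM_DIRECTIONS:
            fv = rlm_features(q, direction)
            want = rlm_bruteforce(q.grid, q.levels, direction)
            for name, v in want.items():
                assert fv[f"{direction}_{name}"] == pytest.approx(v, abs=1e-12), direction

    def test_shortrun_emphasis_bounds(self, rng):
        q = quantize(rng.integers(0, 256, size=(10, 14)), bits=4)
        for direction in RLM_DIRECTIONS:
            v = rlm_features(q, direction)[f"{direction}_ShrtREmp"]
            assert 0 < v <= 1


class TestGradient:
    def test_ramp_has_constant_gradient(self):
        px = np.tile(np.arange(10, dtype=np.uint8), (6, 1))  # I(x, y) = x
        fv = gradient_features(px)
        assert fv["GrMean"] == pytest.approx(2.0)
        assert fv["GrVariance"] == pytest.approx(0.0)
        assert "GrKurtosis" in fv.undefined and "GrSkewness" in fv.undefined

    def test_constant_patch(self):
        fv = gradient_features(np.full((5, 5), 100, dtype=np.uint8))
        assert fv["GrMean"] == 0.0 and fv["GrNonZeros"] == 0.0

    def test_gradient_map_matches_bruteforce(self, rng):
        px = rng.integers(0, 256, size=(14, 11))
        from echotexture.texture_features import gradient_map

        np.testing.assert_allclose(gradient_map(px), gradient_bruteforce(px), atol=1e-12)

    def test_excess_kurtosis_convention_on_normal_draws(self, rng):
        """On 10^6 standard-normal draws the kurtosis estimate -> 0 (excess)."""
        from echotexture.texture_features import _moment_features

        x = rng.standard_normal(1_000_000)
        fv = _moment_features(x, prefix="Gr")
        assert abs(fv["GrKurtosis"]) < 5 * math.sqrt(24 / x.size)


class TestARModel:
    def test_iid_noise_has_no_structure(self, rng):
        patch = ROIPatch(pixels=rng.integers(0, 256, size=(256, 256)))
        fv = ar_model(patch)
        for name in ("Teta1", "Teta2", "Teta3", "Teta4"):
            assert abs(fv[name]) < 0.05

    def test_parameter_recovery(self):
        theta = np.array([0.3, -0.45, 0.05, 0.10])
        patch = simulate_ar_image(theta, sigma=5.0, size=256, seed=11)
        fv = ar_model(patch)
        est = np.array([fv[f"Teta{i}"] for i in (1, 2, 3, 4)])
        np.testing.assert_allclose(est, theta, atol=0.03)

    def test_column_constant_structure(self, rng):
        row = rng.integers(0, 256, size=32)
        patch = np.tile(row, (16, 1)).astype(np.uint8)  # f(x, y) = f(x, y-1)
        fv = ar_model(patch)
        assert fv["Teta2"] == pytest.approx(1.0, abs=1e-8)
        assert fv["Sigma"] == pytest.approx(0.0, abs=1e-8)

    def test_constant_patch_flagged_undefined(self):
        fv = ar_model(np.full((8, 8), 5, dtype=np.uint8))
        assert {"Teta1", "Teta2", "Teta3", "Teta4", "Sigma"} <= fv.undefined


class TestHistogram:
    def test_constant_patch(self):
        fv = histogram_features(np.full((4, 4), 7, dtype=np.uint8))
        assert fv["Mean"] == 7 and fv["Variance"] == 0
        for q in (1, 10, 50, 90, 99):
            assert fv[f"Perc{q:02d}"] == 7

    def test_uniform_ramp_percentile_rule(self):
        px = np.arange(256, dtype=np.uint8).reshape(16, 16)
        fv = histogram_features(px)
        assert fv["Mean"] == pytest.approx(127.5)
        assert fv["Perc50"] == 127  # inverted-CDF rule: observed gray value

    def test_moments_match_direct_summation(self, rng):
        px = rng.integers(0, 256, size=(9, 9))
        fv = histogram_features(px)
        want = moments_bruteforce(px)
        for name, v in want.items():
            assert fv[name] == pytest.approx(v, abs=1e-10)


class TestWavelet:
    def test_constant_patch_has_no_detail_energy(self):
        fv = wavelet_features(np.full((32, 32), 50, dtype=np.uint8))
        for s in (1, 2, 3, 4, 5):
            for band in ("LH", "HL", "HH"):
                assert fv[f"WavEn{band}_{s}"] == pytest.approx(0.0, abs=1e-18)

    def test_orientation_selectivity_of_vertical_stripes(self):
        px = np.tile(np.array([0, 255] * 16, dtype=np.uint8), (32, 1))
        fv = wavelet_features(px)
        assert fv["WavEnLH_1"] == pytest.approx(0.0, abs=1e-18)  # no variation along y
        assert fv["WavEnHL_1"] > fv["WavEnLH_1"]
        assert fv["WavEnHL_1"] > 0

    def test_parseval_identity(self, rng):
        px = rng.integers(0, 256, size=(64, 64))
        fv = wavelet_features(px)
        total = 0.0
        side = 64
        for s in range(1, 6):
            count = (side // 2**s) ** 2
            for band in ("LH", "HL", "HH"):
                total += fv[f"WavEn{band}_{s}"] * count
        total += fv["WavEnLL_5"] * (side // 32) ** 2
        assert total / side**2 == pytest.approx((px.astype(float) ** 2).mean(), rel=1e-8)

    def test_too_small_patch_rejected(self):
        with pytest.raises(ValueError, match="at least 16x16"):
            wavelet_features(np.zeros((8, 8), dtype=np.uint8))


class TestExtractAll:
    def test_deterministic_and_complete(self, rng):
        patch = ROIPatch(pixels=rng.integers(0, 256, size=(64, 64)))
        fv1 = extract_all(patch)
        fv2 = extract_all(patch)
        assert fv1.values == fv2.values
        for name in EQ1_FEATURES:
            assert name in fv1

    def test_six_families_and_descriptor_count(self, rng):
        # patch sized like the mean manually drawn ROI (~34,000 px)
        patch = ROIPatch(pixels=rng.integers(0, 256, size=(170, 200)))
        fv = extract_all(patch)
        assert len(fv) >= 250
        assert {feature_family(n) for n in fv.values} == {
            "histogram", "gradient", "ar_model", "glcm", "rlm", "wavelet"}

    def test_undefined_propagates_as_nan_not_zero(self):
        patch = ROIPatch(pixels=np.full((32, 32), 9, dtype=np.uint8))
        fv = extract_all(patch)
        assert "GrSkewness" in fv.undefined
        assert math.isnan(fv["GrSkewness"])

    def test_registry_covers_extraction(self, rng):
        reg = feature_registry()
        patch = ROIPatch(pixels=rng.integers(0, 256, size=(64, 64)))
        fv = extract_all(patch)
        assert set(fv.values) <= set(reg["name"])
        assert set(reg["family"]) == {"histogram", "gradient", "ar_model",
                                      "glcm", "rlm", "wavelet"}
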