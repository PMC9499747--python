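"""2-D DWT sub-bands and the six-statistic feature vector."""

import numpy as np
import pytest

from gliopipe import dwt2, idwt2, extract_feature_vector, subband_statistics
from gliopipe.dwt_features import DWTFeatureExtractor, FEATURE_NAMES
from gliopipe.wavelets import BAND_NAMES, filters


# ------------------------------------------------------------------ oracle

def brute_features(f):
    """Independent double-loop implementation of the six statistics."""
    m, n = f.shape
    total = 0.0
    for x in range(m):
        for y in range(n):
            total += f[x, y]
    mean = total / (m * n)
    var = sum((f[x, y] - mean) ** 2 for x in range(m) for y in range(n)) / (m * n)
    row_vars = []
    for x in range(m):
        rm = sum(f[x, y] for y in range(n)) / n
        row_vars.append(sum((f[x, y] - rm) ** 2 for y in range(n)) / (n - 1))
    idm = sum(f[x, y] / (1 + (x - y) ** 2)
              for x in range(m) for y in range(n))
    rms = (sum(f[x, y] ** 2 for x in range(m) for y in range(n)) / (m * n)) ** 0.5
    return {
        "mean": mean,
        "std": var ** 0.5,
        "variance_mean": float(np.mean(row_vars)),
        "idm": idm,
        "rms": rms,
        "smoothness": 1 - 1 / (1 + total),
    }


class TestDwt2:
    def test_one_level_yields_exactly_four_subbands(self, rng):
        sb = dwt2(rng.random((16, 16)), "haar", levels=1)
        assert set(sb.bands[1]) == set(BAND_NAMES)
        assert len(sb.bands[1]) == 4

    def test_subband_sides_halve_per_level(self, rng):
        sb = dwt2(rng.random((64, 64)), "haar", levels=2)
        assert sb.bands[1]["LL"].shape == (32, 32)
        assert sb.bands[2]["HL"].shape == (16, 16)

    def test_detail_bands_of_constant_image_are_zero(self):
        sb = dwt2(np.full((16, 16), 9.0), "haar", levels=2)
        for lev in (1, 2):
            for name in ("LH", "HL", "HH"):
                np.testing.assert_allclose(sb.bands[lev][name], 0.0, atol=1e-12)

    @pytest.mark.parametrize("wavelet", ["haar", "db4"])
    def test_perfect_reconstruction(self, wavelet, rng):
        x = rng.random((32, 32)) * 255
        rec = idwt2(dwt2(x, wavelet, levels=2))
        np.testing.assert_allclose(rec, x, atol=1e-8)

    @pytest.mark.parametrize("wavelet", ["haar", "db4"])
    def test_energy_conservation(self, wavelet, rng):
        x = rng.random((32, 32))
        sb = dwt2(x, wavelet, levels=2)
        e = sum((sb.bands[1][k] ** 2).sum() for k in ("LH", "HL", "HH"))
        e += sum((sb.bands[2][k] ** 2).sum() for k in BAND_NAMES)
        assert e == pytest.approx((x ** 2).sum(), rel=1e-6)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            dwt2(np.zeros((2, 2)), "haar", levels=2)

    def test_unknown_wavelet_rejected(self):
        with pytest.raises(ValueError, match="unknown wavelet"):
            filters("sym5")

    def test_haar_level1_matches_hand_blocks(self):
        """Haar LL over disjoint 2x2 blocks is the block mean times 2."""
        x = np.array([[1.0, 3.0], [5.0, 7.0]])
        sb = dwt2(x, "haar", levels=1)
        assert sb.bands[1]["LL"][0, 0] == pytest.approx(x.mean() * 2)


class TestSubbandStatistics:
    def test_constant_grid(self):
        f = subband_statistics(np.full((4, 4), 7.0))
        assert f["mean"] == pytest.approx(7.0)
        assert f["std"] == pytest.approx(0.0)
        assert f["rms"] == pytest.approx(7.0)

    def test_hand_computed_grid(self):
        f = subband_statistics(np.array([[0.0, 10.0], [10.0, 0.0]]))
        assert f["mean"] == pytest.approx(5.0)
        assert f["rms"] == pytest.approx(np.sqrt(50.0))

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(50):
            grid = rng.uniform(-50, 200, (16, 16))
            got = subband_statistics(grid)
            want = brute_features(grid)
            for k in FEATURE_NAMES:
                assert got[k] == pytest.approx(want[k], abs=1e-10), k

    def test_invariants_on_nonnegative_grids(self, rng):
        for _ in range(20):
            grid = rng.uniform(0, 255, (8, 8))
            f = subband_statistics(grid)
            assert f["std"] >= 0
            assert f["rms"] >= abs(f["mean"])
            assert 0 <= f["smoothness"] < 1

    def test_conventional_smoothness_switch(self, rng):
        grid = rng.uniform(0, 10, (8, 8))
        strict = subband_statistics(grid, strict_formulas=True)
        conv = subband_statistics(grid, strict_formulas=False)
        var = grid.var()
        assert conv["smoothness"] == pytest.approx(1 - 1 / (1 + var))
        assert strict["smoothness"] != conv["smoothness"]

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            subband_statistics(np.empty((0, 0)))


class TestExtractFeatureVector:
    def test_vector_has_24_named_features(self, small_phantom):
        fv = extract_feature_vector(small_phantom.image)
        assert len(fv) == 24
        assert list(fv)[:6] == [f"LL1_{n}" for n in FEATURE_NAMES]
        assert list(fv)[6:12] == [f"HL1_{n}" for n in FEATURE_NAMES]

    def test_deterministic(self, small_phantom):
        a = extract_feature_vector(small_phantom.image)
        b = extract_feature_vector(small_phantom.image)
        assert a == b

    def test_doubling_intensities_doubles_mean_and_rms(self, rng):
        img = rng.uniform(0, 100, (32, 32))
        f1 = extract_feature_vector(img)
        f2 = extract_feature_vector(2 * img)
        for tag in ("LL1", "HL1", "LL2", "HL2"):
            assert f2[f"{tag}_mean"] == pytest.approx(2 * f1[f"{tag}_mean"])
            assert f2[f"{tag}_rms"] == pytest.approx(2 * f1[f"{tag}_rms"])

    def test_mask_restricts_to_region(self, small_phantom):
        masked = extract_feature_vector(small_phantom.image,
                                        mask=small_phantom.tumor_mask)
        whole = extract_feature_vector(small_phantom.image)
        assert masked["LL1_mean"] < whole["LL1_mean"]  # most pixels zeroed


class TestDWTFeatureExtractorEstimator:
    def test_transform_shape_and_names(self, phantom_per_class):
        imgs = [s.image.pixels for s in phantom_per_class.values()]
        ext = DWTFeatureExtractor().fit(imgs)
        X = ext.transform(imgs)
        assert X.shape == (3, 24)
        names = ext.get_feature_names_out()
        assert names[0] == "LL1_mean" and names[-1] == "HL2_smoothness"

    def test_estimator_params_roundtrip(self):
        ext = DWTFeatureExtractor(wavelet="db4", levels=1, bands=("LL1",))
        assert ext.get_params()["wavelet"] == "db4"
        X = ext.fit([np.ones((16, 16))]).transform([np.ones((16, 16))])
        assert X.shape == (1, 6)
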