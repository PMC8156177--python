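"""Feature-extraction oracles and contracts (167 per band, 334 fused)."""

import numpy as np
import pytest

from cfidetect.features import (
    FUSED_LENGTH,
    GROUP_SIZES,
    SINGLE_BAND_LENGTH,
    FeatureTable,
    FeatureVector,
    extract_all,
    fuse,
    gabor_features,
    glcm_matrices,
    haralick_features,
    hu_moments,
    intensity_features,
    lbp_codes,
    lbp_features,
)


@pytest.fixture(scope="module")
def textured_image():
    rng = np.random.default_rng(7)
    img = rng.uniform(0, 1, (48, 48))
    mask = np.zeros((48, 48), dtype=bool)
    mask[4:44, 4:44] = True
    return img, mask


# ---------------------------------------------------------------------------
# Haralick


class TestHaralick:
    def test_constant_image(self):
        img = np.full((16, 16), 3.0)
        mask = np.ones((16, 16), dtype=bool)
        f = haralick_features(img, mask)
        names_idx = {"asm": 0, "contrast": 1}
        assert f[names_idx["asm"]] == pytest.approx(1.0)  # ASM mean
        assert f[names_idx["contrast"]] == pytest.approx(0.0)  # contrast mean
        assert f[14 + names_idx["contrast"]] == pytest.approx(0.0)  # contrast range

    def test_glcm_matches_pair_enumeration(self):
        """4x4 checkerboard of two levels: every horizontal/vertical pair is a
        (0,1) transition; enumerate pairs by hand and compare."""
        img = np.indices((4, 4)).sum(axis=0) % 2 * 5.0
        mask = np.ones((4, 4), dtype=bool)
        glcm = glcm_matrices(img, mask, levels=2)

        # row-positive-down convention: 45 deg pairs (r, c) with (r+1, c+1)
        offsets = {0: (0, 1), 1: (1, 1), 2: (1, 0), 3: (1, -1)}
        q = (img > 0).astype(int)
        for a, (dy, dx) in offsets.items():
            counts = np.zeros((2, 2))
            for y in range(4):
                for x in range(4):
                    yy, xx = y + dy, x + dx
                    if 0 <= yy < 4 and 0 <= xx < 4:
                        counts[q[y, x], q[yy, xx]] += 1
                        counts[q[yy, xx], q[y, x]] += 1  # symmetric
            counts /= counts.sum()
            assert np.allclose(glcm[:, :, a], counts)

    def test_checkerboard_contrast(self):
        """Horizontal offset on a checkerboard: every pair differs by one
        quantization level, so contrast (0 deg) = 1 with 2 levels."""
        img = np.indices((8, 8)).sum(axis=0) % 2 * 9.0
        mask = np.ones((8, 8), dtype=bool)
        glcm = glcm_matrices(img, mask, levels=2)
        i, j = np.meshgrid(np.arange(2), np.arange(2), indexing="ij")
        contrast0 = ((i - j) ** 2 * glcm[:, :, 0]).sum()
        assert contrast0 == pytest.approx(1.0)

    def test_glcm_symmetric_normalized(self, textured_image):
        img, mask = textured_image
        glcm = glcm_matrices(img, mask)
        for a in range(4):
            g = glcm[:, :, a]
            assert np.allclose(g, g.T)
            assert g.sum() == pytest.approx(1.0)
            assert (g >= 0).all()

    def test_output_length(self, textured_image):
        assert haralick_features(*textured_image).size == 28

    def test_mask_restriction(self):
        """Pairs crossing the mask boundary must not contribute."""
        img = np.zeros((6, 6))
        img[:, 3:] = 100.0  # bright half excluded by the mask
        mask = np.zeros((6, 6), dtype=bool)
        mask[:, :3] = True
        glcm = glcm_matrices(img, mask, levels=4)
        # all in-mask pixels share one level -> single GLCM entry
        assert glcm[0, 0, 0] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# LBP


def lbp_oracle_histogram(img):
    """Brute-force uniform-LBP histogram: enumerate each interior pixel's
    8-bit pattern, classify by circular transitions, bin by pattern value."""
    uniform_codes = sorted(
        c for c in range(256)
        if sum(((c >> b) & 1) != ((c >> ((b + 1) % 8)) & 1) for b in range(8)) <= 2
    )
    code_to_bin = {c: i for i, c in enumerate(uniform_codes)}
    offs = [(0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1)]
    hist = np.zeros(59)
    H, W = img.shape
    for y in range(1, H - 1):
        for x in range(1, W - 1):
            code = 0
            for bit, (dy, dx) in enumerate(offs):
                if img[y + dy, x + dx] > img[y, x]:
                    code |= 1 << bit
            hist[code_to_bin.get(code, 58)] += 1
    return hist / hist.sum()


class TestLBP:
    def test_constant_image_all_zeros_bin(self):
        img = np.full((10, 10), 4.2)
        mask = np.ones((10, 10), dtype=bool)
        h = lbp_features(img, mask)
        assert h[0] == pytest.approx(1.0)  # all-zeros uniform pattern
        assert h.sum() == pytest.approx(1.0)

    def test_single_bright_pixel_patterns(self):
        """The 8 neighbours of an isolated bright pixel each see exactly one
        set bit -> single-bit uniform patterns, verified by enumeration."""
        img = np.zeros((5, 5))
        img[2, 2] = 10.0
        codes = lbp_codes(img)
        oracle = lbp_oracle_histogram(img)
        mask = np.ones((5, 5), dtype=bool)
        h = lbp_features(img, mask)
        assert np.allclose(h, oracle)
        # centre pixel itself: no neighbour brighter -> all-zeros bin
        assert codes[1, 1] == 0

    def test_matches_bruteforce_on_random_image(self, textured_image):
        img, _ = textured_image
        mask = np.ones(img.shape, dtype=bool)
        assert np.allclose(lbp_features(img, mask), lbp_oracle_histogram(img))

    def test_output_length_and_mass(self, textured_image):
        h = lbp_features(*textured_image)
        assert h.size == 59
        assert h.sum() == pytest.approx(1.0)

    def test_small_mask_rejected(self):
        with pytest.raises(ValueError):
            lbp_features(np.ones((5, 5)), np.zeros((5, 5), dtype=bool))


# ---------------------------------------------------------------------------
# Gabor


class TestGabor:
    def test_constant_image_zero_response(self):
        img = np.full((64, 64), 5.0)
        mask = np.ones((64, 64), dtype=bool)
        f = gabor_features(img, mask)
        assert np.allclose(f, 0.0, atol=1e-9)  # DC-free bank

    def test_grating_peaks_at_matching_filter(self):
        """A grating at a bank frequency/orientation maximizes that filter's
        mean response magnitude over the whole bank."""
        from cfidetect.features import _gabor_bank

        bank = _gabor_bank()
        n = 96
        yy, xx = np.mgrid[0:n, 0:n]
        target = 17  # filter index: f index 2 (0.2 c/px), orientation index 1
        f0, theta0, _ = bank[target]
        # skimage gabor kernels modulate along (cos t, sin t) in (row, col)
        grating = np.cos(2 * np.pi * f0 * (yy * np.sin(theta0) + xx * np.cos(theta0)))
        mask = np.ones((n, n), dtype=bool)
        feats = gabor_features(grating, mask)
        means = feats[:32]
        assert int(np.argmax(means)) == target

    def test_output_length(self, textured_image):
        assert gabor_features(*textured_image).size == 67


# ---------------------------------------------------------------------------
# Intensity & Hu


class TestIntensity:
    def test_constant_conventions(self):
        img = np.ones((4, 4))
        f = intensity_features(img, np.ones((4, 4), dtype=bool))
        assert np.allclose(f, [1, 0, 1, 1, 0, 0])

    def test_four_point_closed_form(self):
        img = np.array([[1.0, 2.0], [3.0, 4.0]])
        mask = np.ones((2, 2), dtype=bool)
        f = intensity_features(img, mask)
        assert f[0] == pytest.approx(2.5)
        assert f[1] == pytest.approx(np.sqrt(1.25))  # population SD
        assert f[2] == 1.0 and f[3] == 4.0
        assert f[4] == pytest.approx(0.0)  # symmetric set
        # excess kurtosis of the uniform 4-point set: m4/m2^2 - 3 = -1.36
        assert f[5] == pytest.approx(2.5625 / 1.25**2 - 3.0)

    def test_length(self, textured_image):
        assert intensity_features(*textured_image).size == 6


def hu_oracle(img):
    """Hu invariants from first principles: raw double-sum moments ->
    central -> scale-normalized -> the 7 algebraic combinations."""
    H, W = img.shape
    m = {(p, q): sum(img[y, x] * x**p * y**q for y in range(H) for x in range(W))
         for p in range(4) for q in range(4)}
    xc, yc = m[(1, 0)] / m[(0, 0)], m[(0, 1)] / m[(0, 0)]
    mu = {(p, q): sum(img[y, x] * (x - xc) ** p * (y - yc) ** q
                      for y in range(H) for x in range(W))
          for p in range(4) for q in range(4)}
    eta = {k: mu[k] / m[(0, 0)] ** (1 + (k[0] + k[1]) / 2) for k in mu if k[0] + k[1] >= 2}
    n = eta
    h1 = n[(2, 0)] + n[(0, 2)]
    h2 = (n[(2, 0)] - n[(0, 2)]) ** 2 + 4 * n[(1, 1)] ** 2
    h3 = (n[(3, 0)] - 3 * n[(1, 2)]) ** 2 + (3 * n[(2, 1)] - n[(0, 3)]) ** 2
    h4 = (n[(3, 0)] + n[(1, 2)]) ** 2 + (n[(2, 1)] + n[(0, 3)]) ** 2
    h5 = ((n[(3, 0)] - 3 * n[(1, 2)]) * (n[(3, 0)] + n[(1, 2)])
          * ((n[(3, 0)] + n[(1, 2)]) ** 2 - 3 * (n[(2, 1)] + n[(0, 3)]) ** 2)
          + (3 * n[(2, 1)] - n[(0, 3)]) * (n[(2, 1)] + n[(0, 3)])
          * (3 * (n[(3, 0)] + n[(1, 2)]) ** 2 - (n[(2, 1)] + n[(0, 3)]) ** 2))
    h6 = ((n[(2, 0)] - n[(0, 2)])
          * ((n[(3, 0)] + n[(1, 2)]) ** 2 - (n[(2, 1)] + n[(0, 3)]) ** 2)
          + 4 * n[(1, 1)] * (n[(3, 0)] + n[(1, 2)]) * (n[(2, 1)] + n[(0, 3)]))
    h7 = ((3 * n[(2, 1)] - n[(0, 3)]) * (n[(3, 0)] + n[(1, 2)])
          * ((n[(3, 0)] + n[(1, 2)]) ** 2 - 3 * (n[(2, 1)] + n[(0, 3)]) ** 2)
          - (n[(3, 0)] - 3 * n[(1, 2)]) * (n[(2, 1)] + n[(0, 3)])
          * (3 * (n[(3, 0)] + n[(1, 2)]) ** 2 - (n[(2, 1)] + n[(0, 3)]) ** 2))
    return np.array([h1, h2, h3, h4, h5, h6, h7])


class TestHuMoments:
    def test_rotation_invariance(self, textured_image):
        img, _ = textured_image
        mask = np.ones(img.shape, dtype=bool)
        a = hu_moments(img, mask)
        b = hu_moments(np.rot90(img), np.rot90(mask))
        assert np.allclose(a, b, rtol=1e-6, atol=1e-6)

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        img = np.zeros((40, 40))
        img[5:15, 5:15] = rng.uniform(1, 2, (10, 10))
        mask = img > 0
        shifted = np.roll(np.roll(img, 7, axis=0), 5, axis=1)
        a = hu_moments(img, mask)
        b = hu_moments(shifted, shifted > 0)
        assert np.allclose(a, b, rtol=1e-8, atol=1e-8)

    def test_matches_double_sum_oracle(self):
        """Centered disk: compare against the defining moment sums (before
        the package's signed-log transform)."""
        n = 31
        yy, xx = np.mgrid[0:n, 0:n]
        disk = (((yy - 15) ** 2 + (xx - 15) ** 2) <= 100).astype(float) * 2.0
        mask = disk > 0
        raw = hu_oracle(disk)
        packaged = hu_moments(disk, mask)
        expected = np.zeros(7)
        nz = raw != 0
        expected[nz] = -np.sign(raw[nz]) * np.log10(np.abs(raw[nz]))
        # tiny invariants (h5..h7 of a symmetric disk) are numerically zero;
        # compare only well-conditioned entries in log space
        big = np.abs(raw) > 1e-12
        assert np.allclose(packaged[big], expected[big], rtol=1e-6)

    def test_zero_intensity_rejected(self):
        with pytest.raises(ValueError):
            hu_moments(np.zeros((8, 8)), np.ones((8, 8), dtype=bool))


# ---------------------------------------------------------------------------
# Assembly, fusion, normalization


class TestExtractAndFuse:
    def test_lengths_and_groups(self, textured_image):
        img, mask = textured_image
        v = extract_all(img, mask, "675")
        assert v.values.size == SINGLE_BAND_LENGTH == 167
        assert GROUP_SIZES == {"haralick": 28, "lbp": 59, "gabor": 67, "intensity": 6, "hu": 7}
        groups = [n.rsplit("_", 1)[0].split("_")[0] for n in v.names]
        for g, size in GROUP_SIZES.items():
            assert groups.count(g) == size

    def test_deterministic(self, textured_image):
        img, mask = textured_image
        a = extract_all(img, mask, "750")
        b = extract_all(img, mask, "750")
        assert np.array_equal(a.values, b.values)

    def test_fuse_round_trip(self, textured_image):
        img, mask = textured_image
        v675 = extract_all(img, mask, "675")
        v750 = extract_all(img * 0.4, mask, "750")
        fused = fuse(v675, v750)
        assert fused.values.size == FUSED_LENGTH == 334
        assert all(n.endswith("_675") for n in fused.names[:167])
        assert np.array_equal(fused.values[:167], v675.values)
        assert np.array_equal(fused.values[167:], v750.values)
        # order-agnostic: swapping arguments yields the same 675-first layout
        assert np.array_equal(fuse(v750, v675).values, fused.values)

    def test_fuse_rejects_duplicate_band(self, textured_image):
        img, mask = textured_image
        v = extract_all(img, mask, "675")
        with pytest.raises(ValueError):
            fuse(v, v)

    def test_feature_vector_validates_length(self):
        with pytest.raises(ValueError):
            FeatureVector(values=np.zeros(10), names=[f"f{i}" for i in range(10)], band="675")


class TestNormalize:
    @pytest.fixture()
    def toy_table(self):
        import pandas as pd

        df = pd.DataFrame(
            {"a_675": [1.0, 2.0, 3.0, 10.0], "b_750": [4.0, 8.0, 6.0, 0.0]},
            index=["s0", "s1", "s2", "s3"],
        )
        labels = pd.Series([0, 1, 1, 2], index=df.index, name="label")
        return FeatureTable(df, labels)

    def test_training_rows_standardized(self, toy_table):
        normed = toy_table.normalize(["s0", "s1", "s2"])
        train = normed.df.loc[["s0", "s1", "s2"]]
        assert np.allclose(train.mean(), 0.0, atol=1e-10)
        assert np.allclose(train.var(ddof=0), 1.0, atol=1e-10)

    def test_manual_arithmetic(self, toy_table):
        """3 training rows with hand-computed mean/SD applied to a test row."""
        normed = toy_table.normalize(["s0", "s1", "s2"])
        # column a: mean 2, population SD sqrt(2/3); row s3 value 10
        assert normed.df.loc["s3", "a_675"] == pytest.approx((10 - 2) / np.sqrt(2 / 3))
        # column b: mean 6, population SD sqrt(8/3); row s3 value 0
        assert normed.df.loc["s3", "b_750"] == pytest.approx((0 - 6) / np.sqrt(8 / 3))

    def test_test_row_at_training_mean_maps_to_zero(self, toy_table):
        import pandas as pd

        df = toy_table.df.copy()
        df.loc["s3"] = df.loc[["s0", "s1", "s2"]].mean()
        t = FeatureTable(df, toy_table.labels.copy())
        normed = t.normalize(["s0", "s1", "s2"])
        assert np.allclose(normed.df.loc["s3"], 0.0, atol=1e-12)

    def test_zero_variance_feature_guard(self, toy_table):
        df = toy_table.df.copy()
        df["c_675"] = 5.0
        t = FeatureTable(df, toy_table.labels.copy())
        with pytest.warns(UserWarning):
            normed = t.normalize(["s0", "s1", "s2"])
        assert np.allclose(normed.df["c_675"], 0.0)

    def test_band_selection(self, toy_table):
        sel = toy_table.select_band("675")
        assert sel.feature_names == ["a_675"]

    def test_csv_round_trip(self, toy_table, tmp_path):
        path = tmp_path / "t.csv"
        toy_table.to_csv(path)
        back = FeatureTable.read_csv(path)
        assert np.allclose(back.df.to_numpy(), toy_table.df.to_numpy())
        assert (back.labels == toy_table.labels).all()
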