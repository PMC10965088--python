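import numpy as np
import pytest
from skimage.feature import graycomatrix, graycoprops

from mrigrade import texture
from mrigrade.texture import (GLCMSpec, GaborBankSpec, LBPSpec, LogEnergySpec,
                              compute_glcm, gabor_features, gabor_kernel,
                              glcm_stats, ica_filter_feature, lbp_codes,
                              lbp_histogram, log_energy, ltp_codes,
                              ltp_histograms, pca_filter_feature, quantize,
                              rlbp_codes, rlbp_histogram)

# ---------------------------------------------------------------------------
# brute-force oracles for the local-pattern operators
# ---------------------------------------------------------------------------


def _bilinear(img, r, c):
    r0, c0 = int(np.floor(r)), int(np.floor(c))
    r1, c1 = min(r0 + 1, img.shape[0] - 1), min(c0 + 1, img.shape[1] - 1)
    fr, fc = r - r0, c - c0
    return ((1 - fr) * (1 - fc) * img[r0, c0] + (1 - fr) * fc * img[r0, c1]
            + fr * (1 - fc) * img[r1, c0] + fr * fc * img[r1, c1])


def _lbp_oracle(img, radius, points):
    m = int(np.ceil(radius))
    h, w = img.shape
    codes = np.zeros((h - 2 * m, w - 2 * m), dtype=int)
    for r in range(m, h - m):
        for c in range(m, w - m):
            code = 0
            for p in range(points):
                a = 2 * np.pi * p / points
                v = _bilinear(img, r - radius * np.sin(a), c + radius * np.cos(a))
                if v >= img[r, c] - 1e-12:
                    code |= 1 << p
            codes[r - m, c - m] = code
    return codes


def _rlbp_oracle(img, points, n_radii):
    m = n_radii
    h, w = img.shape
    codes = np.zeros((h - 2 * m, w - 2 * m), dtype=int)
    for r in range(m, h - m):
        for c in range(m, w - m):
            code = 0
            for p in range(points):
                a = 2 * np.pi * p / points
                v = np.mean([_bilinear(img, r - rad * np.sin(a), c + rad * np.cos(a))
                             for rad in range(1, n_radii + 1)])
                if v >= img[r, c] - 1e-12:
                    code |= 1 << p
            codes[r - m, c - m] = code
    return codes


class TestGLCM:
    def test_hand_counted_two_pixel_pairs(self):
        img = np.array([[0.0, 0.0], [0.6, 0.6]])
        g = compute_glcm(img, GLCMSpec(levels=2, offsets=((0, 1),)))[0]
        assert g[0, 0] == pytest.approx(0.5)
        assert g[1, 1] == pytest.approx(0.5)
        assert g[0, 1] == g[1, 0] == 0

    def test_constant_image_single_cell(self):
        g = compute_glcm(np.full((8, 8), 0.3), GLCMSpec(levels=4, offsets=((0, 1),)))[0]
        assert g[1, 1] == pytest.approx(1.0)
        assert g.sum() == pytest.approx(1.0)

    def test_normalization_contract(self, rng):
        g = compute_glcm(rng.random((16, 16)))
        assert np.allclose(g.sum(axis=(1, 2)), 1.0)

    def test_matches_skimage_for_standard_offsets(self, rng):
        """Independent route: skimage graycomatrix at 0/45/90/135 degrees."""
        img = rng.random((20, 20))
        levels = 8
        q = quantize(img, levels)
        ours = compute_glcm(img, GLCMSpec(levels=levels))
        # skimage's angle t counts pairs toward (+d sin t, +d cos t), so our
        # up-right offset (-1, 1) is its 3pi/4 and our up-left (-1,-1) its pi/4
        # (equivalent under symmetrization).
        angles = [0, 3 * np.pi / 4, np.pi / 2, np.pi / 4]
        theirs = graycomatrix(q.astype(np.uint8), distances=[1], angles=angles,
                              levels=levels, symmetric=True, normed=True)
        for k in range(4):
            assert np.allclose(ours[k], theirs[:, :, 0, k])

    def test_offset_exceeding_image_raises(self):
        with pytest.raises(ValueError):
            compute_glcm(np.zeros((8, 8)), GLCMSpec(levels=2, offsets=((0, 9),)))


class TestGLCMStats:
    def test_diagonal_mass(self):
        p = np.diag([0.5, 0.5])
        contrast, corr, energy, homog, entropy = glcm_stats(p)
        assert contrast == 0
        assert homog == pytest.approx(1.0)
        assert energy == pytest.approx(0.5)
        assert entropy == pytest.approx(1.0)  # one bit

    def test_single_cell(self):
        stats = glcm_stats(np.array([[1.0, 0], [0, 0]]))
        assert stats[2] == pytest.approx(1.0)  # energy
        assert stats[4] == pytest.approx(0.0)  # entropy
        assert stats[1] == 0.0  # degenerate marginals -> correlation 0

    def test_matches_graycoprops(self, rng):
        img = rng.random((16, 16))
        ours = compute_glcm(img, GLCMSpec(levels=8, offsets=((0, 1),)))[0]
        m = graycomatrix(quantize(img, 8).astype(np.uint8), [1], [0],
                         levels=8, symmetric=True, normed=True)
        contrast, corr, energy, homog, _ = glcm_stats(ours)
        assert contrast == pytest.approx(graycoprops(m, "contrast")[0, 0])
        assert corr == pytest.approx(graycoprops(m, "correlation")[0, 0])
        assert energy == pytest.approx(graycoprops(m, "ASM")[0, 0])
        # homogeneity deliberately differs: ours is sum p/(1+|i-j|), the
        # inverse-difference form, not skimage's 1/(1+(i-j)^2)
        assert homog == pytest.approx(float(np.sum(ours / (1.0 + np.abs(
            np.subtract.outer(np.arange(8), np.arange(8)))))))

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            glcm_stats(np.ones((3, 3)))


class TestLBPFamily:
    def test_documented_3x3_code(self):
        # neighbours (E, NE, N, NW, W, SW, S, SE) = (9,9,9,1,1,1,1,9), centre 5
        img = np.array([[1, 9, 9], [1, 5, 9], [1, 1, 9]]) / 10.0
        assert lbp_codes(img)[0, 0] == 0b10000111  # == 135

    def test_constant_image_all_ones_code(self):
        img = np.full((10, 10), 0.4)
        codes = lbp_codes(img)
        assert np.all(codes == 255)
        hist = lbp_histogram(img)
        assert hist[8] == pytest.approx(1.0)  # uniform-RI bin = popcount 8

    def test_codes_match_bruteforce(self, rng):
        for _ in range(3):
            img = rng.random((16, 16))
            assert np.array_equal(lbp_codes(img), _lbp_oracle(img, 1.0, 8))

    def test_histogram_normalized(self, random_image):
        h = lbp_histogram(random_image)
        assert h.sum() == pytest.approx(1.0)
        assert np.all(h >= 0)

    def test_rlbp_single_radius_equals_lbp(self, random_image):
        a = rlbp_histogram(random_image, LBPSpec(), n_radii=1)
        b = lbp_histogram(random_image, LBPSpec())
        assert np.allclose(a, b)

    def test_rlbp_codes_match_bruteforce(self, rng):
        img = rng.random((16, 16))
        assert np.array_equal(rlbp_codes(img, LBPSpec(), 3), _rlbp_oracle(img, 8, 3))

    def test_rlbp_constant_all_ones(self):
        codes = rlbp_codes(np.full((12, 12), 0.7), LBPSpec(), 2)
        assert np.all(codes == 255)

    def test_ltp_definition_cases(self):
        # centre 0.5, t = 0.1: 0.65 -> +1 ; 0.45 -> 0 ; 0.30 -> -1
        img = np.full((3, 3), 0.5)
        img[1, 2], img[0, 2], img[0, 1] = 0.65, 0.45, 0.30
        upper, lower = ltp_codes(img, LBPSpec(), t=0.1)
        assert upper[0, 0] & 0b001 == 1       # east neighbour above the band
        assert upper[0, 0] & 0b010 == 0       # NE inside the band
        assert lower[0, 0] & 0b100 == 0b100   # north below the band
        assert lower[0, 0] & 0b011 == 0

    def test_ltp_constant_upper_all_zero(self):
        upper, lower = ltp_codes(np.full((8, 8), 0.5), t=0.1)
        assert np.all(upper == 0) and np.all(lower == 0)

    def test_ltp_zero_threshold_limit_is_strict_lbp(self, random_image):
        upper, _ = ltp_codes(random_image, LBPSpec(), t=1e-12)
        assert np.array_equal(upper, _lbp_oracle(random_image, 1.0, 8))

    def test_ltp_out_of_range_threshold(self):
        with pytest.raises(ValueError):
            ltp_codes(np.zeros((8, 8)), t=1.5)

    def test_image_too_small_raises(self):
        with pytest.raises(ValueError):
            lbp_codes(np.zeros((2, 2)), LBPSpec(radius=1))


class TestGabor:
    def test_kernels_unit_norm_and_center_values(self):
        spec = GaborBankSpec()
        for f in spec.frequencies:
            for th in spec.orientations:
                gc, gs = gabor_kernel(spec, f, th)
                assert np.linalg.norm(gc) == pytest.approx(1.0, abs=1e-12)
                assert np.linalg.norm(gs) == pytest.approx(1.0, abs=1e-12)
                assert gs[spec.kernel_halfwidth, spec.kernel_halfwidth] == 0.0
                assert gc[spec.kernel_halfwidth, spec.kernel_halfwidth] > 0

    def test_odd_kernel_sums_to_zero(self):
        gc, gs = gabor_kernel(GaborBankSpec(), 0.25, 0.0)
        assert abs(gs.sum()) < 1e-10

    def test_features_nonnegative_and_constant_flat(self, phantom):
        feats = gabor_features(phantom)
        assert np.all(feats >= 0)
        const_feats = gabor_features(np.full((32, 32), 0.5))
        assert np.all(np.isfinite(const_feats))

    def test_grating_excites_matching_orientation(self):
        spec = GaborBankSpec(frequencies=(0.25,), orientations=(0.0, np.pi / 2))
        rows = np.arange(32)
        grating = 0.5 + 0.5 * np.sin(2 * np.pi * 0.25 * rows)
        # phase axis is (i cos t + j sin t) with i the row index, so a
        # grating varying along rows matches theta = 0
        img = np.tile(grating.reshape(-1, 1), (1, 32))
        f_match, f_orth = gabor_features(img, spec)
        assert f_match > 2 * f_orth

    def test_too_small_image_raises(self):
        with pytest.raises(ValueError):
            gabor_features(np.zeros((8, 8)), GaborBankSpec(kernel_halfwidth=7))


def _log_energy_oracle(img, level, eps):
    """Straight-line transliteration of the wavelet log-energy recipe."""
    import pywt
    A = []
    H = []
    V = []
    D = []
    a1 = img
    for _ in range(level):
        a1, (a2, a3, a4) = pywt.dwt2(a1, "haar")
        A.append(np.mean(np.log(np.abs(np.fft.fftshift(np.fft.fft2(a1))) + eps)))
        H.append(np.mean(np.log(np.abs(np.fft.fftshift(np.fft.fft2(a2))) + eps)))
        V.append(np.mean(np.log(np.abs(np.fft.fftshift(np.fft.fft2(a3))) + eps)))
        D.append(np.mean(np.log(np.abs(np.fft.fftshift(np.fft.fft2(a4))) + eps)))
    return np.array([np.sum(np.diff(A)), np.sum(np.diff(H)),
                     np.sum(np.diff(V)), np.sum(np.diff(D))])


class TestLogEnergy:
    def test_level_one_forced_zeros(self, random_image):
        assert np.array_equal(log_energy(random_image, LogEnergySpec(level=1)),
                              np.zeros(4))

    def test_matches_transliterated_recipe(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            img = rng.random((16, 16))
            ours = log_energy(img, LogEnergySpec(level=2))
            assert np.allclose(ours, _log_energy_oracle(img, 2, 1e-12), atol=1e-9)

    def test_detail_channels_invariant_to_global_offset(self, rng):
        img = rng.random((16, 16)) * 0.5
        base = log_energy(img, LogEnergySpec(level=2))
        shifted = log_energy(img + 0.25, LogEnergySpec(level=2))
        assert np.allclose(base[1:], shifted[1:], atol=1e-9)

    def test_level_too_deep_raises(self):
        with pytest.raises(ValueError):
            log_energy(np.zeros((8, 8)), LogEnergySpec(level=4))


class TestPatchFilters:
    def test_constant_image_zero(self):
        const = np.full((32, 32), 0.7)
        assert pca_filter_feature(const) == 0.0
        assert ica_filter_feature(const) == 0.0

    def test_pca_filter_matches_eigendecomposition(self, rng):
        img = rng.random((32, 32))
        ours = pca_filter_feature(img, patch=8)
        tiles = img.reshape(4, 8, 4, 8).transpose(0, 2, 1, 3).reshape(-1, 64)
        tc = tiles - tiles.mean(axis=0)
        w, v = np.linalg.eigh(np.cov(tc.T, bias=True))
        scores = tc @ v[:, -1]
        assert ours == pytest.approx(np.mean(np.abs(scores)), abs=1e-9)
        assert ours >= 0

    def test_ica_deterministic_given_seed(self, rng):
        img = rng.random((32, 32))
        assert ica_filter_feature(img, seed=3) == ica_filter_feature(img, seed=3)

    def test_ica_recovers_mixed_source(self):
        rng = np.random.default_rng(5)
        n_tiles, d = 64, 64
        s1 = np.sign(rng.normal(size=n_tiles))           # super-Gaussian source
        s2 = rng.uniform(-1, 1, size=n_tiles)
        m1, m2 = rng.normal(size=d), rng.normal(size=d)
        tiles = np.outer(s1, m1) + np.outer(s2, m2)
        tiles = (tiles - tiles.min()) / (tiles.max() - tiles.min())
        img = tiles.reshape(8, 8, 8, 8).transpose(0, 2, 1, 3).reshape(64, 64)
        from sklearn.decomposition import FastICA
        ica = FastICA(n_components=2, algorithm="deflation", fun="logcosh",
                      max_iter=400, tol=1e-4, random_state=0, whiten="unit-variance")
        comps = ica.fit_transform(tiles)
        corr = max(abs(np.corrcoef(comps[:, i], s1)[0, 1]) for i in range(2))
        assert corr > 0.9

    def test_too_few_tiles_raises(self):
        with pytest.raises(ValueError):
            pca_filter_feature(np.zeros((8, 8)), patch=8)


class TestHistogramProperties:
    from hypothesis import given, settings, strategies as st
    from hypothesis.extra.numpy import arrays

    @given(arrays(np.float64, (12, 12), elements=st.floats(0, 1, width=16)))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_all_pattern_histograms_normalized_and_finite(self, img):
        for hist in (lbp_histogram(img), rlbp_histogram(img, n_radii=2),
                     *ltp_histograms(img)):
            assert np.all(hist >= 0)
            assert hist.sum() == pytest.approx(1.0, abs=1e-9)

    @given(arrays(np.float64, (10, 10), elements=st.floats(0, 1, width=16)))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_texture_features_finite_on_arbitrary_images(self, img):
        assert np.all(np.isfinite(texture.glcm_features(img)))
        assert np.all(np.isfinite(log_energy(img)))
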