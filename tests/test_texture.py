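"""Co-occurrence matrix construction and the five texture statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import stainqc as sq
from stainqc.texture import EmptyCooccurrenceError

from helpers import brute_force_glcm_counts


def make_glcm(p):
    """Wrap a probability grid as a GLCMatrix (counts scaled arbitrarily)."""
    p = np.asarray(p, dtype=float)
    counts = np.rint(p * 1000).astype(np.int64)
    return sq.GLCMatrix(p=p, counts=counts, total_pairs=int(counts.sum()) or 1)


class TestComputeGLCM:
    def test_constant_image_single_cell(self):
        img = sq.GrayImage(np.full((4, 4), 7, dtype=np.uint8))
        g = sq.compute_glcm(img, sq.GLCMConfig(d=2, phi=0))
        assert g.counts[7, 7] == 8
        assert g.total_pairs == 8
        assert g.p[7, 7] == 1.0

    def test_alternating_strip(self):
        img = sq.GrayImage(np.array([[0, 1, 0, 1]]), levels=2)
        g = sq.compute_glcm(img, sq.GLCMConfig(d=2, phi=0))
        assert g.p[0, 0] == 0.5 and g.p[1, 1] == 0.5
        assert g.p[0, 1] == 0.0 and g.p[1, 0] == 0.0

    @pytest.mark.parametrize("phi", [0, 45, 90, 135])
    @pytest.mark.parametrize("d", [1, 2, 3])
    def test_matches_bruteforce_with_mask(self, rng, phi, d):
        px = rng.integers(0, 16, size=(24, 31)).astype(np.uint8)
        mask = rng.random((24, 31)) > 0.3
        mask[0, 0] = True  # keep the mask nonempty
        img = sq.GrayImage(px, mask=mask, levels=16)
        for symmetric in (False, True):
            g = sq.compute_glcm(img, sq.GLCMConfig(d=d, phi=phi, symmetric=symmetric))
            expected = brute_force_glcm_counts(px, mask, d, phi, 16, symmetric)
            np.testing.assert_array_equal(g.counts, expected)
            assert g.total_pairs == expected.sum()
            assert abs(g.p.sum() - 1.0) < 1e-12

    def test_lr_flip_transposes_counts(self, rng):
        px = rng.integers(0, 8, size=(12, 17)).astype(np.uint8)
        img = sq.GrayImage(px, levels=8)
        flipped = sq.GrayImage(px[:, ::-1].copy(), levels=8)
        cfg = sq.GLCMConfig(d=2, phi=0)
        a = sq.compute_glcm(img, cfg).counts
        b = sq.compute_glcm(flipped, cfg).counts
        np.testing.assert_array_equal(a, b.T)

    def test_symmetric_mode_yields_symmetric_matrix(self, rng):
        px = rng.integers(0, 12, size=(10, 10)).astype(np.uint8)
        g = sq.compute_glcm(sq.GrayImage(px, levels=12),
                            sq.GLCMConfig(d=1, phi=45, symmetric=True))
        np.testing.assert_array_equal(g.counts, g.counts.T)

    def test_matches_skimage_on_unmasked_image(self, rng):
        graycomatrix = pytest.importorskip("skimage.feature").graycomatrix
        px = rng.integers(0, 32, size=(20, 20)).astype(np.uint8)
        ours = sq.compute_glcm(sq.GrayImage(px, levels=32),
                               sq.GLCMConfig(d=2, phi=0)).counts
        theirs = graycomatrix(px, distances=[2], angles=[0], levels=32,
                              symmetric=False, normed=False)[:, :, 0, 0]
        np.testing.assert_array_equal(ours, theirs)

    def test_mask_thinner_than_displacement_raises(self):
        px = np.zeros((6, 6), dtype=np.uint8)
        mask = np.zeros((6, 6), dtype=bool)
        mask[3, 2] = True  # a single pixel: no pair at any displacement
        with pytest.raises(EmptyCooccurrenceError):
            sq.compute_glcm(sq.GrayImage(px, mask=mask), sq.GLCMConfig(d=2, phi=0))

    def test_out_of_range_intensity_rejected(self):
        with pytest.raises(ValueError):
            sq.GrayImage(np.array([[0, 5]]), levels=4)


class TestMarginalsAndFeatures:
    def test_point_mass_marginals(self):
        p = np.zeros((16, 16))
        p[7, 7] = 1.0
        m = sq.glcm_marginals(make_glcm(p))
        assert m.ux == m.uy == 7.0
        assert m.sx == m.sy == 0.0

    def test_two_cell_diagonal_marginals(self):
        p = np.zeros((4, 4))
        p[0, 0] = p[1, 1] = 0.5
        m = sq.glcm_marginals(make_glcm(p))
        assert m.ux == m.uy == pytest.approx(0.5)
        assert m.sx == m.sy == pytest.approx(0.5)

    def test_uniform_marginals(self):
        ng = 8
        m = sq.glcm_marginals(make_glcm(np.full((ng, ng), 1.0 / ng**2)))
        assert m.ux == m.uy == pytest.approx((ng - 1) / 2)

    def test_point_mass_features(self):
        p = np.zeros((16, 16))
        p[5, 5] = 1.0
        tf = sq.texture_features(make_glcm(p))
        assert tf.energy == 1.0
        assert tf.inertia == 0.0
        assert tf.idm == 1.0
        assert tf.entropy == 0.0
        assert not tf.correlation_defined
        assert math.isnan(tf.correlation)

    def test_two_cell_diagonal_features(self):
        p = np.zeros((4, 4))
        p[0, 0] = p[1, 1] = 0.5
        tf = sq.texture_features(make_glcm(p))
        assert tf.energy == pytest.approx(0.5)
        assert tf.inertia == 0.0
        assert tf.idm == pytest.approx(1.0)
        assert tf.entropy == pytest.approx(math.log(2))
        assert tf.correlation == pytest.approx(1.0)

    def test_uniform_features(self):
        ng = 16
        tf = sq.texture_features(make_glcm(np.full((ng, ng), 1.0 / ng**2)))
        assert tf.energy == pytest.approx(1.0 / ng**2)
        assert tf.entropy == pytest.approx(math.log(ng**2))

    def test_entropy_log_base_two(self):
        p = np.zeros((4, 4))
        p[0, 0] = p[1, 1] = 0.5
        cfg = sq.GLCMConfig(entropy_log_base="2")
        assert sq.texture_features(make_glcm(p), cfg).entropy == pytest.approx(1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**32 - 1),
           st.sampled_from([0, 45, 90, 135]))
    def test_feature_ranges_on_random_images(self, seed, phi):
        rng = np.random.default_rng(seed)
        ng = int(rng.integers(2, 24))
        px = rng.integers(0, ng, size=(int(rng.integers(6, 24)),
                                       int(rng.integers(6, 24)))).astype(np.uint8)
        cfg = sq.GLCMConfig(d=1, phi=phi)
        g = sq.compute_glcm(sq.GrayImage(px, levels=ng), cfg)
        assert abs(g.p.sum() - 1.0) < 1e-12
        tf = sq.texture_features(g, cfg)
        assert 1.0 / ng**2 - 1e-12 <= tf.energy <= 1.0 + 1e-12
        assert tf.inertia >= 0.0
        assert 0.0 < tf.idm <= 1.0 + 1e-12
        assert -1e-12 <= tf.entropy <= math.log(ng**2) + 1e-12
        if tf.correlation_defined:
            assert -1.0 - 1e-9 <= tf.correlation <= 1.0 + 1e-9

    def test_constant_region_is_extremal(self):
        """Energy and IDM peak at 1, inertia and entropy floor at 0."""
        img = sq.GrayImage(np.full((9, 9), 42, dtype=np.uint8))
        tf = sq.texture_features(sq.compute_glcm(img))
        assert (tf.energy, tf.idm, tf.inertia, tf.entropy) == (1.0, 1.0, 0.0, 0.0)


class TestUtilities:
    def test_requantize_halves_levels(self):
        img = sq.GrayImage(np.arange(256, dtype=np.uint8).reshape(16, 16))
        q = sq.requantize(img, 8)
        assert q.levels == 8
        assert q.pixels.min() == 0 and q.pixels.max() == 7

    def test_load_gray_image_roundtrip(self, tmp_path, rng):
        from PIL import Image

        px = rng.integers(0, 256, size=(10, 12)).astype(np.uint8)
        path = tmp_path / "gray.png"
        Image.fromarray(px).save(path)
        loaded = sq.load_gray_image(path)
        np.testing.assert_array_equal(loaded.pixels, px)

    def test_load_rgb_image_uses_luminance(self, tmp_path, rng):
        from PIL import Image

        arr = rng.integers(0, 256, size=(8, 8, 3)).astype(np.uint8)
        path = tmp_path / "rgb.png"
        Image.fromarray(arr).save(path)
        loaded = sq.load_gray_image(path)
        assert loaded.pixels.shape == (8, 8)
        np.testing.assert_allclose(loaded.pixels,
                                   arr.mean(axis=2).astype(np.uint8), atol=1)
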