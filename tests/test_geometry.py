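"""Deposit segmentation, region partition and morphometry."""

import numpy as np
import pytest

import stainqc as sq
from stainqc.geometry import SegmentationError


def disk_image(size=256, radius=100.0, level=200, background=20):
    rr, cc = np.indices((size, size))
    c = (size - 1) / 2
    dist = np.hypot(rr - c, cc - c)
    px = np.full((size, size), background, dtype=np.uint8)
    px[dist <= radius] = level
    return sq.GrayImage(px), (c, c)


class TestSegmentStain:
    def test_filled_disk_geometry(self):
        img, center = disk_image(radius=100.0)
        geom = sq.segment_stain(img)
        assert geom.radius == pytest.approx(100.0, abs=1.0)
        assert geom.center[0] == pytest.approx(center[0], abs=1.0)
        assert geom.center[1] == pytest.approx(center[1], abs=1.0)
        assert geom.diameter == 2 * geom.radius

    def test_synthetic_stain_radius_recovery(self, clean_stain):
        img, truth = clean_stain
        geom = sq.segment_stain(img)
        assert geom.radius == pytest.approx(truth.radius, rel=0.02)

    def test_blank_image_fails(self):
        with pytest.raises(SegmentationError):
            sq.segment_stain(sq.GrayImage(np.full((64, 64), 33, dtype=np.uint8)))

    def test_dark_deposit_on_bright_background(self):
        img, _ = disk_image(level=30, background=220)
        geom = sq.segment_stain(img)
        assert geom.radius == pytest.approx(100.0, abs=1.5)


class TestPartitionRegions:
    def test_fixed_fraction_radii(self):
        img, _ = disk_image(radius=100.0)
        geom = sq.segment_stain(img)
        regions = sq.partition_regions(img, geom, fractions=(0.5, 0.6, 0.95))
        assert regions.r_center == pytest.approx(0.5 * geom.radius)
        assert regions.r_in == pytest.approx(0.6 * geom.radius)
        assert regions.r_out == pytest.approx(0.95 * geom.radius)

    def test_masks_disjoint_and_nested(self, clean_stain):
        img, _ = clean_stain
        geom = sq.segment_stain(img)
        regions = sq.partition_regions(img, geom)
        assert not (regions.crown & regions.center).any()
        assert not (regions.crown & ~regions.complete).any()
        assert not (regions.center & ~regions.complete).any()
        assert regions.crown.any() and regions.center.any()

    def test_bad_fractions_rejected(self, clean_stain):
        img, _ = clean_stain
        geom = sq.segment_stain(img)
        with pytest.raises(ValueError):
            sq.partition_regions(img, geom, fractions=(0.7, 0.6, 0.95))

    def test_auto_crown_recovers_generated_annulus(self):
        # crown rendered at [0.7R, 0.9R]: R=150, ring 15, thickness 30
        params = sq.StainParams(seed=11, noise_sd=0.0, ring_width=15.0,
                                crown_thickness=30.0, gamma_jitter=0.0)
        img, truth = sq.render_stain(params)
        geom = sq.segment_stain(img)
        regions = sq.partition_regions(img, geom, auto_crown=True)
        R = geom.radius
        assert regions.r_in / R == pytest.approx(truth.r_crown_inner / truth.radius, abs=0.05)
        assert regions.r_out / R == pytest.approx(truth.r_crown_outer / truth.radius, abs=0.05)


class TestCrownThickness:
    def test_uniform_crown_recovery(self):
        params = sq.StainParams(seed=3, noise_sd=0.0, crown_thickness=20.0,
                                gamma_jitter=0.0)
        img, truth = sq.render_stain(params)
        geom = sq.segment_stain(img)
        cm = sq.crown_thickness(img, geom)
        assert cm.gamma == pytest.approx(20.0, abs=1.0)
        assert cm.ray_thicknesses.shape == (8,)
        assert cm.gamma == pytest.approx(cm.ray_thicknesses.mean())

    def test_no_crown_flag(self):
        params = sq.StainParams(seed=5, crown_thickness=0.0, crown_texture_sd=0.0)
        img, _ = sq.render_stain(params)
        geom = sq.segment_stain(img)
        cm = sq.crown_thickness(img, geom)
        assert cm.gamma == 0.0
        assert cm.no_crown

    def test_group_means_ordered_by_true_thickness(self):
        means = []
        for gt in (20.0, 10.0):
            base = sq.StainParams(crown_thickness=gt)
            vals = []
            for img, _ in sq.make_group(base, 0.0, 6, master_seed=99):
                geom = sq.segment_stain(img)
                vals.append(sq.crown_thickness(img, geom).gamma)
            means.append(np.mean(vals))
        assert means[0] > means[1]

    def test_rotation_invariance(self):
        params = sq.StainParams(seed=13, noise_sd=0.0, crown_thickness=25.0)
        img, _ = sq.render_stain(params)
        rotated = sq.GrayImage(np.rot90(img.pixels).copy())
        g1 = sq.crown_thickness(img, sq.segment_stain(img)).gamma
        g2 = sq.crown_thickness(rotated, sq.segment_stain(rotated)).gamma
        assert g1 == pytest.approx(g2, abs=1.0)


class TestNormalizeCrown:
    def test_identity_and_arithmetic(self):
        assert sq.normalize_crown(15.0, 15.0) == 1.0
        assert sq.normalize_crown(7.5, 15.0) == 0.5

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            sq.normalize_crown(10.0, 0.0)

    def test_control_group_normalizes_to_one(self):
        base = sq.StainParams()
        gammas = []
        for img, _ in sq.make_group(base, 0.0, 8, master_seed=17):
            gammas.append(sq.crown_thickness(img, sq.segment_stain(img)).gamma)
        gamma0 = float(np.mean(gammas))
        normalized = [sq.normalize_crown(g, gamma0) for g in gammas]
        assert np.mean(normalized) == pytest.approx(1.0, abs=1e-9)


class TestAggregateArea:
    def _regions(self, img):
        geom = sq.segment_stain(img)
        return sq.partition_regions(img, geom)

    def test_known_crystal_area_recovery(self, clean_stain):
        img, truth = clean_stain
        agg = sq.central_aggregate_area(img, self._regions(img))
        assert agg.area == pytest.approx(truth.crystal_area_true, rel=0.05)

    def test_featureless_center_reports_zero(self):
        params = sq.StainParams(seed=21, crystal_count=0, noise_sd=2.0)
        img, _ = sq.render_stain(params)
        agg = sq.central_aggregate_area(img, self._regions(img))
        assert agg.area == 0.0
        assert agg.component_count == 0

    def test_two_components_counted_separately(self):
        # two hand-placed 1000 px rectangles inside a plain deposit
        rr, cc = np.indices((384, 384))
        dist = np.hypot(rr - 191.5, cc - 191.5)
        px = np.full((384, 384), 20, dtype=np.uint8)
        px[dist <= 150] = 90
        px[150:190, 140:165] = 200  # 40 x 25 = 1000 px
        px[200:240, 220:245] = 200
        img = sq.GrayImage(px)
        agg = sq.central_aggregate_area(img, self._regions(img))
        assert agg.component_count == 2
        assert agg.area == pytest.approx(2000, rel=0.01)

    def test_subthreshold_components_dropped(self):
        rr, cc = np.indices((256, 256))
        dist = np.hypot(rr - 127.5, cc - 127.5)
        px = np.full((256, 256), 20, dtype=np.uint8)
        px[dist <= 100] = 90
        px[120:124, 120:124] = 200  # 16 px < default 25 px threshold
        img = sq.GrayImage(px)
        agg = sq.central_aggregate_area(img, self._regions(img))
        assert agg.area == 0.0
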