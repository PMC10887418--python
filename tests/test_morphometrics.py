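"""Segmentation and shape-descriptor measurements."""

import numpy as np
import pytest
from skimage.draw import disk as draw_disk, ellipse as draw_ellipse

from nanomech import (
    LabelMask,
    segment_threshold,
    shape_descriptors,
    tumor_area_ratio,
)
from nanomech import synthetic as syn


def _binary_image(shapes, size=(256, 256)):
    img = np.zeros(size)
    for rr, cc in shapes:
        img[rr, cc] = 1.0
    return img


class TestSegmentation:
    def test_two_disks_two_labels(self):
        img = _binary_image(
            [draw_disk((64, 64), 20), draw_disk((180, 180), 30)]
        )
        mask = segment_threshold(img, method="fixed", threshold=0.5)
        assert mask.n_labels == 2

    def test_min_area_filter(self):
        img = _binary_image(
            [draw_disk((64, 64), 20), draw_disk((180, 180), 4)]
        )
        mask = segment_threshold(
            img, method="fixed", threshold=0.5, min_area_px=200
        )
        assert mask.n_labels == 1

    def test_blank_image_empty_mask(self):
        mask = segment_threshold(np.zeros((64, 64)))
        assert mask.n_labels == 0

    def test_otsu_on_noisy_foreground(self):
        rng = np.random.default_rng(3)
        img = rng.normal(0.1, 0.02, (128, 128))
        rr, cc = draw_disk((64, 64), 25)
        img[rr, cc] = rng.normal(0.9, 0.02, rr.size)
        mask = segment_threshold(img, min_area_px=50)
        assert mask.n_labels == 1


class TestShapeDescriptors:
    def test_disk_limits(self):
        img = _binary_image([draw_disk((100, 100), 50)], size=(200, 200))
        d = shape_descriptors(segment_threshold(img, "fixed", 0.5))[0]
        assert 0.95 <= d.circularity <= 1.05
        assert 1.0 <= d.aspect_ratio <= 1.05
        assert d.solidity >= 0.98

    def test_ellipse_moment_aspect_ratio(self):
        img = _binary_image(
            [draw_ellipse(100, 100, 20, 40)], size=(200, 200)
        )
        d = shape_descriptors(segment_threshold(img, "fixed", 0.5))[0]
        assert d.aspect_ratio == pytest.approx(2.0, abs=0.05)

    def test_cross_low_solidity(self):
        img = np.zeros((200, 200))
        img[40:160, 90:110] = 1.0
        img[90:110, 40:160] = 1.0
        d = shape_descriptors(segment_threshold(img, "fixed", 0.5))[0]
        # brute-force hull area of a plus shape: solidity well below 0.9
        assert d.solidity < 0.9

    def test_units_scale_with_pixel_size(self):
        img = _binary_image([draw_disk((100, 100), 30)], size=(200, 200))
        d1 = shape_descriptors(
            segment_threshold(img, "fixed", 0.5, pixel_size_um=1.0)
        )[0]
        d2 = shape_descriptors(
            segment_threshold(img, "fixed", 0.5, pixel_size_um=0.5)
        )[0]
        assert d2.area_um2 == pytest.approx(d1.area_um2 / 4, rel=1e-9)
        assert d2.perimeter_um == pytest.approx(d1.perimeter_um / 2, rel=1e-9)

    def test_rotation_invariance(self):
        img = _binary_image(
            [draw_ellipse(100, 100, 25, 45, rotation=0.3)], size=(200, 200)
        )
        d0 = shape_descriptors(segment_threshold(img, "fixed", 0.5))[0]
        d90 = shape_descriptors(
            segment_threshold(np.rot90(img), "fixed", 0.5)
        )[0]
        for attr in ("area_um2", "aspect_ratio", "circularity", "solidity"):
            assert getattr(d90, attr) == pytest.approx(
                getattr(d0, attr), rel=0.02
            )

    def test_intensity_scale_invariance(self):
        rng = np.random.default_rng(4)
        img = rng.normal(0.1, 0.02, (128, 128))
        rr, cc = draw_disk((64, 64), 25)
        img[rr, cc] = 0.9
        d1 = shape_descriptors(segment_threshold(img))[0]
        d2 = shape_descriptors(segment_threshold(img * 7.5))[0]
        assert d2.circularity == pytest.approx(d1.circularity, rel=0.02)

    def test_circularity_converges_with_radius(self):
        errs = []
        for radius in (10, 30, 100):
            size = 4 * radius
            img = _binary_image(
                [draw_disk((size // 2, size // 2), radius)], size=(size, size)
            )
            d = shape_descriptors(segment_threshold(img, "fixed", 0.5))[0]
            errs.append(abs(d.circularity - 1.0))
        assert errs[2] <= errs[0]
        assert max(errs) < 0.05
        assert errs[2] < 0.01

    def test_degenerate_object_flagged(self):
        labels = np.zeros((32, 32), dtype=int)
        labels[10, 5:25] = 1  # one-pixel line
        d = shape_descriptors(LabelMask(labels))[0]
        assert "degenerate" in d.flags


class TestPopulationRecovery:
    def test_aspect_ratio_recovery(self):
        """Measured aspect ratios track the generating ellipses (r >= 0.99,
        MAE <= 0.05) over a 100-cell synthetic population."""
        from skimage.measure import regionprops

        spec = syn.CellPopulationSpec(
            n_cells=100,
            aspect_ratio_dist=(1.8, 0.5),
            size_dist_um2=(400.0, 80.0),
            image_size_px=(1024, 1024),
            pixel_size_um=0.5,
            seed=7,
        )
        img, truth = syn.simulate_cell_image(spec)
        mask = segment_threshold(img, min_area_px=30, pixel_size_um=0.5)
        assert mask.n_labels == 100
        descs = {d.label: d for d in shape_descriptors(mask)}
        cents = {p.label: p.centroid for p in regionprops(mask.labels)}
        measured, expected = [], []
        for _, row in truth.iterrows():
            label = min(
                cents,
                key=lambda L: (cents[L][0] - row.center_row) ** 2
                + (cents[L][1] - row.center_col) ** 2,
            )
            measured.append(descs[label].aspect_ratio)
            expected.append(row.aspect_ratio)
        measured, expected = np.array(measured), np.array(expected)
        assert np.corrcoef(measured, expected)[0, 1] >= 0.99
        assert np.mean(np.abs(measured - expected)) <= 0.05

    def test_roughness_lowers_solidity(self):
        solidities = []
        for roughness in (0.0, 0.5):
            spec = syn.CellPopulationSpec(
                n_cells=10,
                aspect_ratio_dist=(1.5, 0.2),
                boundary_roughness=roughness,
                image_size_px=(512, 512),
                seed=11,
            )
            img, _ = syn.simulate_cell_image(spec)
            descs = shape_descriptors(segment_threshold(img, min_area_px=30))
            solidities.append(np.mean([d.solidity for d in descs]))
        assert solidities[1] < solidities[0]


class TestTumorAreaRatio:
    def test_half_coverage(self):
        body = np.ones((10, 10), bool)
        pigment = np.zeros((10, 10), bool)
        pigment[:5] = True
        assert tumor_area_ratio(pigment, body) == pytest.approx(0.5)

    def test_extremes(self):
        body = np.ones((8, 8), bool)
        assert tumor_area_ratio(np.zeros((8, 8), bool), body) == 0.0
        assert tumor_area_ratio(np.ones((8, 8), bool), body) == 1.0

    def test_empty_body_errors(self):
        with pytest.raises(ValueError):
            tumor_area_ratio(np.ones((4, 4), bool), np.zeros((4, 4), bool))
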