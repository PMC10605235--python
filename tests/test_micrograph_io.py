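"""Micrograph container, file round trips, preprocessing, exclusions, annotations."""
import json

import numpy as np
import pytest
import tifffile
from hypothesis import given, settings
from hypothesis import strategies as st

import ledscan as ls
from ledscan.errors import FormatError, ValidationError
from ledscan.records import AnnotationSet, ParticleRecord


class TestReadWrite:
    def test_8bit_saturated_maps_to_one(self, tmp_path):
        tifffile.imwrite(tmp_path / "a.tif", np.full((16, 16), 255, dtype=np.uint8))
        img = ls.read_micrograph(tmp_path / "a.tif", 1.0)
        assert np.all(img.pixels == 1.0)

    def test_16bit_zero_maps_to_zero(self, tmp_path):
        tifffile.imwrite(tmp_path / "a.tif", np.zeros((16, 16), dtype=np.uint16))
        img = ls.read_micrograph(tmp_path / "a.tif", 1.0)
        assert np.all(img.pixels == 0.0)

    def test_round_trip_within_16bit_precision(self, tmp_path):
        rng = np.random.default_rng(0)
        img = ls.Micrograph(rng.random((64, 64)), 2.5)
        ls.write_micrograph(img, tmp_path / "rt.tif")
        back = ls.read_micrograph(tmp_path / "rt.tif", 2.5)
        assert np.abs(back.pixels - img.pixels).max() <= 1.0 / 65535 + 1e-12

    def test_rgb_collapsed_by_luminance(self, tmp_path):
        import imageio.v3 as iio

        rgb = np.zeros((8, 8, 3), dtype=np.uint8)
        rgb[..., 1] = 255  # pure green
        iio.imwrite(tmp_path / "rgb.png", rgb)
        img = ls.read_micrograph(tmp_path / "rgb.png", 1.0)
        assert img.pixels.ndim == 2
        assert np.allclose(img.pixels, 0.587, atol=0.01)

    def test_missing_file_and_bad_scale(self, tmp_path):
        with pytest.raises(IOError):
            ls.read_micrograph(tmp_path / "nope.tif", 1.0)
        tifffile.imwrite(tmp_path / "a.tif", np.zeros((4, 4), dtype=np.uint8))
        with pytest.raises(ValidationError):
            ls.read_micrograph(tmp_path / "a.tif", -1.0)

    def test_container_invariants(self):
        with pytest.raises(ValidationError):
            ls.Micrograph(np.full((4, 4), 2.0), 1.0)
        with pytest.raises(ValidationError):
            ls.Micrograph(np.zeros((4, 4)), 1.0, exclusion_mask=np.zeros((3, 3), bool))


class TestBrightnessContrast:
    def test_identity_at_zero(self):
        img = ls.Micrograph(np.random.default_rng(1).random((32, 32)), 1.0)
        out = ls.adjust_brightness_contrast(img, 0.0, 0.0)
        np.testing.assert_allclose(out.pixels, img.pixels)

    def test_midpoint_is_contrast_fixed_point(self):
        img = ls.Micrograph(np.full((8, 8), 0.5), 1.0)
        out = ls.adjust_brightness_contrast(img, 0.0, 80.0)
        np.testing.assert_allclose(out.pixels, 0.5)

    def test_hand_evaluated_value(self):
        """v=0.4 with +50% brightness, +80% contrast: v1=0.6, v2=0.1*1.8+0.5=0.68."""
        img = ls.Micrograph(np.full((4, 4), 0.4), 1.0)
        out = ls.adjust_brightness_contrast(img, 50.0, 80.0)
        np.testing.assert_allclose(out.pixels, 0.68)

    @settings(max_examples=50, deadline=None)
    @given(
        v=st.lists(st.floats(0, 1), min_size=2, max_size=16),
        b=st.floats(-99, 200),
        c=st.floats(-99, 200),
    )
    def test_monotone_in_intensity(self, v, b, c):
        """The transform preserves intensity ordering (before and after clipping)."""
        arr = np.sort(np.asarray(v))
        img = ls.Micrograph(arr[None, :], 1.0)
        out = ls.adjust_brightness_contrast(img, b, c).pixels[0]
        assert np.all(np.diff(out) >= -1e-12)

    def test_preserves_shape_scale_and_masks(self):
        mask = np.zeros((8, 8), bool)
        mask[0, 0] = True
        img = ls.Micrograph(np.full((8, 8), 0.3), 3.0, exclusion_mask=mask)
        out = ls.adjust_brightness_contrast(img)
        assert out.shape == img.shape
        assert out.scale_nm_per_px == 3.0
        np.testing.assert_array_equal(out.exclusion_mask, mask)

    def test_percentages_below_minus_100_rejected(self):
        img = ls.Micrograph(np.zeros((4, 4)), 1.0)
        with pytest.raises(ValidationError):
            ls.adjust_brightness_contrast(img, -150.0, 0.0)


class TestExclusion:
    def test_empty_region_list_unchanged(self):
        img = ls.Micrograph(np.zeros((8, 8)), 1.0)
        out = ls.apply_exclusion(img, [])
        assert out.exclusion_mask.sum() == 0

    def test_rectangle_pixel_count_matches_brute_force(self):
        """Axis-aligned 10x10 px rectangle excludes exactly the 100 enclosed centers."""
        img = ls.Micrograph(np.zeros((50, 50)), 1.0)
        poly = np.array([[-0.5, -0.5], [-0.5, 9.5], [9.5, 9.5], [9.5, -0.5]])
        out = ls.apply_exclusion(img, [poly])
        # brute-force point-in-polygon over all pixel centers
        from shapely.geometry import Point, Polygon

        shp = Polygon([(r, c) for r, c in poly])
        expected = sum(
            shp.contains(Point(r, c)) for r in range(50) for c in range(50)
        )
        assert expected == 100
        assert out.exclusion_mask.sum() == expected

    def test_full_frame_exclusion_suppresses_detection(self, clean_bead_scene):
        img, _ = clean_bead_scene
        h, w = img.shape
        poly = np.array([[-1, -1], [-1, w], [h, w], [h, -1]])
        excluded = ls.apply_exclusion(img, [poly])
        assert ls.detect_particles(excluded) == []

    def test_degenerate_polygon_rejected(self):
        img = ls.Micrograph(np.zeros((8, 8)), 1.0)
        with pytest.raises(ValidationError):
            ls.apply_exclusion(img, [np.array([[0, 0], [1, 1]])])


def _random_particles(n, shape, scale, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        out.append(ParticleRecord(
            id=i,
            centroid_nm=(
                float(rng.uniform(0, (shape[1] - 1) * scale)),
                float(rng.uniform(0, (shape[0] - 1) * scale)),
            ),
            equivalent_diameter_nm=float(rng.uniform(4, 12)),
            circularity=float(rng.uniform(0.6, 1.0)),
            mean_core_intensity=float(rng.uniform(0, 0.3)),
            size_class=rng.choice(["6nm", "10nm"]),
        ))
    return out


class TestAnnotations:
    def test_empty_round_trip(self, tmp_path):
        ann = AnnotationSet(provenance={"image_shape_px": [64, 64], "scale_nm_per_px": 1.0})
        ls.write_annotations(ann, tmp_path / "empty.json")
        back = ls.read_annotations(tmp_path / "empty.json")
        assert back.particles == [] and back.ledds == []
        assert back.provenance["image_shape_px"] == [64, 64]

    def test_hundred_particles_round_trip(self, tmp_path):
        particles = _random_particles(100, (256, 256), 1.5, seed=4)
        ann = AnnotationSet(
            particles=particles,
            provenance={"image_shape_px": [256, 256], "scale_nm_per_px": 1.5},
        )
        ls.write_annotations(ann, tmp_path / "p.json")
        back = ls.read_annotations(tmp_path / "p.json")
        assert len(back.particles) == 100
        for a, b in zip(particles, back.particles):
            assert a.id == b.id and a.size_class == b.size_class
            assert a.centroid_nm[0] == pytest.approx(b.centroid_nm[0], abs=0.006)
            assert a.centroid_nm[1] == pytest.approx(b.centroid_nm[1], abs=0.006)
            assert a.equivalent_diameter_nm == pytest.approx(
                b.equivalent_diameter_nm, abs=0.001
            )

    def test_idempotent_read_write_read(self, tmp_path, default_scene):
        img, _ = default_scene
        dets = ls.detect_particles(img)[:20]
        ann = AnnotationSet(particles=dets, provenance={
            "image_shape_px": list(img.shape), "scale_nm_per_px": img.scale_nm_per_px,
        })
        ls.write_annotations(ann, tmp_path / "a.json")
        once = ls.read_annotations(tmp_path / "a.json")
        ls.write_annotations(once, tmp_path / "b.json")
        twice = ls.read_annotations(tmp_path / "b.json")
        assert [p.centroid_nm for p in once.particles] == [p.centroid_nm for p in twice.particles]

    def test_out_of_bounds_coordinate_rejected(self, tmp_path):
        particles = [ParticleRecord(0, (999.0, 5.0), 6.0, 0.9, 0.1, "6nm")]
        ann = AnnotationSet(particles=particles, provenance={
            "image_shape_px": [16, 16], "scale_nm_per_px": 1.0,
        })
        ls.write_annotations(ann, tmp_path / "oob.json")
        with pytest.raises(FormatError):
            ls.read_annotations(tmp_path / "oob.json")

    def test_schema_mismatch_rejected(self, tmp_path):
        (tmp_path / "bad.json").write_text(json.dumps({"hello": "world"}))
        with pytest.raises(FormatError):
            ls.read_annotations(tmp_path / "bad.json")
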