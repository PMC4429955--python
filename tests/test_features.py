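"""Projection, segmentation, measurement, summarization and QC."""

import numpy as np
import pytest
from skimage.draw import disk, ellipse

from punctascreen import (
    QCConfig,
    max_project,
    measure_objects,
    qc_filter,
    segment_objects,
    summarize_profile,
)
from punctascreen.catalogue import FEATURE_NAMES, PER_OBJECT_MEASUREMENTS, SUMMARY_STATS
from punctascreen.features import MorphProfile, profiles_to_frame


class TestMaxProject:
    def test_elementwise_maximum(self):
        stack = np.array([[[1, 2], [3, 4]], [[4, 1], [0, 9]]], dtype=float)
        assert np.array_equal(max_project(stack), [[4, 2], [3, 9]])

    def test_single_plane_identity(self):
        plane = np.arange(12.0).reshape(1, 3, 4)
        assert np.array_equal(max_project(plane), plane[0])

    def test_projection_dominates_every_plane(self):
        rng = np.random.default_rng(0)
        stack = rng.uniform(0, 100, size=(5, 16, 16))
        proj = max_project(stack)
        assert np.all(proj[None] >= stack)

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            max_project(np.empty((0, 4, 4)))


class TestSegmentation:
    def test_blank_image_zero_objects(self):
        assert segment_objects(np.full((64, 64), 5.0)).max() == 0

    def test_exact_planted_count_noise_free(self, clean_field):
        stack, truth = clean_field
        labels = segment_objects(max_project(stack))
        assert labels.max() == truth.planted_object_count

    def test_labels_contiguous(self, clean_field):
        stack, _ = clean_field
        labels = segment_objects(max_project(stack))
        present = np.unique(labels)
        assert np.array_equal(present, np.arange(labels.max() + 1))

    def test_constant_offset_invariance(self, clean_field):
        stack, _ = clean_field
        proj = max_project(stack)
        assert np.array_equal(segment_objects(proj), segment_objects(proj + 123.0))


class TestMeasurement:
    def test_disk_matches_analytic_geometry(self):
        img = np.zeros((64, 64))
        yy, xx = np.mgrid[:64, :64]
        img[(yy - 32) ** 2 + (xx - 32) ** 2 <= 10**2] = 100.0
        labels = (img > 0).astype(int)
        row = measure_objects(labels, img).iloc[0]
        assert row["area"] == pytest.approx(np.pi * 100, rel=0.02)
        assert row["form_factor"] >= 0.9
        assert row["mean_intensity"] == 100.0
        assert row["min_intensity"] == row["max_intensity"] == 100.0

    def test_single_pixel_object(self):
        img = np.zeros((8, 8))
        img[3, 4] = 7.5
        labels = np.zeros((8, 8), dtype=int)
        labels[3, 4] = 1
        row = measure_objects(labels, img).iloc[0]
        assert row["area"] == 1
        for key in ("integrated_intensity", "mean_intensity", "min_intensity", "max_intensity"):
            assert row[key] == 7.5

    def test_ellipse_aspect_ratio(self):
        img = np.zeros((128, 128))
        rr, cc = ellipse(64, 64, 10, 50)
        img[rr, cc] = 1.0
        row = measure_objects((img > 0).astype(int), img).iloc[0]
        assert row["aspect_ratio"] == pytest.approx(5.0, rel=0.05)
        assert 0 <= row["eccentricity"] < 1

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            measure_objects(np.zeros((4, 4), dtype=int), np.zeros((5, 5)))


class TestSummarize:
    def test_valid_profile_has_145_features(self, noisy_profile):
        assert noisy_profile.valid
        assert len(noisy_profile.features) == 145
        assert np.isfinite(noisy_profile.features).all()

    def test_single_object_spread_statistics_are_zero(self):
        img = np.zeros((32, 32))
        rr, cc = disk((16, 16), 5)
        img[rr, cc] = 50.0
        labels = (img > 0).astype(int)
        profile = summarize_profile(measure_objects(labels, img), img, labels, "s", "p")
        lookup = dict(zip(FEATURE_NAMES, profile.features))
        for measurement in PER_OBJECT_MEASUREMENTS:
            assert lookup[f"{measurement}_sd"] == 0.0
            assert lookup[f"{measurement}_iqr"] == 0.0
            assert lookup[f"{measurement}_mad"] == 0.0
        assert lookup["img_nn_distance_sd"] == 0.0

    def test_two_identical_objects_mean_equals_per_object_value(self):
        img = np.zeros((64, 64))
        for center in ((16, 16), (48, 48)):
            rr, cc = disk(center, 5)
            img[rr, cc] = 80.0
        labels = np.zeros_like(img, dtype=int)
        labels[:32] = (img[:32] > 0).astype(int)
        labels[32:] = 2 * (img[32:] > 0).astype(int)
        table = measure_objects(labels, img)
        profile = summarize_profile(table, img, labels, "s", "p")
        lookup = dict(zip(FEATURE_NAMES, profile.features))
        for measurement in PER_OBJECT_MEASUREMENTS:
            assert lookup[f"{measurement}_mean"] == pytest.approx(table[measurement].iloc[0])
        assert profile.object_count == 2

    def test_zero_objects_yields_invalid_profile(self):
        img = np.full((16, 16), 3.0)
        labels = np.zeros_like(img, dtype=int)
        profile = summarize_profile(measure_objects(labels, img), img, labels, "s", "p")
        assert not profile.valid
        assert profile.object_count == 0
        assert np.isnan(profile.features).all()

    def test_intensity_features_scale_and_size_features_do_not(self, clean_field):
        stack, _ = clean_field
        proj = max_project(stack)
        labels = segment_objects(proj)
        scale = 3.7
        base = summarize_profile(measure_objects(labels, proj), proj, labels, "s", "p")
        scaled = summarize_profile(
            measure_objects(labels, proj * scale), proj * scale, labels, "s", "p"
        )
        lookup = dict(zip(FEATURE_NAMES, base.features))
        lookup_scaled = dict(zip(FEATURE_NAMES, scaled.features))
        size_measurements = PER_OBJECT_MEASUREMENTS[:10]
        intensity_measurements = PER_OBJECT_MEASUREMENTS[10:]
        for m in size_measurements:
            for s in SUMMARY_STATS:
                assert lookup_scaled[f"{m}_{s}"] == pytest.approx(lookup[f"{m}_{s}"], abs=1e-9)
        for m in intensity_measurements:
            for s in SUMMARY_STATS:
                assert lookup_scaled[f"{m}_{s}"] == pytest.approx(
                    scale * lookup[f"{m}_{s}"], rel=1e-9, abs=1e-9
                )
        for name in ("img_object_count", "img_total_object_area", "img_foreground_area_fraction",
                     "img_nn_distance_mean", "img_nn_distance_sd", "img_contrast_ratio"):
            assert lookup_scaled[name] == pytest.approx(lookup[name], rel=1e-9)
        for name in ("img_mean_foreground_intensity", "img_intensity_sd", "img_intensity_p99",
                     "img_total_integrated_intensity"):
            assert lookup_scaled[name] == pytest.approx(scale * lookup[name], rel=1e-9)


def _profile_with_count(count: int) -> MorphProfile:
    features = np.ones(145)
    features[FEATURE_NAMES.index("img_object_count")] = count
    return MorphProfile(
        strain_id=f"s{count}", plate_id="p", features=features, object_count=count, valid=count > 0
    )


class TestQC:
    def test_boundary_counts(self):
        profiles = [_profile_with_count(c) for c in (49, 50, 1000, 1001)]
        retained, removed, report = qc_filter(profiles, QCConfig())
        assert sorted(p.object_count for p in retained) == [50, 1000]
        assert sorted(p.object_count for p in removed) == [49, 1001]
        assert set(report["reason"]) == {"too_few_objects", "too_many_objects"}

    def test_empty_input(self):
        retained, removed, report = qc_filter([], QCConfig())
        assert retained == [] and removed == [] and len(report) == 0

    def test_sweep_matches_closed_interval(self):
        qc = QCConfig()
        counts = range(1, 2001)
        retained, _, _ = qc_filter([_profile_with_count(c) for c in counts], qc)
        expected = {c for c in counts if 50 <= c <= 1000}
        assert {p.object_count for p in retained} == expected


def test_profiles_frame_layout(noisy_profile):
    frame = profiles_to_frame([noisy_profile])
    assert list(frame.columns[:4]) == ["strain_id", "plate_id", "object_count", "valid"]
    assert list(frame.columns[4:]) == list(FEATURE_NAMES)
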