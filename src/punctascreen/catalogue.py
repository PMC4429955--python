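"""Frozen catalogue of the 145 morphological features.

A strain's morphological profile summarizes the population of segmented
punctate objects (e.g. peroxisomes) in one field: 19 per-object
measurements of size, shape and intensity, each condensed by 7 summary
statistics (133 features), plus 12 image-level features. The catalogue is
versioned and frozen here; every profile in the package uses exactly this
ordering.
"""

from __future__ import annotations

CATALOGUE_VERSION = "1.0"

#: 19 per-object measurements: 10 size/shape + 9 intensity.
PER_OBJECT_MEASUREMENTS: tuple[str, ...] = (
    # size / shape
    "area",
    "perimeter",
    "equivalent_diameter",
    "major_axis_length",
    "minor_axis_length",
    "eccentricity",
    "solidity",
    "extent",
    "form_factor",
    "aspect_ratio",
    # intensity
    "integrated_intensity",
    "mean_intensity",
    "median_intensity",
    "sd_intensity",
    "mad_intensity",
    "min_intensity",
    "max_intensity",
    "lq_intensity",
    "uq_intensity",
)

#: 7 summary statistics applied to each per-object measurement.
SUMMARY_STATS: tuple[str, ...] = ("mean", "median", "sd", "mad", "min", "max", "iqr")

#: 12 image-level features.
IMAGE_FEATURES: tuple[str, ...] = (
    "img_object_count",
    "img_log_object_count",
    "img_total_object_area",
    "img_foreground_area_fraction",
    "img_mean_foreground_intensity",
    "img_mean_background_intensity",
    "img_contrast_ratio",
    "img_total_integrated_intensity",
    "img_nn_distance_mean",
    "img_nn_distance_sd",
    "img_intensity_sd",
    "img_intensity_p99",
)

#: The full, ordered catalogue: 19 x 7 summarized features then 12
#: image-level features -- 145 names in total.
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{measurement}_{stat}"
    for measurement in PER_OBJECT_MEASUREMENTS
    for stat in SUMMARY_STATS
) + IMAGE_FEATURES

N_FEATURES = len(FEATURE_NAMES)

assert N_FEATURES == 145
assert len(set(FEATURE_NAMES)) == N_FEATURES
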