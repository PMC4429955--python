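"""From z-stack to morphological profile.

The profiling chain is: maximum-intensity projection -> punctate-object
segmentation (Gaussian smoothing, global Otsu threshold, 8-connected
components, minimum-size filter, hole filling) -> 19 per-object size,
shape and intensity measurements -> summarization into the frozen
145-feature catalogue, with an object-count quality filter that removes
fields whose segmentation is likely spurious (fewer than 50 or more than
1000 objects).

Conventions: coordinates are 0-based and pixel-centered; intensity is the
raw projected value (no rescaling); the MAD is the unscaled median
absolute deviation; quartiles use linear interpolation; summary sd uses
the population convention (ddof=0) so a single object has sd 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import binary_fill_holes, gaussian_filter
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.morphology import remove_small_objects

from .catalogue import (
    FEATURE_NAMES,
    N_FEATURES,
    PER_OBJECT_MEASUREMENTS,
    SUMMARY_STATS,
)
from .matrix import ScreenMatrix
from .simulate import ImageStack


@dataclass(frozen=True)
class SegmentationConfig:
    """Deterministic spot-segmentation settings."""

    smooth_sigma: float = 1.0
    min_object_px: int = 3
    connectivity: int = 2  # scikit-image convention: 2 == 8-connected in 2D

    def __post_init__(self) -> None:
        if self.smooth_sigma < 0:
            raise ValueError("smooth_sigma must be >= 0")
        if self.min_object_px < 1:
            raise ValueError("min_object_px must be >= 1")


@dataclass(frozen=True)
class QCConfig:
    """Object-count bounds for retaining a field's profile."""

    min_objects: int = 50
    max_objects: int = 1000

    def __post_init__(self) -> None:
        if not 0 < self.min_objects <= self.max_objects:
            raise ValueError("require 0 < min_objects <= max_objects")


@dataclass
class MorphProfile:
    """One strain's 145-feature profile.

    ``valid`` is False exactly when no objects were segmented; summary
    statistics are undefined then and ``features`` is all-NaN.
    """

    strain_id: str
    plate_id: str
    features: np.ndarray  # length 145, ordered per catalogue
    object_count: int
    valid: bool

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.shape != (N_FEATURES,):
            raise ValueError(f"profile must have exactly {N_FEATURES} features")
        if self.valid and not np.isfinite(self.features).all():
            raise ValueError("valid profile contains non-finite features")
        if self.valid != (self.object_count > 0):
            raise ValueError("valid flag must equal object_count > 0")


def max_project(stack: ImageStack | np.ndarray) -> np.ndarray:
    """Pixelwise maximum-intensity projection over the z axis."""
    planes = stack.planes if isinstance(stack, ImageStack) else np.asarray(stack, dtype=float)
    if planes.ndim != 3 or planes.shape[0] < 1:
        raise ValueError("expected a non-empty (z, y, x) stack")
    return planes.max(axis=0)


def segment_objects(image: np.ndarray, config: SegmentationConfig | None = None) -> np.ndarray:
    """Segment punctate objects on a projected image.

    Returns a label image with background 0 and objects 1..n (contiguous
    labels). The Otsu threshold is computed on the smoothed image, so the
    result is invariant to a constant intensity offset. A constant image
    yields zero objects.
    """
    cfg = config if config is not None else SegmentationConfig()
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D image")
    if not np.isfinite(img).all():
        raise ValueError("image must be finite")
    if img.max() == img.min():
        return np.zeros(img.shape, dtype=np.int32)
    smoothed = gaussian_filter(img, cfg.smooth_sigma) if cfg.smooth_sigma > 0 else img
    if smoothed.max() == smoothed.min():
        return np.zeros(img.shape, dtype=np.int32)
    threshold = threshold_otsu(smoothed)
    mask = smoothed > threshold
    mask = binary_fill_holes(mask)
    labels = sk_label(mask, connectivity=cfg.connectivity)
    if cfg.min_object_px > 1:
        keep = remove_small_objects(labels > 0, max_size=cfg.min_object_px - 1)
        labels = sk_label(keep, connectivity=cfg.connectivity)
    return labels.astype(np.int32)


def measure_objects(labels: np.ndarray, image: np.ndarray) -> pd.DataFrame:
    """Measure the 19 per-object size/shape/intensity quantities.

    One row per labelled object, columns ordered as in the catalogue's
    per-object measurement list. Intensity statistics are computed over
    the raw projected pixel values inside each object mask.
    """
    labels = np.asarray(labels)
    image = np.asarray(image, dtype=float)
    if labels.shape != image.shape:
        raise ValueError("label image and intensity image shapes differ")
    rows = []
    centroids = []
    for region in regionprops(labels, intensity_image=image):
        pix = image[region.slice][region.image]
        perimeter = float(region.perimeter)
        area = float(region.area)
        form_factor = 4.0 * np.pi * area / perimeter**2 if perimeter > 0 else 1.0
        minor = float(region.axis_minor_length)
        major = float(region.axis_major_length)
        aspect_ratio = major / minor if minor > 0 else 1.0
        lq, med, uq = np.percentile(pix, [25, 50, 75])
        rows.append(
            {
                "area": area,
                "perimeter": perimeter,
                "equivalent_diameter": float(region.equivalent_diameter_area),
                "major_axis_length": major,
                "minor_axis_length": minor,
                "eccentricity": float(region.eccentricity),
                "solidity": float(region.solidity),
                "extent": float(region.extent),
                "form_factor": float(form_factor),
                "aspect_ratio": float(aspect_ratio),
                "integrated_intensity": float(pix.sum()),
                "mean_intensity": float(pix.mean()),
                "median_intensity": float(med),
                "sd_intensity": float(pix.std()),
                "mad_intensity": float(np.median(np.abs(pix - med))),
                "min_intensity": float(pix.min()),
                "max_intensity": float(pix.max()),
                "lq_intensity": float(lq),
                "uq_intensity": float(uq),
            }
        )
        centroids.append(region.centroid)
    table = pd.DataFrame(rows, columns=list(PER_OBJECT_MEASUREMENTS))
    table.attrs["centroids"] = np.array(centroids, dtype=float).reshape(-1, 2)
    return table


def _summary(values: np.ndarray) -> dict[str, float]:
    med = float(np.median(values))
    lq, uq = np.percentile(values, [25, 75])
    return {
        "mean": float(values.mean()),
        "median": med,
        "sd": float(values.std()),
        "mad": float(np.median(np.abs(values - med))),
        "min": float(values.min()),
        "max": float(values.max()),
        "iqr": float(uq - lq),
    }


def summarize_profile(
    measurements: pd.DataFrame,
    image: np.ndarray,
    labels: np.ndarray,
    strain_id: str = "",
    plate_id: str = "",
) -> MorphProfile:
    """Condense per-object measurements into the 145-feature profile.

    133 features summarize each of the 19 measurements with
    {mean, median, sd, mad, min, max, iqr}; 12 image-level features
    describe counts, foreground/background intensity and object spacing.
    A field with zero objects yields an invalid (all-NaN) profile.
    """
    image = np.asarray(image, dtype=float)
    labels = np.asarray(labels)
    n = len(measurements)
    if n == 0:
        return MorphProfile(
            strain_id=strain_id,
            plate_id=plate_id,
            features=np.full(N_FEATURES, np.nan),
            object_count=0,
            valid=False,
        )
    values: dict[str, float] = {}
    for measurement in PER_OBJECT_MEASUREMENTS:
        stats = _summary(measurements[measurement].to_numpy(dtype=float))
        for stat in SUMMARY_STATS:
            values[f"{measurement}_{stat}"] = stats[stat]

    fg = labels > 0
    fg_pix = image[fg]
    bg_pix = image[~fg]
    mean_fg = float(fg_pix.mean())
    mean_bg = float(bg_pix.mean()) if bg_pix.size else 0.0
    centroids = measurements.attrs.get("centroids")
    if centroids is None or len(centroids) != n:
        raise ValueError("measurements table lacks centroid metadata")
    if n >= 2:
        tree = cKDTree(centroids)
        nn_dist, _ = tree.query(centroids, k=2)
        nn = nn_dist[:, 1]
        nn_mean, nn_sd = float(nn.mean()), float(nn.std())
    else:
        nn_mean = nn_sd = 0.0

    values["img_object_count"] = float(n)
    values["img_log_object_count"] = float(np.log10(n + 1))
    values["img_total_object_area"] = float(measurements["area"].sum())
    values["img_foreground_area_fraction"] = float(fg.sum() / fg.size)
    values["img_mean_foreground_intensity"] = mean_fg
    values["img_mean_background_intensity"] = mean_bg
    values["img_contrast_ratio"] = mean_fg / mean_bg if mean_bg > 0 else 0.0
    values["img_total_integrated_intensity"] = float(measurements["integrated_intensity"].sum())
    values["img_nn_distance_mean"] = nn_mean
    values["img_nn_distance_sd"] = nn_sd
    values["img_intensity_sd"] = float(image.std())
    values["img_intensity_p99"] = float(np.percentile(image, 99))

    features = np.array([values[name] for name in FEATURE_NAMES], dtype=float)
    return MorphProfile(
        strain_id=strain_id, plate_id=plate_id, features=features, object_count=n, valid=True
    )


def extract_profile(
    stack: ImageStack,
    strain_id: str = "",
    plate_id: str = "",
    config: SegmentationConfig | None = None,
) -> MorphProfile:
    """Full chain for one field: project, segment, measure, summarize."""
    sid = strain_id or stack.strain_id
    pid = plate_id or stack.plate_id
    projection = max_project(stack)
    labels = segment_objects(projection, config)
    measurements = measure_objects(labels, projection)
    return summarize_profile(measurements, projection, labels, sid, pid)


def qc_filter(
    profiles: Sequence[MorphProfile], qc: QCConfig | None = None
) -> tuple[list[MorphProfile], list[MorphProfile], pd.DataFrame]:
    """Retain profiles whose object count lies in [min_objects, max_objects].

    Returns (retained, removed, report); the report lists each removed
    strain with its count and the reason. Invalid (zero-object) profiles
    always fall below the lower bound.
    """
    cfg = qc if qc is not None else QCConfig()
    retained: list[MorphProfile] = []
    removed: list[MorphProfile] = []
    rows = []
    for profile in profiles:
        ok = cfg.min_objects <= profile.object_count <= cfg.max_objects
        (retained if ok else removed).append(profile)
        if not ok:
            reason = "too_few_objects" if profile.object_count < cfg.min_objects else "too_many_objects"
            rows.append(
                {
                    "strain_id": profile.strain_id,
                    "plate_id": profile.plate_id,
                    "object_count": profile.object_count,
                    "reason": reason,
                }
            )
    report = pd.DataFrame(rows, columns=["strain_id", "plate_id", "object_count", "reason"])
    return retained, removed, report


def profiles_to_matrix(profiles: Sequence[MorphProfile], roles: dict[str, str] | None = None) -> ScreenMatrix:
    """Assemble valid profiles into a :class:`ScreenMatrix`.

    ``roles`` maps strain_id to a role label; strains not listed default
    to ``inlier``. Invalid profiles are rejected (run :func:`qc_filter`
    first).
    """
    bad = [p.strain_id for p in profiles if not p.valid]
    if bad:
        raise ValueError(f"invalid (zero-object) profiles present: {bad[:5]}")
    index = pd.Index([p.strain_id for p in profiles], name="strain_id")
    features = pd.DataFrame(
        np.vstack([p.features for p in profiles]) if profiles else np.empty((0, N_FEATURES)),
        index=index,
        columns=list(FEATURE_NAMES),
    )
    roles = roles or {}
    meta = pd.DataFrame(
        {
            "plate_id": [p.plate_id for p in profiles],
            "role": [roles.get(p.strain_id, "inlier") for p in profiles],
        },
        index=index,
    )
    return ScreenMatrix(features=features, meta=meta)


def profiles_to_frame(profiles: Sequence[MorphProfile]) -> pd.DataFrame:
    """Flat table (one row per profile) matching the profiles CSV layout:
    strain_id, plate_id, object_count, valid, then the 145 features."""
    rows = []
    for p in profiles:
        row: dict[str, object] = {
            "strain_id": p.strain_id,
            "plate_id": p.plate_id,
            "object_count": p.object_count,
            "valid": p.valid,
        }
        row.update({name: val for name, val in zip(FEATURE_NAMES, p.features)})
        rows.append(row)
    return pd.DataFrame(rows, columns=["strain_id", "plate_id", "object_count", "valid", *FEATURE_NAMES])
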