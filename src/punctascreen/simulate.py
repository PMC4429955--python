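"""Synthetic high-content screens with known ground truth.

Real genome-wide localization screens image thousands of strains, each
field holding tens of yeast-sized cells whose organelle marker (e.g. a
GFP-tagged peroxisomal membrane protein) concentrates in a few bright
puncta per cell. This module emulates that acquisition so that every
downstream stage — segmentation, profiling, preprocessing, outlier
ranking, clustering, co-localization — can be tested against planted
truth without access to the original image database.

Two levels of realism are offered:

* :func:`generate_field` / :func:`generate_screen` render actual image
  z-stacks (cells as non-overlapping ellipses, puncta as Gaussian spots,
  Poisson photon noise plus additive read noise) together with a
  :class:`GroundTruth` record.
* :func:`generate_profile_matrix` skips rendering and draws feature
  vectors directly from a configurable per-class distribution — a fast
  surrogate for exercising the statistical stages at screen scale.

Phenotype classes mirror the two aberrant localization patterns a screen
of this kind distinguishes: class A, "more diffused" — many faint puncta
per cell; class B, "sparser but more intense" — fewer, larger, brighter
puncta. The reference role models the control deletion strain
interspersed across plates.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import tifffile

from .catalogue import FEATURE_NAMES
from .matrix import (
    ROLE_INLIER,
    ROLE_OUTLIER_A,
    ROLE_OUTLIER_B,
    ROLE_REFERENCE,
    ScreenMatrix,
)

_SEED_MASK = 0x7FFFFFFF

# ---------------------------------------------------------------------------
# Parameter containers


@dataclass(frozen=True)
class PhenotypeParams:
    """Per-class generative parameters for one field.

    Intensities are in arbitrary detector counts; lengths in pixels.

    Attributes
    ----------
    cells_per_field : int
        Target number of cells to place (fewer may fit at high density).
    puncta_rate : float
        Poisson mean of puncta per cell.
    puncta_radius_px : (float, float)
        Mean and sd of the Gaussian spot scale (sigma) in pixels.
    puncta_peak : float
        Mean peak amplitude of a spot above background.
    diffuse_fraction : float
        Fraction of each cell's marker signal rendered as uniform
        cytosolic haze instead of puncta, in [0, 1].
    psf_sigma_px : float
        In-plane optical blur sd applied to the rendered signal.
    background_level : float
        Constant offset counts added to every pixel.
    read_noise_sd : float
        Sd of zero-mean additive detector noise.
    photon_noise : bool
        Apply Poisson noise to the rendered signal (the background offset
        is treated as a detector pedestal and left noise-free, so a
        zero-signal render is exactly constant).
    puncta_per_cell : int or None
        If set, plant exactly this many puncta in every cell instead of
        drawing Poisson counts.
    min_separation_px : float
        Minimum center-to-center distance enforced between puncta
        (0 disables the constraint).
    """

    cells_per_field: int = 60
    puncta_rate: float = 2.0
    puncta_radius_px: tuple[float, float] = (2.0, 0.3)
    puncta_peak: float = 400.0
    diffuse_fraction: float = 0.05
    psf_sigma_px: float = 1.0
    background_level: float = 100.0
    read_noise_sd: float = 2.0
    photon_noise: bool = True
    puncta_per_cell: int | None = None
    min_separation_px: float = 0.0

    def __post_init__(self) -> None:
        scalars = {
            "cells_per_field": self.cells_per_field,
            "puncta_rate": self.puncta_rate,
            "puncta_peak": self.puncta_peak,
            "diffuse_fraction": self.diffuse_fraction,
            "psf_sigma_px": self.psf_sigma_px,
            "background_level": self.background_level,
            "read_noise_sd": self.read_noise_sd,
            "min_separation_px": self.min_separation_px,
        }
        for name, value in scalars.items():
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"parameter {name!r} must be finite and >= 0, got {value}")
        mean_r, sd_r = self.puncta_radius_px
        if not np.isfinite(mean_r) or mean_r <= 0:
            raise ValueError(f"parameter 'puncta_radius_px' mean must be > 0, got {mean_r}")
        if not np.isfinite(sd_r) or sd_r < 0:
            raise ValueError(f"parameter 'puncta_radius_px' sd must be >= 0, got {sd_r}")
        if self.diffuse_fraction > 1:
            raise ValueError(
                f"parameter 'diffuse_fraction' must be in [0, 1], got {self.diffuse_fraction}"
            )
        if self.puncta_per_cell is not None and self.puncta_per_cell < 0:
            raise ValueError("parameter 'puncta_per_cell' must be >= 0 when set")


@dataclass(frozen=True)
class Acquisition:
    """Stack geometry: defaults match a confocal screen acquiring seven
    1-um-spaced optical sections at 1024 x 1024 pixels."""

    n_slices: int = 7
    z_step_um: float = 1.0
    field_px: int = 1024

    def __post_init__(self) -> None:
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.field_px < 16:
            raise ValueError("field_px must be >= 16")
        if self.z_step_um <= 0:
            raise ValueError("z_step_um must be > 0")


class Well(NamedTuple):
    strain_id: str
    plate_id: str
    role: str


VALID_ROLES = (ROLE_REFERENCE, ROLE_INLIER, ROLE_OUTLIER_A, ROLE_OUTLIER_B)


@dataclass(frozen=True)
class ScreenDesign:
    """Plate layout for a synthetic screen: one well per strain, with the
    reference strain present on every plate."""

    wells: tuple[Well, ...]
    seed: int = 0
    acquisition: Acquisition = field(default_factory=Acquisition)

    def __post_init__(self) -> None:
        object.__setattr__(self, "wells", tuple(Well(*w) for w in self.wells))
        ids = [w.strain_id for w in self.wells]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate strain_id {dup!r} in design")
        for w in self.wells:
            if w.role not in VALID_ROLES:
                raise ValueError(f"unknown role {w.role!r} for strain {w.strain_id!r}")
        plates = {w.plate_id for w in self.wells}
        for plate in sorted(plates):
            if not any(w.role == ROLE_REFERENCE and w.plate_id == plate for w in self.wells):
                raise ValueError(f"plate {plate!r} has no reference well")

    @property
    def roles(self) -> list[str]:
        return [w.role for w in self.wells]


def make_screen_design(
    n_wells: int,
    *,
    reference_fraction: float = 0.05,
    outlier_a_fraction: float = 0.0,
    outlier_b_fraction: float = 0.0,
    n_plates: int = 4,
    seed: int = 0,
    acquisition: Acquisition | None = None,
) -> ScreenDesign:
    """Build a deterministic layout with interspersed reference wells.

    Role counts are rounded to the nearest well; references are spread
    evenly across plates (at least one per plate), outliers and inliers
    fill the remainder in a fixed interleaved order.
    """
    if n_wells < n_plates:
        raise ValueError("need at least one well per plate")
    n_ref = max(n_plates, int(round(reference_fraction * n_wells)))
    n_a = int(round(outlier_a_fraction * n_wells))
    n_b = int(round(outlier_b_fraction * n_wells))
    if n_ref + n_a + n_b > n_wells:
        raise ValueError("role fractions exceed the number of wells")
    roles = (
        [ROLE_REFERENCE] * n_ref
        + [ROLE_OUTLIER_A] * n_a
        + [ROLE_OUTLIER_B] * n_b
        + [ROLE_INLIER] * (n_wells - n_ref - n_a - n_b)
    )
    # deterministic interleave so roles are spread across plates; the
    # layout stream is distinct from the feature-draw stream
    rng = np.random.default_rng([seed & _SEED_MASK, 101])
    order = rng.permutation(n_wells)
    roles = [roles[i] for i in order]
    # ensure each plate still has a reference well
    plate_of = [i % n_plates for i in range(n_wells)]
    for plate in range(n_plates):
        idx = [i for i in range(n_wells) if plate_of[i] == plate]
        if not any(roles[i] == ROLE_REFERENCE for i in idx):
            donor = next(
                i
                for i in range(n_wells)
                if roles[i] == ROLE_REFERENCE
                and sum(
                    1
                    for j in range(n_wells)
                    if plate_of[j] == plate_of[i] and roles[j] == ROLE_REFERENCE
                )
                > 1
            )
            roles[donor], roles[idx[0]] = roles[idx[0]], roles[donor]
    wells = tuple(
        Well(f"strain_{i:05d}", f"plate_{plate_of[i] + 1:02d}", roles[i])
        for i in range(n_wells)
    )
    acq = acquisition if acquisition is not None else Acquisition()
    return ScreenDesign(wells=wells, seed=seed, acquisition=acq)


# ---------------------------------------------------------------------------
# Image-level containers


@dataclass
class ImageStack:
    """An ordered z-stack of equal-shape, non-negative intensity planes."""

    planes: np.ndarray  # (z, y, x) float array
    channel: str = "GFP"
    strain_id: str = ""
    plate_id: str = ""

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes, dtype=float)
        if self.planes.ndim != 3 or self.planes.shape[0] < 1:
            raise ValueError("stack must be a (z, y, x) array with >= 1 plane")
        if not np.isfinite(self.planes).all():
            raise ValueError("stack intensities must be finite")
        if (self.planes < 0).any():
            raise ValueError("stack intensities must be >= 0")

    @property
    def n_planes(self) -> int:
        return self.planes.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.planes.shape[1:]


class Punctum(NamedTuple):
    x: float  # column coordinate, px
    y: float  # row coordinate, px
    radius: float  # Gaussian sigma, px
    amplitude: float  # peak counts above background
    cell_id: int
    z: float  # axial position in slice units


class CellEllipse(NamedTuple):
    cx: float
    cy: float
    semi_major: float
    semi_minor: float
    angle: float  # radians


@dataclass
class GroundTruth:
    """Planted truth for one field: a cell label mask, the puncta that
    were rendered, and their total count."""

    cell_masks: np.ndarray  # (y, x) int label image, 0 = background
    cells: list[CellEllipse]
    puncta: list[Punctum]

    @property
    def planted_object_count(self) -> int:
        return len(self.puncta)

    def to_json_dict(self) -> dict:
        return {
            "planted_object_count": self.planted_object_count,
            "cells": [list(c) for c in self.cells],
            "puncta": [list(p) for p in self.puncta],
        }


# ---------------------------------------------------------------------------
# Field rendering


def _place_cells(
    rng: np.random.Generator,
    n_cells: int,
    shape: tuple[int, int],
    axis_range: tuple[float, float],
) -> tuple[np.ndarray, list[CellEllipse]]:
    """Place up to ``n_cells`` non-overlapping ellipses; overlap is
    prevented conservatively via bounding circles."""
    h, w = shape
    cells: list[CellEllipse] = []
    mask = np.zeros(shape, dtype=np.int32)
    attempts = 0
    max_attempts = 200 * max(n_cells, 1)
    lo, hi = axis_range
    while len(cells) < n_cells and attempts < max_attempts:
        attempts += 1
        a = rng.uniform(lo, hi) / 2.0  # semi-major
        b = rng.uniform(lo, a * 2.0) / 2.0  # semi-minor <= semi-major
        margin = a + 2
        cx = rng.uniform(margin, w - margin)
        cy = rng.uniform(margin, h - margin)
        if any(math.hypot(cx - c.cx, cy - c.cy) < a + c.semi_major + 2 for c in cells):
            continue
        angle = rng.uniform(0, math.pi)
        cells.append(CellEllipse(cx, cy, a, b, angle))
    for label, c in enumerate(cells, start=1):
        r0 = int(max(0, c.cy - c.semi_major - 1))
        r1 = int(min(h, c.cy + c.semi_major + 2))
        c0 = int(max(0, c.cx - c.semi_major - 1))
        c1 = int(min(w, c.cx + c.semi_major + 2))
        yy, xx = np.mgrid[r0:r1, c0:c1]
        dx, dy = xx - c.cx, yy - c.cy
        ca, sa = math.cos(c.angle), math.sin(c.angle)
        u = dx * ca + dy * sa
        v = -dx * sa + dy * ca
        inside = (u / c.semi_major) ** 2 + (v / c.semi_minor) ** 2 <= 1.0
        mask[r0:r1, c0:c1][inside] = label
    return mask, cells


def _sample_point_in_ellipse(rng: np.random.Generator, cell: CellEllipse) -> tuple[float, float]:
    # uniform in the unit disk, then affine map into the ellipse
    r = math.sqrt(rng.uniform())
    t = rng.uniform(0, 2 * math.pi)
    u = r * math.cos(t) * cell.semi_major
    v = r * math.sin(t) * cell.semi_minor
    ca, sa = math.cos(cell.angle), math.sin(cell.angle)
    return cell.cx + u * ca - v * sa, cell.cy + u * sa + v * ca


def _render_spot(plane: np.ndarray, x: float, y: float, sigma: float, amp: float) -> None:
    """Add a 2D Gaussian spot, truncated at three sigma, in place."""
    h, w = plane.shape
    half = max(1, int(math.ceil(3 * sigma)))
    r0, r1 = max(0, int(y) - half), min(h, int(y) + half + 1)
    c0, c1 = max(0, int(x) - half), min(w, int(x) + half + 1)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    d2 = (xx - x) ** 2 + (yy - y) ** 2
    spot = amp * np.exp(-d2 / (2.0 * sigma**2))
    spot[d2 > (3.0 * sigma) ** 2] = 0.0
    plane[r0:r1, c0:c1] += spot


def generate_field(
    params: PhenotypeParams,
    acquisition: Acquisition | None = None,
    seed: int = 0,
    *,
    noise_seed: int | None = None,
    cell_axis_range: tuple[float, float] = (40.0, 70.0),
    z_sigma: float = 1.0,
    strain_id: str = "",
    plate_id: str = "",
) -> tuple[ImageStack, GroundTruth]:
    """Render one synthetic field as a z-stack plus ground truth.

    The render is deterministic for a fixed ``seed``. Geometry (cells,
    puncta) and noise use separate streams: passing the same ``seed`` with
    different ``noise_seed`` values re-renders the identical field under
    fresh noise. The expectation of a noisy render equals the noise-free
    render (Poisson noise applies to the signal only; the background level
    is a constant pedestal), so averaging replicates converges to the
    clean image.
    """
    acq = acquisition if acquisition is not None else Acquisition()
    rng = np.random.default_rng([int(seed) & _SEED_MASK, 0])
    noise_rng = np.random.default_rng(
        [int(seed if noise_seed is None else noise_seed) & _SEED_MASK, 1]
    )
    shape = (acq.field_px, acq.field_px)

    cell_masks, cells = _place_cells(rng, params.cells_per_field, shape, cell_axis_range)

    mean_r, sd_r = params.puncta_radius_px
    puncta: list[Punctum] = []
    for cell_id, cell in enumerate(cells, start=1):
        if params.puncta_per_cell is not None:
            n = params.puncta_per_cell
        else:
            n = int(rng.poisson(params.puncta_rate))
        placed = 0
        attempts = 0
        while placed < n:
            attempts += 1
            if attempts > 500 * max(n, 1):
                if params.puncta_per_cell is not None:
                    raise RuntimeError(
                        "could not place the requested fixed puncta count with the "
                        "given min_separation_px; reduce the count or separation"
                    )
                break
            x, y = _sample_point_in_ellipse(rng, cell)
            if params.min_separation_px > 0 and any(
                math.hypot(x - p.x, y - p.y) < params.min_separation_px for p in puncta
            ):
                continue
            radius = max(0.6, rng.normal(mean_r, sd_r))
            amp = params.puncta_peak * math.exp(rng.normal(0.0, 0.2))
            z = rng.uniform(0, acq.n_slices - 1) if acq.n_slices > 1 else 0.0
            puncta.append(Punctum(x, y, radius, amp, cell_id, z))
            placed += 1

    signal = np.zeros((acq.n_slices,) + shape, dtype=float)
    df = params.diffuse_fraction
    for p in puncta:
        for zi in range(acq.n_slices):
            factor = math.exp(-((zi - p.z) ** 2) / (2.0 * z_sigma**2))
            if factor < 1e-3:
                continue
            _render_spot(signal[zi], p.x, p.y, p.radius, (1.0 - df) * p.amplitude * factor)

    if df > 0 and cells:
        haze = np.zeros(shape, dtype=float)
        for cell_id, cell in enumerate(cells, start=1):
            integral = sum(
                p.amplitude * 2.0 * math.pi * p.radius**2 for p in puncta if p.cell_id == cell_id
            )
            area = float(np.count_nonzero(cell_masks == cell_id))
            if area > 0 and integral > 0:
                haze[cell_masks == cell_id] = df * integral / area
        signal += haze[None, :, :]

    if params.psf_sigma_px > 0:
        from scipy.ndimage import gaussian_filter

        for zi in range(acq.n_slices):
            signal[zi] = gaussian_filter(signal[zi], params.psf_sigma_px)

    if params.photon_noise:
        signal = noise_rng.poisson(np.clip(signal, 0, None)).astype(float)
    planes = signal + params.background_level
    if params.read_noise_sd > 0:
        planes = planes + noise_rng.normal(0.0, params.read_noise_sd, size=planes.shape)
    planes = np.clip(planes, 0, None)

    stack = ImageStack(planes=planes, channel="GFP", strain_id=strain_id, plate_id=plate_id)
    truth = GroundTruth(cell_masks=cell_masks, cells=cells, puncta=puncta)
    return stack, truth


# ---------------------------------------------------------------------------
# Screen-level generation


def default_class_params() -> dict[str, PhenotypeParams]:
    """Default generative parameters per role.

    Reference and inlier strains share the wild-type-like phenotype of
    roughly two bright puncta per cell. Class A ("more diffused") plants
    many faint puncta with extra cytosolic haze; class B ("sparser but
    more intense") plants rare, larger, brighter puncta.
    """
    base = PhenotypeParams()
    return {
        ROLE_REFERENCE: base,
        ROLE_INLIER: base,
        ROLE_OUTLIER_A: replace(
            base,
            puncta_rate=12.0,
            puncta_peak=base.puncta_peak * 0.40,
            diffuse_fraction=0.25,
        ),
        ROLE_OUTLIER_B: replace(
            base,
            puncta_rate=0.7,
            puncta_peak=base.puncta_peak * 2.50,
            puncta_radius_px=(base.puncta_radius_px[0] * 1.6, base.puncta_radius_px[1]),
        ),
    }


def well_seed(design_seed: int, strain_id: str) -> int:
    """Reproducible, well-order-independent per-well seed."""
    ss = np.random.SeedSequence([int(design_seed) & _SEED_MASK, zlib.crc32(strain_id.encode())])
    return int(ss.generate_state(1)[0]) & _SEED_MASK


@dataclass
class ScreenImages:
    """Rendered screen: stacks and truths keyed by strain, plus layout."""

    stacks: dict[str, ImageStack]
    truths: dict[str, GroundTruth]
    layout: pd.DataFrame  # strain_id, plate_id, role, path, seed


def generate_screen(
    design: ScreenDesign,
    class_params: Mapping[str, PhenotypeParams] | None = None,
) -> ScreenImages:
    """Render every well of a design; per-well seeds derive from the
    design seed and strain id so two runs produce identical screens."""
    if class_params is None:
        class_params = default_class_params()
    missing = sorted({w.role for w in design.wells} - set(class_params))
    if missing:
        raise ValueError(f"no PhenotypeParams supplied for roles: {missing}")
    stacks: dict[str, ImageStack] = {}
    truths: dict[str, GroundTruth] = {}
    rows = []
    for w in design.wells:
        seed = well_seed(design.seed, w.strain_id)
        stack, truth = generate_field(
            class_params[w.role],
            design.acquisition,
            seed,
            strain_id=w.strain_id,
            plate_id=w.plate_id,
        )
        stacks[w.strain_id] = stack
        truths[w.strain_id] = truth
        rows.append(
            {"strain_id": w.strain_id, "plate_id": w.plate_id, "role": w.role, "path": "", "seed": seed}
        )
    return ScreenImages(stacks=stacks, truths=truths, layout=pd.DataFrame(rows))


def write_stack(stack: ImageStack, path: Path | str) -> None:
    """Write a stack as a multi-page 16-bit TIFF, one page per plane."""
    data = np.clip(np.round(stack.planes), 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(path), data, photometric="minisblack")


def read_stack(path: Path | str, channel: str = "GFP") -> ImageStack:
    data = tifffile.imread(str(path)).astype(float)
    if data.ndim == 2:
        data = data[None, :, :]
    return ImageStack(planes=data, channel=channel)


def write_screen(screen: ScreenImages, out_dir: Path | str) -> pd.DataFrame:
    """Write stacks (TIFF), truths (JSON) and the layout CSV to a
    directory; returns the layout with populated paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    layout = screen.layout.copy()
    paths = []
    for strain_id in layout["strain_id"]:
        path = out / f"{strain_id}.tif"
        write_stack(screen.stacks[strain_id], path)
        with open(out / f"{strain_id}.truth.json", "w") as fh:
            json.dump(screen.truths[strain_id].to_json_dict(), fh)
        paths.append(str(path))
    layout["path"] = paths
    layout.to_csv(out / "layout.csv", index=False)
    return layout


# ---------------------------------------------------------------------------
# Direct profile-matrix generation (rendering-free surrogate)


@dataclass(frozen=True)
class EffectConfig:
    """Distributional recipe for rendering-free profile matrices.

    Baseline rows are independent Gaussians with mean ``baseline_mean``
    and sd ``baseline_sd`` in every feature; reference and inlier rows
    share this distribution. ``class_shifts`` maps a role to mean shifts
    (in sd units) on named catalogue features.
    """

    baseline_mean: float = 1.0
    baseline_sd: float = 0.1
    class_shifts: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.baseline_sd <= 0:
            raise ValueError("baseline_sd must be > 0")
        known = set(FEATURE_NAMES)
        for role, shifts in self.class_shifts.items():
            for name in shifts:
                if name not in known:
                    raise ValueError(
                        f"shift for role {role!r} references unknown feature {name!r}"
                    )


#: Default planted effects: class A raises object-count-type features and
#: lowers per-object intensity; class B does the opposite and additionally
#: raises object size. All shifts are >= 4 sd on >= 10 features per class.
DEFAULT_CLASS_SHIFTS: dict[str, dict[str, float]] = {
    ROLE_OUTLIER_A: {
        "img_object_count": 5.0,
        "img_log_object_count": 5.0,
        "img_total_object_area": 4.0,
        "img_foreground_area_fraction": 4.0,
        "mean_intensity_mean": -4.0,
        "mean_intensity_median": -4.0,
        "max_intensity_mean": -4.0,
        "max_intensity_median": -4.0,
        "integrated_intensity_mean": -4.0,
        "integrated_intensity_median": -4.0,
        "img_nn_distance_mean": -4.0,
        "img_contrast_ratio": -4.0,
    },
    ROLE_OUTLIER_B: {
        "img_object_count": -5.0,
        "img_log_object_count": -5.0,
        "img_nn_distance_mean": 4.0,
        "mean_intensity_mean": 4.0,
        "mean_intensity_median": 4.0,
        "max_intensity_mean": 4.0,
        "max_intensity_median": 4.0,
        "integrated_intensity_mean": 5.0,
        "integrated_intensity_median": 5.0,
        "area_mean": 4.0,
        "area_median": 4.0,
        "equivalent_diameter_mean": 4.0,
        "img_contrast_ratio": 4.0,
    },
}


def default_effect_config() -> EffectConfig:
    return EffectConfig(class_shifts=DEFAULT_CLASS_SHIFTS)


def generate_profile_matrix(
    design: ScreenDesign,
    effect_config: EffectConfig | None = None,
    seed: int | None = None,
) -> ScreenMatrix:
    """Draw a strains x 145-feature matrix directly from the class model.

    One row per well in design order; planted shifts are applied exactly
    as configured, so ground-truth class means differ from the baseline by
    ``shift * baseline_sd`` per shifted feature.
    """
    cfg = effect_config if effect_config is not None else default_effect_config()
    missing = {w.role for w in design.wells} - {ROLE_REFERENCE, ROLE_INLIER} - set(cfg.class_shifts)
    if missing:
        raise ValueError(f"effect_config has no shifts for roles: {sorted(missing)}")
    rng = np.random.default_rng([(design.seed if seed is None else seed) & _SEED_MASK, 202])
    n = len(design.wells)
    values = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=(n, len(FEATURE_NAMES)))
    col_index = {name: j for j, name in enumerate(FEATURE_NAMES)}
    for i, w in enumerate(design.wells):
        for name, shift in cfg.class_shifts.get(w.role, {}).items():
            values[i, col_index[name]] += shift * cfg.baseline_sd
    index = pd.Index([w.strain_id for w in design.wells], name="strain_id")
    features = pd.DataFrame(values, index=index, columns=list(FEATURE_NAMES))
    meta = pd.DataFrame(
        {"plate_id": [w.plate_id for w in design.wells], "role": [w.role for w in design.wells]},
        index=index,
    )
    return ScreenMatrix(features=features, meta=meta)


# ---------------------------------------------------------------------------
# Two-channel co-localization fields


@dataclass
class ColocTruth:
    """Planted truth for a two-channel field."""

    cell_masks: np.ndarray
    red_centroids: np.ndarray  # (n, 2) as (x, y)
    green_centroids: np.ndarray
    green_is_coloc: np.ndarray  # bool per green focus
    per_cell_red_counts: np.ndarray  # indexed by cell label - 1

    @property
    def planted_coloc_fraction(self) -> float:
        return float(self.green_is_coloc.mean()) if len(self.green_is_coloc) else 0.0


def generate_coloc_field(
    *,
    n_cells: int = 12,
    red_rate: float = 0.9,
    n_green: int = 30,
    coloc_fraction: float = 0.30,
    d_c: float = 3.0,
    field_px: int = 256,
    spot_sigma: float = 1.5,
    peak: float = 400.0,
    background_level: float = 100.0,
    read_noise_sd: float = 2.0,
    photon_noise: bool = True,
    min_spot_separation: float = 8.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, ColocTruth]:
    """Render a green/red two-channel field with a planted co-localized
    fraction of green foci.

    Red foci are planted per cell at Poisson(``red_rate``). A fraction
    ``coloc_fraction`` of the ``n_green`` green foci is placed within
    ``d_c / 4`` of a red focus; the rest are kept at least ``3 * d_c``
    away from every red focus. Same-channel foci keep a minimum mutual
    separation so spot detection resolves them individually.
    """
    if not 0.0 <= coloc_fraction <= 1.0:
        raise ValueError("coloc_fraction must be in [0, 1]")
    rng = np.random.default_rng(int(seed) & _SEED_MASK)
    shape = (field_px, field_px)
    cell_masks, cells = _place_cells(rng, n_cells, shape, (34.0, 50.0))

    red: list[tuple[float, float]] = []
    per_cell_counts = np.zeros(len(cells), dtype=int)
    for cell_id, cell in enumerate(cells, start=1):
        k = int(rng.poisson(red_rate))
        placed = 0
        attempts = 0
        while placed < k and attempts < 2000:
            attempts += 1
            x, y = _sample_point_in_ellipse(rng, cell)
            if any(math.hypot(x - rx, y - ry) < min_spot_separation for rx, ry in red):
                continue
            red.append((x, y))
            per_cell_counts[cell_id - 1] += 1
            placed += 1

    n_coloc = int(round(coloc_fraction * n_green))
    green: list[tuple[float, float]] = []
    is_coloc: list[bool] = []

    def _far_from_red(x: float, y: float, dmin: float) -> bool:
        return all(math.hypot(x - rx, y - ry) >= dmin for rx, ry in red)

    # each co-localized green needs its own host red focus (same-channel
    # separation forbids stacking several greens on one red); plant extra
    # host reds inside cells if the Poisson draw fell short
    while len(red) < n_coloc and cells:
        cell_id = int(rng.integers(len(cells))) + 1
        x, y = _sample_point_in_ellipse(rng, cells[cell_id - 1])
        if any(math.hypot(x - rx, y - ry) < min_spot_separation for rx, ry in red):
            continue
        red.append((x, y))
        per_cell_counts[cell_id - 1] += 1
    hosts = list(rng.permutation(len(red))[:n_coloc]) if red else []
    for host in hosts:
        rx, ry = red[host]
        attempts = 0
        while attempts < 1000:
            attempts += 1
            r = (d_c / 4.0) * math.sqrt(rng.uniform())
            t = rng.uniform(0, 2 * math.pi)
            x, y = rx + r * math.cos(t), ry + r * math.sin(t)
            if not (2 <= x < field_px - 2 and 2 <= y < field_px - 2):
                continue
            if any(math.hypot(x - gx, y - gy) < min_spot_separation for gx, gy in green):
                continue
            green.append((x, y))
            is_coloc.append(True)
            break
    attempts = 0
    while len(green) < n_green and attempts < 50000:
        attempts += 1
        x = rng.uniform(4, field_px - 4)
        y = rng.uniform(4, field_px - 4)
        if not _far_from_red(x, y, 3.0 * d_c):
            continue
        if any(math.hypot(x - gx, y - gy) < min_spot_separation for gx, gy in green):
            continue
        green.append((x, y))
        is_coloc.append(False)

    def _render_channel(centroids: Sequence[tuple[float, float]]) -> np.ndarray:
        img = np.zeros(shape, dtype=float)
        for x, y in centroids:
            _render_spot(img, x, y, spot_sigma, peak)
        if photon_noise:
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
        img = img + background_level
        if read_noise_sd > 0:
            img = img + rng.normal(0.0, read_noise_sd, size=img.shape)
        return np.clip(img, 0, None)

    green_img = _render_channel(green)
    red_img = _render_channel(red)
    truth = ColocTruth(
        cell_masks=cell_masks,
        red_centroids=np.array(red, dtype=float).reshape(-1, 2),
        green_centroids=np.array(green, dtype=float).reshape(-1, 2),
        green_is_coloc=np.array(is_coloc, dtype=bool),
        per_cell_red_counts=per_cell_counts,
    )
    return green_img, red_img, truth
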