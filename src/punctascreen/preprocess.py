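"""Profile preprocessing: variance filter, unit-norm scaling, range
filter, and reference-profile subtraction.

The chain removes uninformative features, puts the remaining features on
a common scale, and expresses every strain as a difference from the
averaged reference strain, in this order:

1. drop features with variance at or below ``variance_tol`` (effectively
   constant columns);
2. scale each feature so its Euclidean norm over all rows — all plates
   pooled — equals 1;
3. drop features whose max-minus-min range on the normalized scale is
   strictly below ``range_tol`` (default 0.01);
4. subtract the columnwise mean of the reference-strain rows from every
   row, reference rows included.

Boundary semantics are fixed: variance <= tol is removed; range >= tol is
retained. Row order and strain metadata pass through unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ROLE_REFERENCE, ScreenMatrix


class PreprocessError(ValueError):
    """A preprocessing stage removed every feature or lacks references."""


@dataclass(frozen=True)
class PreprocessConfig:
    variance_tol: float = 1e-12
    range_tol: float = 0.01
    reference_role: str = ROLE_REFERENCE
    per_plate_norm: bool = False  # sensitivity variant: normalize within plates

    def __post_init__(self) -> None:
        if self.variance_tol < 0 or self.range_tol < 0:
            raise ValueError("tolerances must be >= 0")


@dataclass
class StageRecord:
    stage: str
    n_features_before: int
    n_features_after: int
    dropped: dict[str, str] = field(default_factory=dict)  # feature -> reason


@dataclass
class PreprocessReport:
    stages: list[StageRecord] = field(default_factory=list)

    def add(self, record: StageRecord) -> None:
        if self.stages and record.n_features_before != self.stages[-1].n_features_after:
            raise ValueError("stage feature counts are inconsistent")
        self.stages.append(record)

    @property
    def feature_counts(self) -> list[int]:
        counts = [self.stages[0].n_features_before] if self.stages else []
        counts += [s.n_features_after for s in self.stages]
        return counts

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"stage": s.stage, "feature": name, "reason": reason}
            for s in self.stages
            for name, reason in s.dropped.items()
        ]
        return pd.DataFrame(rows, columns=["stage", "feature", "reason"])


def drop_low_variance(
    matrix: ScreenMatrix, variance_tol: float = 1e-12, report: PreprocessReport | None = None
) -> ScreenMatrix:
    """Remove effectively constant features (variance <= tolerance)."""
    variances = matrix.features.var(axis=0, ddof=0)
    drop = variances.index[variances.to_numpy() <= variance_tol]
    if len(drop) == matrix.n_features:
        raise PreprocessError("variance filter would remove every feature")
    if report is not None:
        report.add(
            StageRecord(
                "drop_low_variance",
                matrix.n_features,
                matrix.n_features - len(drop),
                {name: f"variance {variances[name]:.3g} <= {variance_tol:g}" for name in drop},
            )
        )
    return matrix.with_features(matrix.features.drop(columns=drop))


def normalize_unit_norm(
    matrix: ScreenMatrix, report: PreprocessReport | None = None, per_plate: bool = False
) -> ScreenMatrix:
    """Scale each feature to unit Euclidean norm over all rows.

    All plates are pooled (the default literal reading of normalizing
    across plates); ``per_plate=True`` instead normalizes within each
    plate, as a sensitivity variant. Zero-norm features cannot be scaled
    and are dropped with a logged reason.
    """
    features = matrix.features
    norms = np.sqrt((features.to_numpy(dtype=float) ** 2).sum(axis=0))
    zero = features.columns[norms == 0]
    if len(zero) == matrix.n_features:
        raise PreprocessError("all features have zero norm")
    if len(zero):
        warnings.warn(f"dropping {len(zero)} zero-norm feature(s)", stacklevel=2)
    kept = features.drop(columns=zero)
    if per_plate:
        parts = []
        for _, idx in matrix.meta.groupby("plate_id").groups.items():
            block = kept.loc[idx]
            block_norms = np.sqrt((block.to_numpy(dtype=float) ** 2).sum(axis=0))
            block_norms[block_norms == 0] = 1.0
            parts.append(block / block_norms)
        out = pd.concat(parts).loc[kept.index]
    else:
        out = kept / norms[norms != 0]
    if report is not None:
        report.add(
            StageRecord(
                "normalize_unit_norm",
                matrix.n_features,
                matrix.n_features - len(zero),
                {name: "zero norm" for name in zero},
            )
        )
    return matrix.with_features(out)


def range_filter(
    matrix: ScreenMatrix, range_tol: float = 0.01, report: PreprocessReport | None = None
) -> ScreenMatrix:
    """Drop features whose max - min over all rows is strictly below the
    tolerance; a feature with range exactly at the tolerance is kept."""
    features = matrix.features
    ranges = features.max(axis=0) - features.min(axis=0)
    drop = ranges.index[ranges.to_numpy() < range_tol]
    if len(drop) == matrix.n_features:
        raise PreprocessError("range filter would remove every feature")
    if report is not None:
        report.add(
            StageRecord(
                "range_filter",
                matrix.n_features,
                matrix.n_features - len(drop),
                {name: f"range {ranges[name]:.3g} < {range_tol:g}" for name in drop},
            )
        )
    return matrix.with_features(features.drop(columns=drop))


def subtract_reference(
    matrix: ScreenMatrix,
    reference_role: str = ROLE_REFERENCE,
    report: PreprocessReport | None = None,
) -> ScreenMatrix:
    """Subtract the averaged reference profile from every row.

    The resulting difference profiles describe each strain's deviation
    from the reference phenotype; reference rows are centered too, so
    their mean difference is the zero vector.
    """
    is_ref = matrix.roles == reference_role
    if not is_ref.any():
        raise PreprocessError(f"no rows with reference role {reference_role!r}")
    reference_mean = matrix.features.loc[is_ref].mean(axis=0)
    out = matrix.features - reference_mean
    if report is not None:
        report.add(StageRecord("subtract_reference", matrix.n_features, matrix.n_features))
    return matrix.with_features(out)


def preprocess(
    matrix: ScreenMatrix, config: PreprocessConfig | None = None
) -> tuple[ScreenMatrix, PreprocessReport]:
    """Run the full chain and return the difference matrix plus a
    per-stage report of dropped features."""
    cfg = config if config is not None else PreprocessConfig()
    report = PreprocessReport()
    out = drop_low_variance(matrix, cfg.variance_tol, report)
    out = normalize_unit_norm(out, report, per_plate=cfg.per_plate_norm)
    out = range_filter(out, cfg.range_tol, report)
    out = subtract_reference(out, cfg.reference_role, report)
    return out, report
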