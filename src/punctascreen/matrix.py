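"""Screen-level feature matrix: strains x morphological features.

The :class:`ScreenMatrix` is the package's central tabular container. Rows
are strains (wells), identified by a unique ``strain_id`` and annotated
with a ``plate_id`` and a ``role`` (``reference`` for the control deletion
strain interspersed across plates, ``inlier``/``mutant`` for ordinary
library strains, or a planted outlier class in synthetic screens). Columns
are named features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ROLE_REFERENCE = "reference"
ROLE_INLIER = "inlier"
ROLE_OUTLIER_A = "outlier_A"
ROLE_OUTLIER_B = "outlier_B"

META_COLUMNS = ("plate_id", "role")


@dataclass
class ScreenMatrix:
    """Feature matrix with per-strain metadata.

    Parameters
    ----------
    features : pandas.DataFrame
        Numeric matrix indexed by ``strain_id`` with named feature columns.
    meta : pandas.DataFrame
        Indexed identically to ``features``; carries ``plate_id`` and
        ``role`` columns.
    """

    features: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.features.index.equals(self.meta.index):
            raise ValueError("features and meta must share the same strain index")
        if self.features.index.has_duplicates:
            dupes = self.features.index[self.features.index.duplicated()].unique()
            raise ValueError(f"duplicate strain_id: {list(dupes)[:5]}")
        if len(set(self.features.columns)) != self.features.shape[1]:
            raise ValueError("feature column names must be unique")
        for col in META_COLUMNS:
            if col not in self.meta.columns:
                raise ValueError(f"meta is missing required column {col!r}")
        values = self.features.to_numpy(dtype=float, copy=False)
        if values.size and not np.isfinite(values).all():
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_strains(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    @property
    def roles(self) -> pd.Series:
        return self.meta["role"]

    def with_features(self, features: pd.DataFrame) -> "ScreenMatrix":
        """Return a new matrix with the same metadata and new feature block."""
        return ScreenMatrix(features=features, meta=self.meta.copy())

    def subset(self, strain_ids) -> "ScreenMatrix":
        return ScreenMatrix(
            features=self.features.loc[strain_ids].copy(),
            meta=self.meta.loc[strain_ids].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """Flatten to a single table: strain_id index, meta columns first."""
        return pd.concat([self.meta[list(META_COLUMNS)], self.features], axis=1)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=True, index_label="strain_id")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ScreenMatrix":
        meta = frame[list(META_COLUMNS)].copy()
        features = frame.drop(columns=list(META_COLUMNS)).astype(float)
        return cls(features=features, meta=meta)

    @classmethod
    def from_csv(cls, path) -> "ScreenMatrix":
        frame = pd.read_csv(path, index_col="strain_id")
        return cls.from_frame(frame)
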