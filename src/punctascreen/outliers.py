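"""One-class-SVM outlyingness ranking and screen-quality estimation.

A one-class support vector machine is fitted to the difference profiles
of the whole screen (references included). The signed distance to the
learned decision boundary, negated so that larger means more aberrant, is
the strain's outlyingness score. Strains are ranked by score; the top
fraction (default 10%) is flagged as phenotypically abnormal; the first
kink in the descending score curve delimits the most pronounced subgroup.

Screen quality is estimated two ways: the pollution of the flagged list
(fraction of flagged strains that are actually reference strains) and a
two-sample Kolmogorov-Smirnov test comparing mutant and reference score
distributions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.stats import ks_2samp
from sklearn.svm import OneClassSVM

from .matrix import ROLE_REFERENCE, ScreenMatrix

SCORE_COLUMNS = ["strain_id", "role", "score", "rank", "flagged"]


@dataclass(frozen=True)
class OutlierModelConfig:
    """One-class SVM settings.

    ``nu`` is the expected outlier fraction (the nu-property bounds the
    fraction of training rows outside the boundary). The default RBF
    width rule ``gamma='total-variance'`` sets
    gamma = 1 / (n_features * total variance), where the total variance
    is the trace of the feature covariance (sum of per-feature
    variances); scikit-learn's ``'scale'`` rule (mean per-feature
    variance) and explicit floats are also accepted.
    """

    nu: float = 0.10
    kernel: str = "rbf"
    gamma: float | str = "total-variance"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.nu <= 1.0:
            raise ValueError("nu must be in (0, 1]")
        if self.kernel not in ("rbf", "linear"):
            raise ValueError("kernel must be 'rbf' or 'linear'")


@dataclass
class OutlierModel:
    svm: OneClassSVM | None
    feature_names: tuple[str, ...]
    config: OutlierModelConfig
    degenerate: bool = False


@dataclass
class QualityReport:
    """Screen-quality summary for a flagged score table."""

    pollution: float  # fraction of the flagged list that is reference
    reference_flag_rate: float  # fraction of all references that got flagged
    ks_statistic: float
    ks_p: float
    n_flagged: int
    cutoff_rank: int

    def to_dict(self) -> dict:
        return {
            "pollution": self.pollution,
            "reference_flag_rate": self.reference_flag_rate,
            "ks_statistic": self.ks_statistic,
            "ks_p": self.ks_p,
            "n_flagged": self.n_flagged,
            "cutoff_rank": self.cutoff_rank,
        }


def fit_outlier_model(matrix: ScreenMatrix, config: OutlierModelConfig | None = None) -> OutlierModel:
    """Fit the one-class SVM on all difference profiles.

    Fitting includes reference rows: references can legitimately be
    flagged, and their flag rate is itself a quality readout. A screen in
    which every profile is identical is degenerate — all scores are equal
    and no ranking is meaningful.
    """
    cfg = config if config is not None else OutlierModelConfig()
    X = matrix.features.to_numpy(dtype=float)
    if X.shape[0] < 10:
        raise ValueError(f"need >= 10 strains to fit the outlier model, got {X.shape[0]}")
    if not np.isfinite(X).all():
        raise ValueError("difference matrix contains non-finite values")
    names = tuple(matrix.feature_names)
    if np.all(X == X[0]):
        warnings.warn("all profiles identical; outlier model is degenerate", stacklevel=2)
        return OutlierModel(svm=None, feature_names=names, config=cfg, degenerate=True)
    gamma = cfg.gamma
    if gamma == "total-variance":
        total_variance = float(X.var(axis=0, ddof=0).sum())
        gamma = 1.0 / (X.shape[1] * total_variance) if total_variance > 0 else "scale"
    svm = OneClassSVM(kernel=cfg.kernel, nu=cfg.nu, gamma=gamma)
    svm.fit(X)
    return OutlierModel(svm=svm, feature_names=names, config=cfg)


def score_strains(model: OutlierModel, matrix: ScreenMatrix) -> pd.DataFrame:
    """Score every strain and rank by decreasing outlyingness.

    The outlyingness score is the negated SVM decision value, so strains
    far outside the boundary score highest. Ranks run 1..n from most to
    least outlying; ties are broken by strain_id so the table is fully
    deterministic and invariant to input row order.
    """
    if tuple(matrix.feature_names) != model.feature_names:
        raise ValueError("feature names differ from the model's training space")
    if model.degenerate or model.svm is None:
        scores = np.zeros(matrix.n_strains)
    else:
        scores = -model.svm.decision_function(matrix.features.to_numpy(dtype=float))
    table = pd.DataFrame(
        {
            "strain_id": matrix.features.index.to_numpy(),
            "role": matrix.roles.to_numpy(),
            "score": scores,
        }
    )
    table = table.sort_values(["score", "strain_id"], ascending=[False, True], kind="mergesort")
    table["rank"] = np.arange(1, len(table) + 1)
    table["flagged"] = False
    return table.reset_index(drop=True)


def select_outliers(table: pd.DataFrame, fraction: float = 0.10) -> pd.DataFrame:
    """Flag the top ceil(fraction * n) strains by rank."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    n_flag = math.ceil(fraction * len(table))
    out = table.copy()
    out["flagged"] = out["rank"] <= n_flag
    return out


def kink_cutoff(
    scores: np.ndarray | pd.DataFrame,
    window: int = 5,
    threshold_multiplier: float = 3.0,
) -> int:
    """Locate the first kink in a descending score sequence.

    The sequence is smoothed with a centered moving average and the
    absolute discrete second differences of the smoothed curve are
    compared against ``threshold_multiplier`` times their median; the
    first contiguous run of exceedances marks the kink region, and the
    cutoff is localized at the peak of the raw (unsmoothed) second
    differences within that region (1-based rank into the sequence), so
    a clean piecewise-linear slope break is returned at its vertex. A
    sequence with no detectable break — e.g. exactly linear scores —
    returns the full sequence length, i.e. no subgroup is delimited.
    Edge-affected second differences (within half a window of either
    end) are ignored.
    """
    if isinstance(scores, pd.DataFrame):
        subset = scores[scores["flagged"]] if scores["flagged"].any() else scores
        seq = subset.sort_values("rank")["score"].to_numpy(dtype=float)
    else:
        seq = np.asarray(scores, dtype=float)
    n = len(seq)
    if n < 5:
        warnings.warn("fewer than 5 scores; no kink cutoff, returning full length", stacklevel=2)
        return n
    smoothed = uniform_filter1d(seq, size=window, mode="nearest")
    d2 = np.abs(np.diff(smoothed, n=2))
    half = window // 2
    lo, hi = half, len(d2) - half  # indices unaffected by edge padding
    if hi <= lo:
        return n
    valid = d2[lo:hi]
    scale = float(seq.max() - seq.min())
    threshold = threshold_multiplier * float(np.median(valid)) + 1e-12 * max(scale, 1.0)
    exceed = np.flatnonzero(valid > threshold) + lo
    if exceed.size == 0:
        return n
    run = [int(exceed[0])]
    for j in exceed[1:]:
        if j == run[-1] + 1:
            run.append(int(j))
        else:
            break
    raw_d2 = np.abs(np.diff(seq, n=2))
    search = np.arange(max(lo, run[0] - half), min(hi, run[-1] + half + 1))
    best = int(search[np.argmax(raw_d2[search])])
    # d2 index j corresponds to sequence index j + 1, hence rank j + 2
    return best + 2


def annotate_kink(table: pd.DataFrame, window: int = 5, threshold_multiplier: float = 3.0) -> tuple[pd.DataFrame, int]:
    """Mark flagged strains above the first-kink cutoff (`above_kink`)."""
    cutoff = kink_cutoff(table, window=window, threshold_multiplier=threshold_multiplier)
    out = table.copy()
    out["above_kink"] = out["flagged"] & (out["rank"] <= cutoff)
    return out, cutoff


def pollution_rate(table: pd.DataFrame, reference_role: str = ROLE_REFERENCE) -> float:
    """Fraction of the flagged list made up of reference strains."""
    flagged = table[table["flagged"]]
    if len(flagged) == 0:
        raise ValueError("no strains are flagged")
    return float((flagged["role"] == reference_role).mean())


def ks_scores_test(mutant_scores, reference_scores) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov test; sample sizes may
    differ. Returns (D, p)."""
    mutant = np.asarray(mutant_scores, dtype=float)
    reference = np.asarray(reference_scores, dtype=float)
    if len(mutant) < 2 or len(reference) < 2:
        raise ValueError("both samples need at least 2 observations")
    result = ks_2samp(mutant, reference, alternative="two-sided", method="auto")
    return float(result.statistic), float(result.pvalue)


def quality_report(
    table: pd.DataFrame,
    reference_role: str = ROLE_REFERENCE,
    window: int = 5,
    threshold_multiplier: float = 3.0,
) -> QualityReport:
    """Compute pollution, reference flag rate, the mutant-vs-reference KS
    test on scores, and the kink cutoff for a flagged score table."""
    is_ref = table["role"] == reference_role
    pollution = pollution_rate(table, reference_role)
    n_ref = int(is_ref.sum())
    ref_rate = float(table.loc[is_ref, "flagged"].mean()) if n_ref else 0.0
    d_stat, p_val = ks_scores_test(
        table.loc[~is_ref, "score"], table.loc[is_ref, "score"]
    )
    cutoff = kink_cutoff(table, window=window, threshold_multiplier=threshold_multiplier)
    return QualityReport(
        pollution=pollution,
        reference_flag_rate=ref_rate,
        ks_statistic=d_stat,
        ks_p=p_val,
        n_flagged=int(table["flagged"].sum()),
        cutoff_rank=cutoff,
    )
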