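"""Organizing flagged strains into phenotype groups.

Flagged (outlying) strains are clustered by complete-linkage hierarchical
clustering on Euclidean distances between difference profiles. Groups
obtained by cutting the tree are characterized feature-by-feature with a
two-sample Kolmogorov-Smirnov statistic against inlying strains, and gene
groups can be tested for annotation-term enrichment with a one-sided
hypergeometric test (Benjamini-Hochberg adjusted across terms).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from scipy.stats import hypergeom, ks_2samp
from statsmodels.stats.multitest import multipletests


@dataclass
class Dendrogram:
    """Merge structure from agglomerative clustering.

    ``merges`` is the scipy linkage matrix: each row (a, b, height, size)
    merges nodes a and b (leaves are 0..n-1, internal nodes n..2n-2) at
    the given cophenetic height. Complete linkage guarantees heights are
    non-decreasing.
    """

    merges: np.ndarray
    leaf_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.leaf_ids)
        if self.merges.shape != (n - 1, 4):
            raise ValueError("expected n - 1 merges for n leaves")
        heights = self.merges[:, 2]
        if np.any(np.diff(heights) < -1e-9):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def to_newick(self) -> str:
        """Render the tree as a Newick string with merge heights as
        branch lengths."""
        n = self.n_leaves
        nodes: dict[int, tuple[str, float]] = {
            i: (str(self.leaf_ids[i]), 0.0) for i in range(n)
        }
        for k, (a, b, height, _) in enumerate(self.merges):
            na, ha = nodes.pop(int(a))
            nb, hb = nodes.pop(int(b))
            text = f"({na}:{height - ha:.6g},{nb}:{height - hb:.6g})"
            nodes[n + k] = (text, float(height))
        (text, _), = nodes.values()
        return text + ";"


def pairwise_distances(features: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Euclidean distance matrix between profiles."""
    if features.shape[0] < 2:
        raise ValueError("need at least 2 profiles")
    values = features.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("profiles contain non-finite values")
    dist = squareform(pdist(values, metric="euclidean"))
    return pd.DataFrame(dist, index=features.index, columns=features.index)


def hcluster_complete(distances: pd.DataFrame) -> Dendrogram:
    """Complete-linkage hierarchical clustering of a distance matrix.

    The merge height of two clusters is the maximum pairwise distance
    between their members. Input must be symmetric with a zero diagonal.
    """
    dist = distances.to_numpy(dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(dist), 0.0, atol=1e-8):
        raise ValueError("distance matrix must have a zero diagonal")
    condensed = squareform(dist, checks=False)
    merges = hierarchy.linkage(condensed, method="complete")
    return Dendrogram(merges=merges, leaf_ids=tuple(str(i) for i in distances.index))


def cut_tree(dendrogram: Dendrogram, k: int) -> pd.Series:
    """Cut the dendrogram into exactly k groups.

    Returns a Series mapping strain_id to a 1-based group label. Cuts are
    nested: the k-group partition refines the (k-1)-group partition.
    """
    n = dendrogram.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    labels = hierarchy.cut_tree(dendrogram.merges, n_clusters=k).ravel() + 1
    return pd.Series(labels, index=pd.Index(dendrogram.leaf_ids, name="strain_id"), name="group")


def characterize_group(group_features: pd.DataFrame, inlier_features: pd.DataFrame) -> pd.DataFrame:
    """Per-feature two-sample KS comparison of a group against inliers.

    For each shared feature the two-sided KS statistic D and p-value are
    computed between group and inlier values; the direction of the shift
    is the sign of (group median - inlier median). Features are ranked by
    D descending, ties broken by feature name.
    """
    if group_features.shape[0] < 2 or inlier_features.shape[0] < 2:
        raise ValueError("both samples need at least 2 profiles per feature")
    if list(group_features.columns) != list(inlier_features.columns):
        raise ValueError("group and inlier feature spaces differ")
    rows = []
    for name in group_features.columns:
        g = group_features[name].to_numpy(dtype=float)
        i = inlier_features[name].to_numpy(dtype=float)
        res = ks_2samp(g, i, alternative="two-sided", method="auto")
        rows.append(
            {
                "feature": name,
                "ks_statistic": float(res.statistic),
                "p_value": float(res.pvalue),
                "direction": int(np.sign(np.median(g) - np.median(i))),
            }
        )
    table = pd.DataFrame(rows)
    return table.sort_values(
        ["ks_statistic", "feature"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def enrich_terms(
    group_genes,
    background_genes,
    annotation: pd.DataFrame | dict,
) -> pd.DataFrame:
    """Hypergeometric term enrichment of a gene group.

    ``annotation`` maps terms to genes, either as a mapping
    ``{term: iterable of genes}`` or a DataFrame with ``gene`` and
    ``term`` columns. For each term, the one-sided upper-tail
    hypergeometric p-value is the probability of drawing at least the
    observed number of annotated genes when sampling the group from the
    background; p-values are Benjamini-Hochberg adjusted across terms.
    """
    group = set(group_genes)
    background = set(background_genes)
    stray = group - background
    if stray:
        raise ValueError(f"group genes absent from background: {sorted(stray)[:5]}")
    if isinstance(annotation, pd.DataFrame):
        mapping = {
            term: set(sub["gene"]) for term, sub in annotation.groupby("term", sort=True)
        }
    else:
        mapping = {term: set(genes) for term, genes in annotation.items()}
    m_total = len(background)
    n_group = len(group)
    rows = []
    for term in sorted(mapping):
        annotated = mapping[term] & background
        k_hits = len(annotated & group)
        k_background = len(annotated)
        p = float(hypergeom.sf(k_hits - 1, m_total, k_background, n_group))
        rows.append(
            {
                "term": term,
                "group_hits": k_hits,
                "group_size": n_group,
                "background_hits": k_background,
                "background_size": m_total,
                "p_value": min(p, 1.0),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["term", "group_hits", "group_size", "background_hits", "background_size", "p_value"],
    )
    if len(table):
        table["p_adjusted"] = multipletests(table["p_value"], method="fdr_bh")[1]
    else:
        table["p_adjusted"] = pd.Series(dtype=float)
    return table.sort_values(["p_value", "term"], kind="mergesort").reset_index(drop=True)
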