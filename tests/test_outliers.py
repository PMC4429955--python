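"""One-class-SVM ranking, kink cutoff, pollution and KS quality tests."""

import itertools

import numpy as np
import pandas as pd
import pytest

from punctascreen import (
    OutlierModelConfig,
    fit_outlier_model,
    kink_cutoff,
    ks_scores_test,
    pollution_rate,
    score_strains,
    select_outliers,
)

from conftest import make_matrix


def _cloud_with_planted(n_inlier=200, n_out=10, dim=8, shift=10.0, seed=0):
    rng = np.random.default_rng(seed)
    inliers = rng.normal(size=(n_inlier, dim))
    directions = rng.normal(size=(n_out, dim))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    # distinct radii so the outlyingness order among planted rows is unambiguous
    radii = shift + 5.0 * np.arange(n_out)
    outliers = radii[:, None] * directions
    values = np.vstack([inliers, outliers])
    roles = ["inlier"] * n_inlier + ["outlier_A"] * n_out
    return make_matrix(values, roles=["reference"] * 2 + roles[2:]), n_inlier


class TestModelFit:
    def test_planted_points_get_top_scores(self):
        """On a radially symmetric cloud the ranking must agree with the
        centroid-distance oracle: the 10 planted distant rows score highest."""
        mat, n_inlier = _cloud_with_planted()
        table = score_strains(fit_outlier_model(mat), mat)
        planted = set(mat.features.index[n_inlier:])
        top10 = set(table.nsmallest(10, "rank")["strain_id"])
        assert top10 == planted
        # the most distant planted point has rank 1
        dist = np.linalg.norm(mat.features.to_numpy() - mat.features.to_numpy().mean(0), axis=1)
        farthest = mat.features.index[int(np.argmax(dist))]
        assert table.loc[table["rank"] == 1, "strain_id"].iloc[0] == farthest

    def test_identical_rows_degenerate(self):
        mat = make_matrix(np.ones((20, 3)))
        with pytest.warns(UserWarning, match="degenerate"):
            model = fit_outlier_model(mat)
        table = score_strains(model, mat)
        assert model.degenerate
        assert (table["score"] == table["score"].iloc[0]).all()

    def test_nu_property_on_inlier_only_data(self):
        rng = np.random.default_rng(1)
        mat = make_matrix(rng.normal(size=(1000, 20)))
        model = fit_outlier_model(mat, OutlierModelConfig(nu=0.10))
        outside = int((model.svm.decision_function(mat.features.to_numpy()) < 0).sum())
        assert 80 <= outside <= 120

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="10"):
            fit_outlier_model(make_matrix(np.random.default_rng(0).normal(size=(5, 3))))


class TestScoring:
    def test_tied_profiles_get_equal_scores_adjacent_ranks(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=(30, 4))
        values[7] = values[3]  # s0007 duplicates s0003
        mat = make_matrix(values)
        table = score_strains(fit_outlier_model(mat), mat).set_index("strain_id")
        assert table.loc["s0003", "score"] == table.loc["s0007", "score"]
        r3, r7 = table.loc["s0003", "rank"], table.loc["s0007", "rank"]
        assert r7 == r3 + 1  # tie broken by strain_id order

    def test_row_order_invariance(self):
        mat, _ = _cloud_with_planted(seed=3)
        model = fit_outlier_model(mat)
        table = score_strains(model, mat).set_index("strain_id")
        rng = np.random.default_rng(4)
        perm = rng.permutation(mat.n_strains)
        shuffled = mat.subset(mat.features.index[perm])
        table_shuffled = score_strains(model, shuffled).set_index("strain_id")
        pd.testing.assert_frame_equal(table, table_shuffled.loc[table.index])

    def test_feature_mismatch_rejected(self):
        mat, _ = _cloud_with_planted(seed=5)
        model = fit_outlier_model(mat)
        renamed = mat.with_features(
            mat.features.rename(columns={mat.feature_names[0]: "other"})
        )
        with pytest.raises(ValueError, match="feature"):
            score_strains(model, renamed)


class TestSelection:
    @pytest.mark.parametrize(
        "n,fraction,expected", [(4830, 0.10, 483), (10, 1.0, 10), (7, 0.10, 1)]
    )
    def test_flag_count_is_ceiling(self, n, fraction, expected):
        table = pd.DataFrame(
            {
                "strain_id": [f"s{i}" for i in range(n)],
                "role": "inlier",
                "score": -np.arange(n, dtype=float),
                "rank": np.arange(1, n + 1),
                "flagged": False,
            }
        )
        out = select_outliers(table, fraction)
        assert int(out["flagged"].sum()) == expected
        assert out.loc[out["flagged"], "rank"].max() == expected

    def test_invalid_fraction(self):
        table = pd.DataFrame({"strain_id": ["a"], "role": ["inlier"], "score": [0.0],
                              "rank": [1], "flagged": [False]})
        with pytest.raises(ValueError):
            select_outliers(table, 0.0)


class TestKink:
    def test_single_slope_break_found_at_vertex(self):
        scores = np.concatenate(
            [10 - 0.05 * np.arange(109), 10 - 0.05 * 108 - 0.002 * np.arange(1, 375)]
        )
        assert kink_cutoff(scores) == 109

    def test_linear_scores_have_no_kink(self):
        assert kink_cutoff(10 - 0.01 * np.arange(400)) == 400

    def test_first_of_two_breaks_wins(self):
        """Exhaustive check: the raw second-difference peak inside the first
        exceedance run is the strongest early slope change."""
        scores = np.concatenate(
            [
                10 - 0.1 * np.arange(40),
                10 - 0.1 * 39 - 0.01 * np.arange(1, 161),
                10 - 0.1 * 39 - 0.01 * 160 - 0.005 * np.arange(1, 100),
            ]
        )
        cutoff = kink_cutoff(scores)
        assert cutoff == 40
        raw = np.abs(np.diff(scores, 2))
        assert np.argmax(raw) + 2 == cutoff  # strongest break overall is the early one

    def test_short_sequences_warn_and_return_length(self):
        with pytest.warns(UserWarning):
            assert kink_cutoff(np.array([3.0, 2.0, 1.0])) == 3


class TestQuality:
    def test_pollution_examples(self):
        n = 4830
        roles = np.array(["inlier"] * n, dtype=object)
        # 6 of the 483 flagged are references
        roles[:6] = "reference"
        table = pd.DataFrame(
            {
                "strain_id": [f"s{i}" for i in range(n)],
                "role": roles,
                "score": -np.arange(n, dtype=float),
                "rank": np.arange(1, n + 1),
                "flagged": np.arange(1, n + 1) <= 483,
            }
        )
        assert pollution_rate(table) == pytest.approx(6 / 483)
        table.loc[:5, "role"] = "inlier"
        assert pollution_rate(table) == 0.0
        table["flagged"] = table["role"] == "inlier"
        table.loc[:, "role"] = np.where(table["flagged"], "reference", "inlier")
        assert pollution_rate(table) == 1.0

    def test_no_flagged_rejected(self):
        table = pd.DataFrame({"strain_id": ["a", "b"], "role": ["inlier"] * 2,
                              "score": [1.0, 0.0], "rank": [1, 2], "flagged": [False, False]})
        with pytest.raises(ValueError):
            pollution_rate(table)


class TestKS:
    def test_identical_samples(self):
        d, p = ks_scores_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0 and p == 1.0

    def test_disjoint_supports(self):
        d, _ = ks_scores_test([1.0, 2.0, 3.0], [101.0, 102.0, 103.0])
        assert d == 1.0

    def test_small_sample_p_matches_exact_permutation_enumeration(self):
        """Oracle: enumerate every way of labelling the pooled sample and
        take the fraction of labelings with a KS statistic >= observed."""

        def ks_stat(a, b):
            pooled = np.sort(np.concatenate([a, b]))
            cdf_a = np.searchsorted(np.sort(a), pooled, side="right") / len(a)
            cdf_b = np.searchsorted(np.sort(b), pooled, side="right") / len(b)
            return np.max(np.abs(cdf_a - cdf_b))

        rng = np.random.default_rng(7)
        for _ in range(5):
            pooled = rng.normal(size=9)
            a, b = pooled[:4], pooled[4:]
            d_obs, p = ks_scores_test(a, b)
            stats = []
            for idx in itertools.combinations(range(9), 4):
                mask = np.zeros(9, dtype=bool)
                mask[list(idx)] = True
                stats.append(ks_stat(pooled[mask], pooled[~mask]))
            p_exact = np.mean(np.array(stats) >= d_obs - 1e-12)
            assert p == pytest.approx(p_exact, abs=1e-9)

    def test_sample_too_small(self):
        with pytest.raises(ValueError):
            ks_scores_test([1.0], [1.0, 2.0])
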