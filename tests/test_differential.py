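import numpy as np
import pandas as pd
import pytest
from scipy import stats

from binplex.differential import (
    RatioTable,
    anova_by_label,
    case_pca,
    code_bins,
    label_ratios,
    poisson_upper_tail,
    trimmed_mean_lambda,
)


class TestTrimmedMean:
    @pytest.mark.parametrize(
        "values, trim, expected",
        [
            (list(range(1, 11)), 0.05, 5.5),  # floor(0.5)=0 dropped per side
            (list(range(1, 21)), 0.05, 10.5),  # 1 dropped per side -> mean(2..19)
            ([7, 7, 7], 0.2, 7.0),
        ],
        ids=["no-drop", "one-per-side", "constant"],
    )
    def test_sort_drop_mean(self, make_matrix, values, trim, expected):
        mat = make_matrix(np.array(values, float)[:, None], ["m"])
        assert trimmed_mean_lambda(mat, trim=trim)["m"] == pytest.approx(expected)

    def test_missing_values_excluded(self, make_matrix):
        mat = make_matrix(np.array([[1.0], [np.nan], [3.0]]), ["m"])
        assert trimmed_mean_lambda(mat, trim=0.0)["m"] == pytest.approx(2.0)

    def test_all_missing_marker_is_error(self, make_matrix):
        mat = make_matrix(np.array([[np.nan], [np.nan]]), ["m"])
        with pytest.raises(ValueError, match="m"):
            trimmed_mean_lambda(mat)

    def test_invalid_trim_rejected(self, make_matrix):
        mat = make_matrix(np.array([[1.0]]), ["m"])
        with pytest.raises(ValueError):
            trimmed_mean_lambda(mat, trim=0.5)


class TestPoissonUpperTail:
    def test_degenerate_lambda_zero(self):
        assert poisson_upper_tail(0, 0.0) == 0.0

    @pytest.mark.parametrize(
        "count, lam, expected",
        [(0, 1.0, 1 - np.exp(-1)), (5, 5.0, 0.384039345166937)],
        ids=["zero-count", "count-at-mean"],
    )
    def test_known_values(self, count, lam, expected):
        # expected values from term-by-term pmf summation (see acceptance suite)
        assert poisson_upper_tail(count, lam) == pytest.approx(expected, abs=1e-12)

    def test_strict_upper_tail_excludes_count(self):
        # P(X > k) + P(X = k) + P(X < k) = 1
        k, lam = 3, 2.5
        total = (
            poisson_upper_tail(k, lam)
            + stats.poisson.pmf(k, lam)
            + stats.poisson.cdf(k - 1, lam)
        )
        assert total == pytest.approx(1.0, abs=1e-12)


class TestCodeBins:
    def test_threshold_is_strict(self, make_matrix):
        lam = 10.0
        # find counts either side of the 0.05 upper-tail boundary
        counts = np.arange(0, 40, dtype=float)[:, None]
        mat = make_matrix(counts, ["m"])
        coding = code_bins(mat, lambdas=pd.Series({"m": lam}))
        expected = (stats.poisson.sf(counts[:, 0], lam) < 0.05).astype(np.uint8)
        np.testing.assert_array_equal(coding.values[:, 0], expected)
        assert expected.min() == 0 and expected.max() == 1  # both sides exercised

    def test_missing_counts_code_to_zero(self, make_matrix):
        mat = make_matrix(np.array([[np.nan], [100.0]]), ["m"])
        coding = code_bins(mat, lambdas=pd.Series({"m": 1.0}))
        assert coding.values[0, 0] == 0 and coding.values[1, 0] == 1

    def test_counts_at_lambda_not_positive_for_large_lambda(self, make_matrix):
        lam = 50.0
        mat = make_matrix(np.full((5, 1), lam), ["m"])
        coding = code_bins(mat, lambdas=pd.Series({"m": lam}))
        assert coding.values.sum() == 0  # upper tail ~0.48 > 0.05

    def test_coding_monotone_in_count(self, make_matrix):
        mat = make_matrix(np.arange(0, 101, dtype=float)[:, None], ["m"])
        coding = code_bins(mat, lambdas=pd.Series({"m": 30.0}))
        assert (np.diff(coding.values[:, 0].astype(int)) >= 0).all()


class TestLabelRatios:
    def test_hand_tallied_ratios(self, make_coding):
        c1 = make_coding([[1, 0], [1, 1], [0, 0], [1, 0], [0, 0], [0, 1]], ["A", "B"], "S1", "g1")
        c2 = make_coding([[0, 0]] * 6, ["A", "B"], "S2", "g2")
        table = label_ratios([c1, c2])
        assert table.ratios.loc["S1", "A"] == pytest.approx(3 / 6)
        assert table.ratios.loc["S1", "B"] == pytest.approx(2 / 6)
        assert (table.ratios.loc["S2"] == 0).all()
        assert table.groups["S1"] == "g1"

    def test_bounds(self, make_coding):
        c = make_coding([[1], [1], [1]], ["A"], "S1", "g1")
        assert label_ratios([c]).ratios.loc["S1", "A"] == 1.0


def _ratio_table(groups_to_values, marker="m"):
    rows, groups = {}, {}
    i = 0
    for g, values in groups_to_values.items():
        for v in values:
            rows[f"S{i}"] = {marker: v}
            groups[f"S{i}"] = g
            i += 1
    return RatioTable(ratios=pd.DataFrame.from_dict(rows, orient="index"),
                      groups=pd.Series(groups))


class TestAnovaByLabel:
    def test_f_statistic_matches_closed_form(self):
        # groups {1,2,3},{2,3,4},{3,4,5} scaled into [0,1]: F is scale-free
        table = _ratio_table({"A": [0.1, 0.2, 0.3], "B": [0.2, 0.3, 0.4], "C": [0.3, 0.4, 0.5]})
        res = anova_by_label(table)
        row = res.by_label.iloc[0]
        assert row["F"] == pytest.approx(3.0, abs=1e-9)
        assert row["p_raw"] == pytest.approx(stats.f.sf(3.0, 2, 6), abs=1e-9)
        assert not row["differential"]  # p ~ 0.125 >= 0.10

    def test_identical_group_means_give_f_zero(self):
        table = _ratio_table({"A": [0.1, 0.2, 0.3], "B": [0.1, 0.2, 0.3]})
        res = anova_by_label(table)
        assert res.by_label.iloc[0]["F"] == pytest.approx(0.0, abs=1e-12)

    def test_bh_adjustment_step_up_oracle(self):
        rng = np.random.default_rng(2)
        rows = {}
        groups = {}
        for i, g in enumerate(["A"] * 4 + ["B"] * 4):
            rows[f"S{i}"] = {f"m{j}": rng.random() for j in range(6)}
            groups[f"S{i}"] = g
        table = RatioTable(ratios=pd.DataFrame.from_dict(rows, orient="index"),
                           groups=pd.Series(groups))
        res = anova_by_label(table)
        p = res.by_label["p_raw"].to_numpy()
        # independent step-up oracle: min over tail of p*m/rank, capped at 1
        m = len(p)
        order = np.argsort(p)
        adj = np.empty(m)
        running = 1.0
        for rank_from_top, idx in enumerate(order[::-1]):
            rank = m - rank_from_top
            running = min(running, p[idx] * m / rank)
            adj[idx] = running
        np.testing.assert_allclose(res.by_label["p_bh"], adj, atol=1e-12)
        assert (res.by_label["p_bh"] >= res.by_label["p_raw"] - 1e-15).all()

    def test_constant_marker_reported_untestable(self):
        table = _ratio_table({"A": [0.2, 0.2], "B": [0.2, 0.2]})
        res = anova_by_label(table)
        row = res.by_label.iloc[0]
        assert not row["testable"] and not row["differential"]
        assert np.isnan(row["F"])

    def test_tukey_mean_differences_match_group_means(self):
        table = _ratio_table({"A": [0.1, 0.2, 0.3], "B": [0.4, 0.5, 0.6], "C": [0.2, 0.3, 0.4]})
        res = anova_by_label(table)
        tuk = res.tukey.set_index(["group1", "group2"])
        assert tuk.loc[("A", "B"), "meandiff"] == pytest.approx(0.3, abs=1e-12)
        assert len(res.tukey) == 3  # all pairwise comparisons present
        assert ((res.tukey["p_adj"] >= 0) & (res.tukey["p_adj"] <= 1)).all()


class TestCasePCA:
    def test_pc1_separates_groups_differing_in_one_marker(self):
        rows = {}
        groups = {}
        for i in range(4):
            rows[f"A{i}"] = {"m1": 0.1, "m2": 0.5}
            groups[f"A{i}"] = "A"
            rows[f"B{i}"] = {"m1": 0.6, "m2": 0.5}
            groups[f"B{i}"] = "B"
        table = RatioTable(ratios=pd.DataFrame.from_dict(rows, orient="index"),
                           groups=pd.Series(groups))
        scores, explained = case_pca(table)
        a = scores.loc[scores["group"] == "A", "PC1"]
        b = scores.loc[scores["group"] == "B", "PC1"]
        assert max(a.max(), b.max()) * min(a.min(), b.min()) != 0
        assert (a.max() < b.min()) or (b.max() < a.min())  # separated, sign arbitrary
        assert explained[0] == pytest.approx(1.0)

    def test_identical_sections_give_zero_scores(self):
        table = _ratio_table({"A": [0.3, 0.3], "B": [0.3, 0.3]})
        scores, explained = case_pca(table)
        np.testing.assert_allclose(scores[["PC1", "PC2"]], 0.0, atol=1e-12)

    def test_single_section_rejected(self):
        table = RatioTable(
            ratios=pd.DataFrame({"m": [0.5]}, index=["S0"]),
            groups=pd.Series({"S0": "A"}),
        )
        with pytest.raises(ValueError):
            case_pca(table)

    def test_covariance_pca_is_centred_not_scaled(self):
        # one high-variance marker dominates PC1 when columns are not scaled
        rng = np.random.default_rng(0)
        big = rng.normal(0.5, 0.2, 8).clip(0, 1)
        small = rng.normal(0.5, 0.001, 8).clip(0, 1)
        table = RatioTable(
            ratios=pd.DataFrame({"big": big, "small": small},
                                index=[f"S{i}" for i in range(8)]),
            groups=pd.Series({f"S{i}": "AB"[i % 2] for i in range(8)}),
        )
        scores, _ = case_pca(table)
        r = np.corrcoef(scores["PC1"], big - big.mean())[0, 1]
        assert abs(r) > 0.999


def test_figures_render_without_error():
    from binplex.differential import plot_case_pca, plot_ratio_heatmap

    table = _ratio_table({"A": [0.1, 0.2, 0.3], "B": [0.4, 0.5, 0.6]})
    fig = plot_ratio_heatmap(table)
    assert fig is not None
    scores, explained = case_pca(table)
    fig2 = plot_case_pca(scores, explained)
    assert fig2 is not None
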