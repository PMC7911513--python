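"""CVs, ANOVA decompositions, post-hoc tests, span metric, approach tables."""

import math

import numpy as np
import pytest
import scipy.stats

from platekd import (
    anova_oneway,
    anova_repeated,
    average_intra_cv,
    cv,
    pooled_intra_cv,
    posthoc_ttests,
    span_kd,
    summarize_approaches,
)


def two_point_sample(mean: float, sd: float) -> list[float]:
    """Two values with exactly the given sample mean and SD."""
    h = sd / math.sqrt(2.0)
    return [mean - h, mean + h]


class TestCv:
    def test_constant_values_zero(self):
        assert cv([5.0, 5.0, 5.0]) == 0.0

    @pytest.mark.parametrize(
        "mean,sd,expected",
        [(55.6, 0.9, 1.6), (51.3, 3.6, 7.0), (56.3, 3.8, 6.8), (71.4, 3.6, 5.0)],
    )
    def test_reported_mean_sd_pairs(self, mean, sd, expected):
        assert cv(two_point_sample(mean, sd)) == pytest.approx(expected, abs=0.1)

    def test_zero_mean_explicit_error(self):
        with pytest.raises(ValueError):
            cv([-1.0, 1.0])

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            cv([1.0])


class TestPooledCv:
    def test_single_group_reduces_to_cv(self):
        g = [10.0, 10.5, 9.8, 10.2]
        assert pooled_intra_cv({"a": g}).cv_pct == pytest.approx(cv(g))

    def test_two_groups_match_bruteforce_formula(self):
        a, b = [10.0, 10.4, 9.6], [12.0, 11.5, 12.5, 12.2]
        ssa = (len(a) - 1) * np.var(a, ddof=1)
        ssb = (len(b) - 1) * np.var(b, ddof=1)
        pooled_sd = math.sqrt((ssa + ssb) / (len(a) - 1 + len(b) - 1))
        grand = np.mean(a + b)
        res = pooled_intra_cv({"a": a, "b": b})
        assert res.pooled_sd == pytest.approx(pooled_sd, rel=1e-12)
        assert res.cv_pct == pytest.approx(100 * pooled_sd / grand, rel=1e-12)

    def test_identical_constants_zero(self):
        assert pooled_intra_cv([[3.0, 3.0], [3.0, 3.0, 3.0]]).cv_pct == 0.0

    def test_all_singletons_rejected(self):
        with pytest.raises(ValueError):
            pooled_intra_cv([[1.0], [2.0]])

    def test_average_over_runs(self):
        run1 = {"a": [10.0, 10.2, 9.8]}
        run2 = {"a": [20.0, 20.8, 19.2]}
        expect = np.mean([pooled_intra_cv(run1).cv_pct, pooled_intra_cv(run2).cv_pct])
        assert average_intra_cv([run1, run2]) == pytest.approx(expect)


class TestAnovaOneway:
    def test_identical_groups_not_significant(self):
        g = [1.0, 1.1, 0.9, 1.05, 0.95]
        res = anova_oneway([g, list(g), list(g)])
        assert res.f == pytest.approx(0.0)
        assert not res.significant

    def test_balanced_example_matches_bruteforce(self):
        rng = np.random.default_rng(5)
        groups = [rng.normal(m, 1.0, 5).tolist() for m in (0.0, 0.5, 2.0)]
        res = anova_oneway(groups)
        # brute-force sums of squares
        allx = np.concatenate(groups)
        grand = allx.mean()
        ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
        ssw = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
        f_brute = (ssb / 2) / (ssw / 12)
        assert res.f == pytest.approx(f_brute, rel=1e-10)
        # independent route: scipy's implementation
        f_scipy, p_scipy = scipy.stats.f_oneway(*groups)
        assert res.f == pytest.approx(f_scipy, rel=1e-10)
        assert res.p == pytest.approx(p_scipy, rel=1e-10)

    def test_two_group_f_equals_t_squared(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 10)
        res = anova_oneway([a, b])
        t = posthoc_ttests({"a": a, "b": b}, correction="none")[0]
        assert res.f == pytest.approx(t.t**2, rel=1e-10)

    def test_null_rejection_rate_near_level(self):
        rng = np.random.default_rng(7)
        rejections = 0
        for _ in range(1000):
            groups = [rng.normal(0, 1, 5) for _ in range(3)]
            if anova_oneway(groups).significant:
                rejections += 1
        assert rejections / 1000 == pytest.approx(0.05, abs=0.02)

    def test_degenerate_grouping_rejected(self):
        with pytest.raises(ValueError):
            anova_oneway([[1.0, 2.0]])


class TestAnovaRepeated:
    def test_identical_runs_f_zero(self):
        col = [1.0, 2.0, 3.0, 4.0]
        m = np.column_stack([col, col, col])
        res = anova_repeated(m)
        assert res.f_run == pytest.approx(0.0)

    def test_hand_decomposition_4x3(self):
        m = np.array([[1.0, 2.0, 1.5], [2.0, 2.5, 2.2], [0.5, 1.0, 0.8], [3.0, 3.5, 3.1]])
        res = anova_repeated(m)
        grand = m.mean()
        ss_rows = 3 * ((m.mean(axis=1) - grand) ** 2).sum()
        ss_cols = 4 * ((m.mean(axis=0) - grand) ** 2).sum()
        ss_err = ((m - grand) ** 2).sum() - ss_rows - ss_cols
        f_run = (ss_cols / 2) / (ss_err / 6)
        assert res.f_run == pytest.approx(f_run, rel=1e-10)
        assert res.p_run == pytest.approx(scipy.stats.f.sf(f_run, 2, 6), rel=1e-10)

    def test_shifted_run_is_significant(self):
        rng = np.random.default_rng(8)
        base = rng.normal(10, 0.1, 6)
        m = np.column_stack([base, base + rng.normal(0, 0.1, 6), base + 5.0])
        res = anova_repeated(m)
        assert res.significant_run

    def test_missing_cells_rejected(self):
        m = np.array([[1.0, np.nan], [2.0, 2.0]])
        with pytest.raises(ValueError):
            anova_repeated(m)


class TestPosthoc:
    def test_identical_pair(self):
        g = [1.0, 1.2, 0.8]
        res = posthoc_ttests({"a": g, "b": list(g)})[0]
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_closed_form_pooled_t(self):
        a = [10.0, 10.5, 9.5, 10.2, 9.8]
        b = [11.0, 11.4, 10.6, 11.2, 10.8]
        n1 = n2 = 5
        sp2 = ((n1 - 1) * np.var(a, ddof=1) + (n2 - 1) * np.var(b, ddof=1)) / (n1 + n2 - 2)
        t_oracle = (np.mean(a) - np.mean(b)) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
        res = posthoc_ttests({"a": a, "b": b}, correction="none")[0]
        assert res.t == pytest.approx(t_oracle, rel=1e-12)
        # dual route: scipy's pooled-variance t-test
        t_scipy, p_scipy = scipy.stats.ttest_ind(a, b, equal_var=True)
        assert res.t == pytest.approx(t_scipy, rel=1e-12)
        assert res.p == pytest.approx(p_scipy, rel=1e-12)

    def test_shifted_group_drives_exactly_its_pairs(self):
        rng = np.random.default_rng(10)
        groups = {
            "run1": rng.normal(10, 0.1, 5),
            "run2": rng.normal(10, 0.1, 5),
            "run3": rng.normal(13, 0.1, 5),
        }
        res = posthoc_ttests(groups)
        flagged = {(r.group1, r.group2) for r in res if r.significant()}
        assert flagged == {("run1", "run3"), ("run2", "run3")}

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError):
            posthoc_ttests({"a": [1.0], "b": [1.0, 2.0]})


class TestSpanKd:
    def test_identical_values_zero_under_every_definition(self):
        for definition in ("range_over_min", "range_over_reference", "range_over_mean"):
            res = span_kd([55.0, 55.0, 55.0], reference=57.0, definition=definition)
            assert res.percent == 0.0

    def test_printed_extremes(self):
        # 100 (65.9 - 47.4) / 47.4 = 39.03%, within rounding of the
        # reported 39.2% total span
        res = span_kd([47.4, 50.0, 65.9])
        assert res.percent == pytest.approx(100 * (65.9 - 47.4) / 47.4, rel=1e-12)
        assert res.percent == pytest.approx(39.2, abs=1.0)
        assert (res.low, res.high) == (47.4, 65.9)

    def test_definitions_diverge_and_are_labeled(self):
        vals = [-14.1, -15.8]
        r1 = span_kd(vals, definition="range_over_min")
        r2 = span_kd(vals, reference=-14.8, definition="range_over_reference")
        assert r1.definition != r2.definition
        assert r1.percent != pytest.approx(r2.percent)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            span_kd([1.0, 2.0], reference=0.0, definition="range_over_reference")


class TestSummarizeApproaches:
    def test_constant_approach_all_zero(self):
        df = summarize_approaches({"X": [55.0, 55.0, 55.0, 55.0], "Y": [50.0, 60.0]})
        row = df[df["approach"] == "X"].iloc[0]
        assert row["sd_kd_ml_g"] == 0.0
        assert row["cv_pct"] == 0.0
        assert row["span_pct"] == 0.0

    def test_total_row_pools_every_value(self):
        lists = {"X": [50.0, 52.0], "Y": [60.0, 58.0, 59.0]}
        df = summarize_approaches(lists, points_per_kd={"X": 30, "Y": "64/56"})
        total = df[df["approach"] == "Av."].iloc[0]
        pooled = [50.0, 52.0, 60.0, 58.0, 59.0]
        assert total["n_single_kd"] == 5
        assert total["avg_kd_ml_g"] == pytest.approx(np.mean(pooled))
        assert total["cv_pct"] == pytest.approx(cv(pooled))
        assert df[df["approach"] == "Y"].iloc[0]["points_per_kd"] == "64/56"


def test_statistics_match_bruteforce_on_random_datasets():
    """cv, pooled CV, ANOVA and t all agree with naive loops to 1e-10."""
    rng = np.random.default_rng(99)
    for _ in range(200):
        k = int(rng.integers(2, 5))
        groups = [rng.normal(rng.uniform(5, 10), rng.uniform(0.1, 2), int(rng.integers(3, 8)))
                  for _ in range(k)]
        # cv
        g0 = groups[0]
        mean = sum(g0) / len(g0)
        sd = math.sqrt(sum((v - mean) ** 2 for v in g0) / (len(g0) - 1))
        assert cv(g0) == pytest.approx(100 * sd / abs(mean), rel=1e-10)
        # pooled cv
        num = sum(
            sum((v - sum(g) / len(g)) ** 2 for v in g) for g in groups
        )
        df = sum(len(g) - 1 for g in groups)
        pooled_sd = math.sqrt(num / df)
        grand = sum(v for g in groups for v in g) / sum(len(g) for g in groups)
        assert pooled_intra_cv(groups).cv_pct == pytest.approx(
            100 * pooled_sd / abs(grand), rel=1e-10
        )
        # one-way ANOVA F
        f_scipy, _ = scipy.stats.f_oneway(*groups)
        assert anova_oneway(groups).f == pytest.approx(f_scipy, rel=1e-10)
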