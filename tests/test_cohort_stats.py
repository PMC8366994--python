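"""Concordance, outlier classification and group-comparison statistics."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from globquant import (
    classify_accumulators,
    compare_groups,
    generate_cohort_table,
    lin_ccc,
    load_cohort_table,
    summarize_cohort,
)
from globquant.cohort_stats import dunn_posthoc


class TestLinCCC:
    def test_perfect_concordance(self):
        ccc, lo, hi = lin_ccc([1, 2, 3], [1, 2, 3])
        assert ccc == 1.0

    def test_worked_shift_example(self):
        """Unit shift of (1,2,3): s_x2 = s_y2 = s_xy = 2/3 -> CCC = 4/7."""
        ccc, _, _ = lin_ccc([1, 2, 3], [2, 3, 4])
        assert ccc == pytest.approx(4 / 7)

    def test_constant_against_varying_is_zero(self):
        ccc, _, _ = lin_ccc([5, 5, 5, 5], [1, 2, 3, 4])
        assert ccc == 0.0

    def test_both_constant_equal_means_is_one(self):
        assert lin_ccc([2, 2, 2], [2, 2, 2])[0] == 1.0

    def test_ci_brackets_estimate(self, rng):
        x = rng.normal(0, 1, 30)
        y = x + rng.normal(0, 0.3, 30)
        ccc, lo, hi = lin_ccc(x, y)
        assert lo <= ccc <= hi
        assert 0 < ccc < 1

    def test_ccc_bounded_by_pearson(self, rng):
        """|CCC| <= |r| for 1000 random pairs; equality needs matched moments."""
        for _ in range(1000):
            n = rng.integers(3, 20)
            x = rng.normal(rng.uniform(-2, 2), rng.uniform(0.1, 3), n)
            y = rng.normal(rng.uniform(-2, 2), rng.uniform(0.1, 3), n)
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            ccc = lin_ccc(x, y)[0]
            r = np.corrcoef(x, y)[0, 1]
            assert abs(ccc) <= abs(r) + 1e-12

    @pytest.mark.parametrize("x,y", [([1, 2], [1, 2]), ([1], [1])])
    def test_too_short_rejected(self, x, y):
        with pytest.raises(ValueError):
            lin_ccc(x, y)


def quantile_oracle(values):
    """Outlier flags by re-deriving linear-interpolation quartiles."""
    v = sorted(values)
    n = len(v)

    def quantile(q):
        pos = q * (n - 1)
        lo, frac = int(pos), pos - int(pos)
        return v[lo] if frac == 0 else v[lo] * (1 - frac) + v[lo + 1] * frac

    q1, q3 = quantile(0.25), quantile(0.75)
    iqr = q3 - q1
    fence = q3 + 1.5 * iqr
    if iqr == 0:
        return [False] * len(values)
    return [val >= fence for val in values]


class TestClassifyAccumulators:
    def test_worked_outlier_example(self):
        values = list(range(1, 9)) + [100]
        cls = classify_accumulators(values)
        assert cls.outlier_flags == quantile_oracle(values)
        assert cls.outlier_flags[-1] is True or cls.outlier_flags[-1] == True
        assert sum(cls.outlier_flags) == 1

    def test_zero_iqr_guard_flags_none(self):
        cls = classify_accumulators([3.0] * 6)
        assert cls.n_outliers == 0

    def test_scaling_invariance_of_flags(self, rng):
        values = rng.lognormal(0, 1, 40)
        a = classify_accumulators(values)
        b = classify_accumulators(values * 123.4)
        assert a.outlier_flags == b.outlier_flags
        assert b.upper_fence == pytest.approx(a.upper_fence * 123.4)

    def test_exhaustive_oracle_on_small_subsets(self):
        """Agrees with the brute-force quantile oracle on all size<=8 draws."""
        grid = [0.0, 0.5, 1.0, 2.0, 10.0]
        from itertools import combinations_with_replacement

        for size in (4, 5, 6, 7, 8):
            for combo in combinations_with_replacement(grid, size):
                cls = classify_accumulators(list(combo))
                assert cls.outlier_flags == quantile_oracle(list(combo)), combo

    def test_quartile_labels_partition(self, rng):
        values = rng.normal(0, 1, 50)
        cls = classify_accumulators(values)
        assert len(cls.quartile_labels) == 50
        assert set(cls.quartile_labels) <= {"Q1", "Q2", "Q3", "Q4"}

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            classify_accumulators([1, 2, 3])


def _table(groups: dict[str, list[float]], value="v", group="g"):
    rows = [
        {value: val, group: name} for name, vals in groups.items() for val in vals
    ]
    return pd.DataFrame(rows)


class TestCompareGroups:
    def test_identical_groups_kw_zero(self):
        t = _table({"a": [1.0] * 10, "b": [1.0] * 10, "c": [1.0] * 10})
        res = compare_groups(t, "v", "g")
        assert res.test == "kruskal_wallis"
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_two_groups_use_mann_whitney(self, rng):
        t = _table({"F": list(rng.normal(0, 1, 20)),
                    "M": list(rng.normal(1, 1, 20))})
        res = compare_groups(t, "v", "g")
        assert res.test == "mann_whitney"
        assert 0 <= res.p_value <= 1
        assert res.posthoc == []

    def test_location_shift_detected_in_most_replicates(self):
        """log-normal groups shifted 0.5 in log10, n=30: power >= 90%."""
        rng = np.random.default_rng(1234)
        hits = 0
        for _ in range(200):
            a = 10 ** rng.normal(0.0, 0.5, 30)
            b = 10 ** rng.normal(0.5, 0.5, 30)
            res = compare_groups(_table({"a": list(a), "b": list(b)}), "v", "g")
            hits += res.p_value < 0.05
        assert hits >= 180

    def test_three_groups_kruskal_with_dunn(self, rng):
        t = _table({g: list(rng.normal(mu, 1, 15))
                    for g, mu in [("0", 0), ("1", 1), ("2", 2)]})
        res = compare_groups(t, "v", "g")
        assert res.test == "kruskal_wallis"
        assert len(res.posthoc) == 3  # all pairs
        for pair in res.posthoc:
            assert 0 <= pair["p_adj"] <= 1

    def test_kw_statistic_invariant_under_monotone_transform(self, rng):
        groups = {g: list(rng.lognormal(mu, 0.6, 12))
                  for g, mu in [("a", 0), ("b", 0.5), ("c", 1.0)]}
        res1 = compare_groups(_table(groups), "v", "g")
        logged = {g: list(np.log(vals)) for g, vals in groups.items()}
        res2 = compare_groups(_table(logged), "v", "g")
        assert res1.statistic == pytest.approx(res2.statistic)

    def test_log10_anova_path_excludes_zeros(self, rng):
        groups = {
            "a": [0.0] + list(rng.lognormal(0, 0.3, 12)),
            "b": list(rng.lognormal(0.6, 0.3, 12)),
        }
        res = compare_groups(_table(groups), "v", "g", log10_anova=True)
        assert res.test == "anova_log10"
        assert res.n_zeros_excluded == 1
        assert res.group_sizes["a"] == 12
        assert len(res.posthoc) == 1

    def test_normality_reported_per_group(self, rng):
        t = _table({"a": list(rng.normal(0, 1, 25)),
                    "b": list(rng.lognormal(0, 1, 25))})
        res = compare_groups(t, "v", "g")
        assert set(res.normality) == {"a", "b"}
        assert all(0 <= p <= 1 for p in res.normality.values())

    def test_small_group_named_in_error(self, rng):
        t = _table({"a": list(rng.normal(0, 1, 10)), "b": [1.0]})
        with pytest.raises(ValueError, match="b"):
            compare_groups(t, "v", "g")

    def test_dunn_bonferroni_never_smaller(self, rng):
        samples = {g: rng.normal(mu, 1, 12)
                   for g, mu in [("a", 0), ("b", 0.7), ("c", 1.4)]}
        plain = dunn_posthoc(samples)
        adj = dunn_posthoc(samples, adjust="bonferroni")
        for p, a in zip(plain, adj):
            assert a["p_adj"] >= p["p_adj"] - 1e-15


class TestSummarize:
    def test_single_stratum_no_fold_change(self, rng):
        t = pd.DataFrame({"v": rng.normal(5, 1, 20), "s": ["x"] * 20})
        out = summarize_cohort(t, "v", "s")
        assert len(out) == 1
        assert np.isnan(out["fold_change"].iloc[0])

    def test_fold_change_is_median_ratio(self):
        t = pd.DataFrame(
            {"v": [1, 2, 3, 4.5, 5.5, 6.5], "s": [0, 0, 0, 1, 1, 1]}
        )
        out = summarize_cohort(t, "v", "s")
        assert out["median"].tolist() == [2.0, 5.5]
        assert out["fold_change"].iloc[1] == pytest.approx(2.75)

    def test_gaussian_column_flagged(self, rng):
        t = pd.DataFrame({"v": rng.normal(10, 1, 60), "s": ["x"] * 60})
        out = summarize_cohort(t, "v", "s")
        assert bool(out["gaussian"].iloc[0])


class TestLoadCohortTable:
    def _write(self, tmp_path, df, name="cohort.csv", column_map=None):
        if column_map:
            df = df.rename(columns=column_map)
        path = tmp_path / name
        if name.endswith(".xlsx"):
            df.to_excel(path, index=False)
        else:
            df.to_csv(path, index=False)
        return path

    def test_round_trip_with_column_map(self, tmp_path):
        df = generate_cohort_table(20, seed=1)
        cmap = {"subject_id": "Subject", "pasd_pct_area": "PASD %Area"}
        path = self._write(tmp_path, df, column_map=cmap)
        out = load_cohort_table(path, column_map=cmap)
        assert len(out) == 20
        np.testing.assert_allclose(
            out["pasd_pct_area"], df["pasd_pct_area"]
        )

    def test_xlsx_supported(self, tmp_path):
        df = generate_cohort_table(10, seed=2)
        path = self._write(tmp_path, df, name="cohort.xlsx")
        out = load_cohort_table(path)
        assert len(out) == 10

    def test_missing_required_column_errors(self, tmp_path):
        df = generate_cohort_table(10, seed=3).drop(columns=["metavir"])
        path = self._write(tmp_path, df)
        with pytest.raises(ValueError, match="metavir"):
            load_cohort_table(path)

    def test_duplicate_subjects_rejected(self, tmp_path):
        df = generate_cohort_table(5, seed=4)
        df.loc[1, "subject_id"] = df.loc[0, "subject_id"]
        path = self._write(tmp_path, df)
        with pytest.raises(ValueError, match="duplicate"):
            load_cohort_table(path)
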