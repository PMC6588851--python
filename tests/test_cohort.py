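"""Status classification, contingency tests, rank correlation, multinomial fits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from sundose.cohort import (
    DegenerateTableError,
    EmptyCohortError,
    STATUS_CATEGORIES,
    apply_detection_limit,
    build_contingency,
    chi_square_test,
    classify_status,
    format_p_value,
    multinomial_logit,
    spearman_correlation,
    summarize_cohort,
)
from sundose.synthetic import simulate_multinomial


class TestDetectionLimit:
    @pytest.mark.parametrize(
        "raw, expected",
        [(5.2, (8.0, True)), (8.1, (8.1, False)), (13.6, (13.6, False)), (0.0, (8.0, True))],
    )
    def test_censoring_rule(self, raw, expected):
        assert apply_detection_limit(raw) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            apply_detection_limit(-0.1)


class TestClassifyStatus:
    @pytest.mark.parametrize(
        "level, expected",
        [
            (13.6, "deficient"),
            (19.999, "deficient"),
            (20.0, "insufficient"),
            (29.999, "insufficient"),
            (30.0, "normal"),
            (8.0, "deficient"),
        ],
    )
    def test_cutoffs(self, level, expected):
        assert classify_status(level) == expected

    @settings(max_examples=100, derandomize=True)
    @given(raw=st.floats(min_value=0.0, max_value=200.0, allow_nan=False))
    def test_classification_total_after_censoring(self, raw):
        # the composed map is total on [0, inf) and lands in the partition
        level, below = apply_detection_limit(raw)
        status = classify_status(level)
        assert status in STATUS_CATEGORIES
        if below:
            assert status == "deficient"
        assert (status == "deficient") == (level < 20)
        assert (status == "normal") == (level >= 30)


# Published cohort characteristic counts (deficient, insufficient, normal)
HIJAB_TABLE = pd.DataFrame(
    [[77, 25, 6], [87, 8, 1]], index=["No", "Yes"], columns=list(STATUS_CATEGORIES)
)


class TestBuildContingency:
    def test_counts_match_crosstab_layout(self):
        rows = []
        for level, counts in HIJAB_TABLE.iterrows():
            for cat, k in counts.items():
                rows += [{"hijab": level, "status": cat}] * int(k)
        df = pd.DataFrame(rows)
        table = build_contingency(df, "hijab", levels=["No", "Yes"])
        pd.testing.assert_frame_equal(
            table, HIJAB_TABLE, check_names=False, check_dtype=False
        )
        assert int(table.to_numpy().sum()) == 204

    def test_empty_records(self):
        table = build_contingency(pd.DataFrame(), "hijab", levels=["No", "Yes"])
        assert (table.to_numpy() == 0).all()

    def test_single_record(self):
        df = pd.DataFrame([{"hijab": "Yes", "status": "deficient"}])
        table = build_contingency(df, "hijab")
        assert int(table.to_numpy().sum()) == 1
        assert table.loc["Yes", "deficient"] == 1

    def test_unknown_covariate(self):
        df = pd.DataFrame([{"hijab": "Yes", "status": "deficient"}])
        with pytest.raises(KeyError):
            build_contingency(df, "nope")


def brute_force_chi_square(counts):
    """Independent oracle: expected counts from margin products / total."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / total
    stat = ((counts - expected) ** 2 / expected).sum()
    df = (counts.shape[0] - 1) * (counts.shape[1] - 1)
    return stat, df, stats.chi2.sf(stat, df)


class TestChiSquare:
    def test_published_hijab_table(self):
        result = chi_square_test(HIJAB_TABLE)
        assert format_p_value(result.p_value) == "0.002"
        assert result.df == 2

    def test_perfect_independence(self):
        table = np.outer([10, 20], [3, 5, 2])  # rows proportional to column margins
        result = chi_square_test(table)
        assert result.statistic == pytest.approx(0.0, abs=1e-12)
        assert result.p_value == pytest.approx(1.0)

    def test_zero_margin_is_degenerate(self):
        with pytest.raises(DegenerateTableError):
            chi_square_test(np.array([[5, 0], [3, 0]]))
        with pytest.raises(DegenerateTableError):
            chi_square_test(np.array([[0, 0], [3, 2]]))

    def test_small_expected_counts_warn(self):
        with pytest.warns(UserWarning, match="expected count"):
            result = chi_square_test(np.array([[50, 1], [40, 2]]))
        assert result.small_expected

    def test_oracle_equivalence_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            shape = rng.integers(2, 6, size=2)
            counts = rng.integers(1, 40, size=shape)
            result = chi_square_test(counts)
            stat, df, p = brute_force_chi_square(counts)
            assert result.statistic == pytest.approx(stat, abs=1e-9)
            assert result.df == df
            assert result.p_value == pytest.approx(p, abs=1e-9)

    def test_monte_carlo_agrees_roughly_with_asymptotic(self):
        result = chi_square_test(
            np.array([[30, 20, 10], [15, 25, 20]]), monte_carlo=True, seed=0
        )
        assert result.monte_carlo_p == pytest.approx(result.p_value, abs=0.03)


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman_correlation([1, 2, 3, 4], [10, 20, 30, 40]).rho == 1.0
        assert spearman_correlation([1, 2, 3, 4], [40, 30, 20, 10]).rho == -1.0

    def test_tied_floor_values_match_rank_then_pearson_oracle(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([8.0, 8, 8, 20, 30])  # heavy assay-floor ties
        rx = stats.rankdata(x, method="average")
        ry = stats.rankdata(y, method="average")
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert spearman_correlation(x, y).rho == pytest.approx(oracle, abs=1e-12)

    @settings(max_examples=30, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(st.floats(0, 100), st.floats(0, 100)), min_size=5, max_size=40
        )
    )
    def test_invariance_and_antisymmetry(self, data):
        x = np.array([a for a, _ in data])
        y = np.array([b for _, b in data])
        res = spearman_correlation(x, y)
        if res.undefined:
            return
        # invariant under a strictly increasing transform of one argument
        # (scaling preserves float distinctness, unlike exp which can underflow)
        assert spearman_correlation(3.0 * x, y).rho == pytest.approx(
            res.rho, abs=1e-12
        )
        # antisymmetric under order reversal of one argument
        assert spearman_correlation(-x, y).rho == pytest.approx(-res.rho, abs=1e-12)

    def test_constant_vector_flagged(self):
        res = spearman_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert res.undefined and np.isnan(res.rho)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            spearman_correlation([1, 2, 3], [1, 2])


TRUE_COEFS = np.array([[0.5, -0.3], [0.8, 0.2], [-0.5, 0.6]])  # intercept, x1, x2


class TestMultinomialLogit:
    def test_parameter_recovery_within_three_se(self):
        df = simulate_multinomial(2000, TRUE_COEFS, seed=3)
        result = multinomial_logit(df, ["x1", "x2"], base="normal")
        assert result.converged and not result.separation
        for j, cat in enumerate(["deficient", "insufficient"]):
            for i, term in enumerate(["intercept", "x1", "x2"]):
                row = result.table.loc[(cat, term)]
                assert abs(row["coef"] - TRUE_COEFS[i, j]) < 3 * row["se"]
                assert row["odds_ratio"] == pytest.approx(np.exp(row["coef"]))

    def test_null_exposure_ci_covers_one(self):
        # x2 carries no effect
        coefs = np.array([[0.5, -0.3], [0.8, 0.2], [0.0, 0.0]])
        df = simulate_multinomial(2000, coefs, seed=5)
        result = multinomial_logit(df, ["x1", "x2"], base="normal")
        for cat in ("deficient", "insufficient"):
            row = result.table.loc[(cat, "x2")]
            assert row["ci_low"] < 1.0 < row["ci_high"]

    def test_zero_variance_exposure(self):
        df = simulate_multinomial(500, TRUE_COEFS, seed=1)
        df["flat"] = 0.0
        with pytest.raises(ValueError, match="zero-variance"):
            multinomial_logit(df, ["flat"])
        result = multinomial_logit(df, ["flat"], ridge=1.0)
        for cat in ("deficient", "insufficient"):
            assert result.odds_ratio(cat, "flat") == pytest.approx(1.0, abs=1e-6)

    def test_perfect_separation_flagged(self):
        df = simulate_multinomial(400, TRUE_COEFS, seed=2)
        df["oracle"] = (df["status"] == "deficient").astype(float)
        result = multinomial_logit(df, ["oracle"])
        assert result.separation

    def test_ridge_stabilizes_separation(self):
        df = simulate_multinomial(400, TRUE_COEFS, seed=2)
        df["oracle"] = (df["status"] == "deficient").astype(float)
        result = multinomial_logit(df, ["oracle"], ridge=1.0)
        assert result.converged
        assert np.isfinite(result.table["odds_ratio"]).all()

    def test_absent_category_inestimable(self):
        df = simulate_multinomial(200, TRUE_COEFS, seed=4)
        df = df[df["status"] != "normal"]
        with pytest.raises(EmptyCohortError, match="normal"):
            multinomial_logit(df, ["x1"])


class TestSummarizeCohort:
    def test_frequencies_match_contingency_margins(self, default_cohort):
        cohort, _ = default_cohort
        summary = summarize_cohort(cohort)
        table = build_contingency(cohort, "education")
        for level, stats_ in summary["categorical"]["education"].items():
            assert stats_["count"] == int(table.loc[level].sum())
        assert summary["n"] == len(cohort)
        total = sum(v["count"] for v in summary["status"].values())
        assert total == len(cohort)

    def test_identical_records_have_zero_spread(self):
        df = pd.DataFrame([{"serum_25ohd": 14.0, "age": 30.0}] * 5)
        summary = summarize_cohort(df)
        assert summary["continuous"]["serum_25ohd"]["sd"] == 0.0
        assert summary["continuous"]["serum_25ohd"]["iqr"] == 0.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(EmptyCohortError):
            summarize_cohort(pd.DataFrame())


class TestPValueFormatting:
    @pytest.mark.parametrize(
        "p, expected",
        [(0.00216, "0.002"), (0.187, "0.19"), (0.0001, "<0.001"), (0.27, "0.27")],
    )
    def test_report_precision(self, p, expected):
        assert format_p_value(p) == expected
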