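"""Feature-table QC, fold changes and the summary statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from aifquant.cohortqc import (
    FeatureTable,
    export_model_matrices,
    fisher_exact_2x2,
    log2_fold_change,
    qc_filter,
    ttest_from_summary,
    tukey_outlier_flags,
)
from aifquant.synthgen import CohortSpec, simulate_cohort_table


def fence_oracle(values, k=4.0):
    """Brute-force Tukey fence check with hand-rolled type-7 quartiles."""
    x = sorted(v for v in values if np.isfinite(v))

    def quantile(q):
        pos = q * (len(x) - 1)
        lo = math.floor(pos)
        frac = pos - lo
        return x[lo] if frac == 0 else x[lo] * (1 - frac) + x[lo + 1] * frac

    q1, q3 = quantile(0.25), quantile(0.75)
    iqr = q3 - q1
    return [
        np.isfinite(v) and (v < q1 - k * iqr or v > q3 + k * iqr) for v in values
    ]


def fisher_enum_oracle(a, b, c, d):
    """Two-sided Fisher p by enumerating all tables with fixed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def p_table(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = p_table(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(p_table(x) for x in range(lo, hi + 1) if p_table(x) <= p_obs * (1 + 1e-12))


def _table(values: pd.DataFrame, groups=None) -> FeatureTable:
    samples = values.index.get_level_values(0).unique()
    info = pd.DataFrame(
        {"group": groups if groups is not None else ["responder"] * len(samples)},
        index=samples,
    )
    return FeatureTable(values=values, sample_info=info)


class TestTukeyFlags:
    def test_constant_vector_has_no_outliers(self):
        assert not tukey_outlier_flags([5.0] * 20).any()

    def test_single_gross_outlier_flagged(self):
        rng = np.random.default_rng(2)
        x = np.append(rng.standard_normal(99), 1000.0)
        flags = tukey_outlier_flags(x, k=4.0)
        assert flags.sum() == 1 and flags[-1]

    def test_missing_values_never_flagged(self):
        x = np.array([1.0, 2.0, np.nan, 3.0, 4.0, 1000.0])
        flags = tukey_outlier_flags(x, k=1.5)
        assert not flags[2] and flags[-1]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            x = rng.standard_t(df=3, size=40) * rng.uniform(0.5, 20)
            k = rng.uniform(1.0, 5.0)
            assert tukey_outlier_flags(x, k=k).tolist() == fence_oracle(x, k=k)

    @given(
        st.floats(min_value=-100, max_value=100),
        st.floats(min_value=0.01, max_value=50),
    )
    @settings(max_examples=40, derandomize=True)
    def test_flags_invariant_under_affine_transform(self, shift, scale):
        rng = np.random.default_rng(11)
        x = rng.standard_t(df=3, size=60)
        base = tukey_outlier_flags(x, k=4.0)
        assert (tukey_outlier_flags(x * scale + shift, k=4.0) == base).all()

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            tukey_outlier_flags([1.0, 2.0, np.nan])


class TestQcFilter:
    def _values(self, data):
        n = len(next(iter(data.values())))
        idx = pd.MultiIndex.from_product(
            [[f"S{i}" for i in range(n)], ["CID1"]],
            names=["sample_id", "timepoint"],
        )
        return pd.DataFrame(data, index=idx)

    def test_feature_above_missing_threshold_discarded(self):
        col = [1.0] * 89 + [np.nan] * 11
        values = self._values({"bad": col, "good": [1.0 + 0.01 * i for i in range(100)]})
        _, decisions = qc_filter(_table(values))
        by = {d.feature: d for d in decisions}
        assert not by["bad"].retained and by["good"].retained

    def test_clean_table_passes_unchanged(self):
        rng = np.random.default_rng(3)
        values = self._values({f"f{i}": rng.lognormal(size=50) for i in range(5)})
        filtered, decisions = qc_filter(_table(values))
        assert all(d.retained for d in decisions)
        assert list(filtered.values.columns) == list(values.columns)

    def test_decisions_independent_of_feature_order(self):
        table, _ = simulate_cohort_table(CohortSpec(n_per_group=20), seed=5)
        _, fwd = qc_filter(table)
        reversed_table = FeatureTable(
            values=table.values[table.features[::-1]],
            sample_info=table.sample_info,
        )
        _, rev = qc_filter(reversed_table)
        assert {d.feature: d.retained for d in fwd} == {
            d.feature: d.retained for d in rev
        }

    def test_planted_violations_all_discarded(self):
        table, truth = simulate_cohort_table(CohortSpec(), seed=0)
        filtered, decisions = qc_filter(table)
        discarded = sorted(d.feature for d in decisions if not d.retained)
        assert discarded == truth["violating_features"]
        assert filtered.values.shape[1] == 104

    def test_empty_table_rejected(self):
        idx = pd.MultiIndex.from_arrays([[], []], names=["sample_id", "timepoint"])
        with pytest.raises(ValueError):
            qc_filter(_table(pd.DataFrame(index=idx)))


class TestLog2FoldChange:
    def _two_timepoints(self, cid1, cid2):
        idx = pd.MultiIndex.from_tuples(
            [(f"S{i}", tp) for i in range(len(cid1)) for tp in ("CID1", "CID2")],
            names=["sample_id", "timepoint"],
        )
        data = []
        for a, b in zip(cid1, cid2):
            data += [{"f": a}, {"f": b}]
        return _table(pd.DataFrame(data, index=idx))

    def test_unchanged_halved_doubled(self):
        table = self._two_timepoints([1.0, 2.0, 3.0], [1.0, 1.0, 6.0])
        fc = log2_fold_change(table)["f"]
        assert fc.tolist() == pytest.approx([0.0, -1.0, 1.0])

    def test_missing_input_propagates(self):
        table = self._two_timepoints([1.0, np.nan], [np.nan, 2.0])
        fc = log2_fold_change(table)["f"]
        assert fc.isna().all()

    def test_zero_baseline_propagates_missing(self):
        table = self._two_timepoints([0.0], [2.0])
        assert log2_fold_change(table)["f"].isna().all()


class TestTtestFromSummary:
    def test_identical_groups_give_t0_p1(self):
        t, _, p = ttest_from_summary(5.0, 1.0, 30, 5.0, 1.0, 30)
        assert t == 0.0 and p == 1.0

    @pytest.mark.parametrize(
        "m1, sd1, m2, sd2, expected_p",
        [
            (36.0502, 5.3902, 34.4904, 4.7794, 0.129),  # BMI
            (3.2890, 2.1510, 3.5588, 1.5983, 0.478),  # HOMA-IR
            (1.1104e0, 0.3291, 1.0164, 0.2453, None),  # HDL-like, sanity only
        ],
    )
    def test_cohort_baseline_rows_reproduced(self, m1, sd1, m2, sd2, expected_p):
        _, _, p = ttest_from_summary(m1, sd1, 50, m2, sd2, 50)
        if expected_p is not None:
            assert round(p, 3) == expected_p

    def test_welch_agrees_with_scipy(self):
        t, df, p = ttest_from_summary(10.0, 2.0, 12, 8.5, 3.5, 20, kind="welch")
        ref = stats.ttest_ind_from_stats(10.0, 2.0, 12, 8.5, 3.5, 20, equal_var=False)
        assert t == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_pooled_agrees_with_raw_data_test(self):
        """Construct two-point samples matching the summary moments
        exactly; the pooled summary test must equal the raw-data test."""
        for m1, s1, m2, s2 in [(5.0, 1.0, 6.0, 2.0), (0.1, 0.05, 0.12, 0.4)]:
            a = [m1 - s1 / math.sqrt(2), m1 + s1 / math.sqrt(2)]
            b = [m2 - s2 / math.sqrt(2), m2 + s2 / math.sqrt(2)]
            t, _, p = ttest_from_summary(m1, s1, 2, m2, s2, 2, kind="pooled")
            ref = stats.ttest_ind(a, b, equal_var=True)
            assert t == pytest.approx(ref.statistic, abs=1e-9)
            assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_degenerate_n_rejected(self):
        with pytest.raises(ValueError):
            ttest_from_summary(1.0, 0.1, 1, 2.0, 0.1, 30)


class TestFisherExact:
    def test_symmetric_table_gives_p1(self):
        assert fisher_exact_2x2(10, 10, 10, 10) == pytest.approx(1.0)

    def test_cohort_gender_table(self):
        p = fisher_exact_2x2(14, 36, 30, 20)
        assert p == pytest.approx(0.002333, rel=5e-4)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(40):
            a, b, c, d = rng.integers(1, 25, size=4)
            assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
                fisher_enum_oracle(int(a), int(b), int(c), int(d)), rel=1e-9
            )

    def test_invariant_under_simultaneous_row_and_column_swap(self):
        assert fisher_exact_2x2(14, 36, 30, 20) == pytest.approx(
            fisher_exact_2x2(20, 30, 36, 14), rel=1e-12
        )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 5, 5, 5)


class TestExportModelMatrices:
    def test_split_is_stratified_and_seeded(self):
        table, _ = simulate_cohort_table(CohortSpec(n_per_group=20), seed=9)
        out = export_model_matrices(table, seed=1)
        split = out["split"]
        for g in ("responder", "non-responder"):
            part = split[split["group"] == g]["partition"]
            assert (part == "test").sum() == 5  # 25 % of 20
        again = export_model_matrices(table, seed=1)["split"]
        assert (split["partition"] == again["partition"]).all()

    def test_matrices_align_on_samples(self):
        table, _ = simulate_cohort_table(CohortSpec(n_per_group=10), seed=9)
        out = export_model_matrices(table, seed=0)
        assert out["baseline"].shape[0] == 20
        assert (out["baseline"].index == out["split"].index).all()
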