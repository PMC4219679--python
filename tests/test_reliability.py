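"""Two-way ANOVA decomposition, ICC estimation, degeneracy and band reports."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from epnet import (
    ICCReliability,
    RatingDataset,
    anova_decompose,
    classify_bands,
    icc_two_way_random,
    load_published_icc,
    reliability_report,
)
from epnet.reliability import format_reliability_table
from conftest import make_long


def oracle_ss(y):
    """First-principles sums-of-squares oracle: explicit loops, no shortcuts."""
    n, k = y.shape
    grand = sum(y[i, j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(y[i, j] for j in range(k)) / k for i in range(n)]
    col = [sum(y[i, j] for i in range(n)) / n for j in range(k)]
    ss_rows = sum(k * (row[i] - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (col[j] - grand) ** 2 for j in range(k))
    ss_err = sum(
        (y[i, j] - row[i] - col[j] + grand) ** 2 for i in range(n) for j in range(k)
    )
    return ss_rows / (n - 1), ss_cols / (k - 1), ss_err / ((n - 1) * (k - 1))


def oracle_icc(y, form):
    msr, msc, mse = oracle_ss(y)
    n, k = y.shape
    if form == "consistency":
        return (msr - mse) / (msr + (k - 1) * mse)
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))


FIXTURE_4x3 = np.array([[1, 2, 2], [3, 3, 4], [2, 1, 2], [4, 4, 3]], float)


class TestAnova:
    def test_fixture_matches_frozen_oracle_values(self):
        """4x3 integer grid: mean squares frozen from the loop-based oracle
        (exact rationals 41/12, 1/12, 5/12)."""
        comp = anova_decompose(FIXTURE_4x3)
        assert comp.ms_rows == pytest.approx(41 / 12, abs=1e-12)
        assert comp.ms_cols == pytest.approx(1 / 12, abs=1e-12)
        assert comp.ms_error == pytest.approx(5 / 12, abs=1e-12)
        assert (comp.df_rows, comp.df_cols, comp.df_error) == (3, 2, 6)
        msr, msc, mse = oracle_ss(FIXTURE_4x3)
        assert comp.ms_rows == pytest.approx(msr, abs=1e-12)
        assert comp.ms_cols == pytest.approx(msc, abs=1e-12)
        assert comp.ms_error == pytest.approx(mse, abs=1e-12)

    def test_perfect_agreement_two_by_two(self):
        comp = anova_decompose(np.array([[0.0, 0.0], [1.0, 1.0]]))
        assert (comp.ms_error, comp.ms_cols, comp.ms_rows) == (0.0, 0.0, 1.0)

    def test_constant_matrix(self):
        comp = anova_decompose(np.full((4, 3), 2.0))
        assert (comp.ms_rows, comp.ms_cols, comp.ms_error) == (0.0, 0.0, 0.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        arrays(
            float,
            st.tuples(st.integers(2, 8), st.integers(2, 5)),
            elements=st.floats(-10, 10, allow_nan=False, width=32),
        )
    )
    def test_ss_identity(self, y):
        """SS_rows + SS_cols + SS_error equals the total sum of squares."""
        comp = anova_decompose(np.asarray(y, float))
        total = np.square(y - np.mean(y)).sum()
        assert comp.ss_total == pytest.approx(total, abs=1e-8 * (1 + total))

    def test_rejects_missing_and_tiny(self):
        with pytest.raises(ValueError):
            anova_decompose(np.array([[1.0, np.nan], [0.0, 1.0]]))
        with pytest.raises(ValueError):
            anova_decompose(np.array([[1.0, 2.0]]))


class TestICC:
    def test_fixture_estimates_exact(self):
        """Frozen closed-form values on the 4x3 fixture: ICC(A,1)=3/4,
        ICC(C,1)=12/17."""
        res_a = icc_two_way_random(FIXTURE_4x3, "absolute_agreement")
        res_c = icc_two_way_random(FIXTURE_4x3, "consistency")
        assert res_a.estimate == pytest.approx(0.75, abs=1e-12)
        assert res_c.estimate == pytest.approx(12 / 17, abs=1e-12)
        assert res_a.ci_low < res_a.estimate < res_a.ci_high

    @pytest.mark.parametrize("form", ["absolute_agreement", "consistency"])
    def test_matches_loop_oracle_on_random_grids(self, form):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n, k = rng.integers(2, 11), rng.integers(2, 5)
            y = rng.normal(size=(n, k)) + rng.normal(size=(n, 1))
            res = icc_two_way_random(y, form)
            if res.degeneracy != "none":
                continue
            assert res.estimate == pytest.approx(oracle_icc(y, form), abs=1e-10)

    def test_matches_pingouin(self):
        """Independent library cross-check of estimates and CIs."""
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        for _ in range(10):
            n, k = int(rng.integers(5, 20)), int(rng.integers(2, 5))
            y = rng.normal(size=(n, k)) + 1.2 * rng.normal(size=(n, 1))
            frame = pd.DataFrame(
                {
                    "t": np.repeat(np.arange(n), k),
                    "r": np.tile(np.arange(k), n),
                    "y": y.ravel(),
                }
            )
            table = pg.intraclass_corr(frame, targets="t", raters="r", ratings="y").set_index("Type")
            for form, key in (("absolute_agreement", "ICC(A,1)"), ("consistency", "ICC(C,1)")):
                res = icc_two_way_random(y, form)
                assert res.estimate == pytest.approx(table.loc[key, "ICC"], abs=1e-10)
                lo, hi = table.loc[key, "CI95"]
                assert res.ci_low == pytest.approx(lo, abs=5e-3)  # pingouin rounds CIs
                assert res.ci_high == pytest.approx(hi, abs=5e-3)

    def test_affine_invariance(self):
        rng = np.random.default_rng(9)
        y = rng.normal(size=(12, 3)) + rng.normal(size=(12, 1))
        for form in ("absolute_agreement", "consistency"):
            base = icc_two_way_random(y, form)
            shifted = icc_two_way_random(2.5 * y - 7.0, form)
            assert shifted.estimate == pytest.approx(base.estimate, abs=1e-12)
            assert shifted.ci_low == pytest.approx(base.ci_low, abs=1e-9)
            assert shifted.ci_high == pytest.approx(base.ci_high, abs=1e-9)

    def test_forms_agree_without_column_effects(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=(15, 3)) + rng.normal(size=(15, 1))
        y = y - y.mean(axis=0, keepdims=True)  # remove observer offsets exactly
        res_a = icc_two_way_random(y, "absolute_agreement")
        res_c = icc_two_way_random(y, "consistency")
        # MSC < MSE makes the agreement denominator smaller, so estimates
        # coincide only in the zero-column-variance population limit; on the
        # exactly-centred sample the identity is est_A computed with MSC=0.
        msr, msc, mse = oracle_ss(y)
        assert msc == pytest.approx(0.0, abs=1e-12)
        n, k = y.shape
        expected = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (0 - mse))
        assert res_a.estimate == pytest.approx(expected, abs=1e-12)
        assert res_c.estimate == pytest.approx((msr - mse) / (msr + (k - 1) * mse), abs=1e-12)

    def test_listwise_deletion(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=(8, 3)) + rng.normal(size=(8, 1))
        y_missing = np.vstack([y, [np.nan, 0.0, 1.0]])
        full = icc_two_way_random(y, "absolute_agreement")
        dropped = icc_two_way_random(y_missing, "absolute_agreement")
        assert dropped.n == 8
        assert dropped.estimate == pytest.approx(full.estimate, abs=1e-15)

    def test_consistency_ci_coverage_nominal(self):
        """The consistency-form interval is an exact F construction: on
        two-way random-effects data it covers its own estimand
        s_c^2/(s_c^2+s_e^2) at the nominal 95% rate (k=3, n=86)."""
        from epnet import simulate_two_way_matrix

        sc, so, se = 1.0565, 0.35, 0.5
        target = sc**2 / (sc**2 + se**2)
        rng = np.random.default_rng(12)
        covered = 0
        reps = 800
        for _ in range(reps):
            res = icc_two_way_random(simulate_two_way_matrix(86, 3, sc, so, se, rng), "consistency")
            covered += res.ci_low <= target <= res.ci_high
        assert covered / reps == pytest.approx(0.95, abs=0.03)

    def test_degenerate_interval_is_nan_not_error(self):
        # msr = msc = 0 with mse > 0: estimand undefined, no exception
        res = icc_two_way_random(np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert np.isnan(res.estimate) or res.estimate <= 0

    def test_negative_estimate_retained_then_clipped_for_display(self):
        # anti-correlated raters: estimate below zero
        y = np.array([[1.0, 4.0], [4.0, 1.0], [2.0, 3.5], [3.5, 2.0]])
        res = icc_two_way_random(y, "consistency")
        assert res.estimate < 0
        assert res.display_estimate == 0.0


class TestDegeneracy:
    def test_perfect_agreement_with_variation_is_one(self):
        res = icc_two_way_random(np.array([[0, 0], [1, 1]], float))
        assert res.estimate == 1.0
        assert res.degeneracy == "constant_perfect_agreement"
        assert np.isnan(res.ci_low) and np.isnan(res.ci_high)

    def test_universally_present_feature_is_one(self):
        res = icc_two_way_random(np.ones((10, 3)))
        assert (res.estimate, res.degeneracy) == (1.0, "constant_perfect_agreement")

    def test_never_observed_feature_not_calculable(self):
        res = icc_two_way_random(np.zeros((10, 3)))
        assert res.degeneracy == "never_observed"
        assert np.isnan(res.estimate)

    def test_floor_convention_respects_scale_floor(self):
        # ordinal scale whose floor is 1: constant at 1 means never observed
        res = icc_two_way_random(np.ones((6, 3)), floor=1.0)
        assert res.degeneracy == "never_observed"

    def test_insufficient_data_is_result_not_exception(self):
        res = icc_two_way_random(np.array([[1.0, 2.0]]))
        assert res.degeneracy == "insufficient_data"
        res = icc_two_way_random(np.array([[1.0, np.nan], [2.0, 1.0], [0.0, np.nan]]))
        assert res.degeneracy == "insufficient_data"


class TestBands:
    def test_boundary_inclusive(self):
        counts = classify_bands([0.39, 0.40, 0.41], thresholds=(0.4,))
        assert counts.counts == (1, 2)

    def test_published_fixture_shape(self):
        pub = load_published_icc()
        assert len(pub) == 60
        assert pub["icc"].notna().sum() == 59
        assert pub.loc[pub["item_id"] == "Q19.desert", "icc"].isna().all()

    def test_not_calculable_excluded_but_in_denominator(self):
        counts = classify_bands([0.8, float("nan"), 0.5], thresholds=(0.4, 0.7))
        assert counts.counts == (0, 1, 1)
        assert counts.n_not_calculable == 1
        assert counts.denominator == 3

    def test_empty_input(self):
        counts = classify_bands([], thresholds=(0.4, 0.7))
        assert counts.counts == (0, 0, 0)

    def test_bad_thresholds(self):
        with pytest.raises(ValueError):
            classify_bands([0.5], thresholds=(0.7, 0.4))

    def test_frame_percentages(self):
        frame = classify_bands([0.8, 0.8, 0.2, np.nan], (0.4, 0.7)).to_frame()
        assert frame["denominator"].tolist() == [4, 4, 4]
        assert frame.loc[frame["band"] == ">=0.7", "percent"].iloc[0] == pytest.approx(50.0)


class TestReport:
    def test_one_result_per_item_in_catalog_order(self, small_dataset):
        report = reliability_report(small_dataset)
        assert report["item_id"].tolist() == list(small_dataset.catalog.item_ids)
        pd.testing.assert_frame_equal(report, reliability_report(small_dataset))

    def test_single_community_all_insufficient(self, catalog):
        records = [
            ("c1", "Canada", "urban", obs, it.item_id, it.scale.min_level)
            for obs in ("o1", "o2", "o3")
            for it in catalog
        ]
        report = reliability_report(make_long(records))
        assert (report["degeneracy"] == "insufficient_data").all()

    def test_absent_item_reported_insufficient(self):
        records = [
            (c, "Canada", "urban", o, "Q4", v)
            for (c, o, v) in [("c1", "o1", 1), ("c1", "o2", 2), ("c2", "o1", 4), ("c2", "o2", 4)]
        ]
        report = reliability_report(make_long(records)).set_index("item_id")
        assert report.loc["Q4", "degeneracy"] == "none"
        assert report.loc["Q1", "degeneracy"] == "insufficient_data"

    def test_by_region_groups(self, small_dataset):
        report = reliability_report(small_dataset, by_region=True)
        assert set(report["group"]) == {"overall", "Canada", "Brazil/Colombia", "India/China"}
        per_group = report.groupby("group").size()
        assert (per_group == len(small_dataset.catalog)).all()

    def test_display_table_clips(self):
        raw = pd.DataFrame({"icc": [-0.2, 0.5], "ci_low": [-0.5, 0.3], "ci_high": [0.1, 0.9]})
        shown = format_reliability_table(raw)
        assert shown["icc"].tolist() == [0.0, 0.5]

    def test_estimator_wrapper(self, small_dataset):
        est = ICCReliability(form="consistency").fit(small_dataset)
        assert est.n_communities_ == 6
        direct = reliability_report(small_dataset, form="consistency")
        pd.testing.assert_frame_equal(est.results_, direct)
        counts = est.band_counts((0.4, 0.7))
        assert counts.denominator == sum(counts.counts) + counts.n_not_calculable
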