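import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from t2ie import (
    PhantomSpec,
    VarianceComponents,
    build_report,
    cov_by_effect,
    cov_percent,
    group_by_effect,
    icc_by_roi,
    icc_consistency_single,
    make_design,
    pairwise_ranksum_bonferroni,
    roi_means,
    sample_scan_truth,
)


def truth_as_roi_table(truth: pd.DataFrame) -> pd.DataFrame:
    return truth.rename(columns={"region": "roi", "true_t2ie_ms": "value"})


def anova_icc_oracle(m):
    """Independent sums-of-squares computation of the consistency ICC."""
    n, k = m.shape
    grand = m.mean()
    ss_rows = sum(k * (m[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (m[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = ((m - grand) ** 2).sum()
    msr = ss_rows / (n - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse)


class TestRoiMeans:
    def test_uniform_label(self):
        labels = np.zeros((4, 4, 4), int)
        labels[:2] = 1
        m = np.full((4, 4, 4), 70.0)
        assert roi_means(m, labels) == {1: 70.0}

    def test_absent_label_no_row(self):
        labels = np.ones((2, 2, 2), int)
        out = roi_means(np.full((2, 2, 2), 5.0), labels)
        assert 2 not in out

    def test_nan_voxels_excluded(self):
        labels = np.ones((2, 2, 2), int)
        m = np.full((2, 2, 2), 3.0)
        m[0, 0, 0] = np.nan
        assert roi_means(m, labels)[1] == pytest.approx(3.0)

    def test_mixed_matches_mask_and_average_oracle(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 4, size=(6, 6, 6))
        m = rng.random((6, 6, 6))
        out = roi_means(m, labels)
        for lab in (1, 2, 3):
            assert out[lab] == pytest.approx(m[labels == lab].mean())

    def test_all_nan_roi_warned_and_omitted(self):
        labels = np.ones((2, 2, 2), int)
        with pytest.warns(UserWarning, match="no valid voxels"):
            out = roi_means(np.full((2, 2, 2), np.nan), labels)
        assert out == {}


class TestGrouping:
    @pytest.fixture(scope="class")
    def table(self):
        truth = sample_scan_truth(
            make_design(), VarianceComponents(), PhantomSpec(), seed=1
        )
        return truth_as_roi_table(truth)

    def test_default_design_group_counts(self, table):
        """20x2x2x2 design: 80/40/20/2 groups per ROI for the four effects."""
        n_rois = table.roi.nunique()
        expected = {
            "inter_run": 80,
            "inter_session": 40,
            "inter_scanner": 20,
            "inter_subject": 2,
        }
        for effect, count in expected.items():
            grouping = group_by_effect(table, effect)
            assert len(grouping.groups) == count * n_rois

    def test_group_sizes(self, table):
        assert all(len(v) == 2 for v in group_by_effect(table, "inter_run").groups.values())
        assert all(
            len(v) == 20
            for v in group_by_effect(table, "inter_subject").groups.values()
        )

    def test_single_subject_design_inter_subject_degenerate(self):
        truth = sample_scan_truth(
            make_design(1, 2, 2, 2), VarianceComponents(), PhantomSpec(), seed=2
        )
        with pytest.warns(UserWarning, match="fewer than 2"):
            grouping = group_by_effect(truth_as_roi_table(truth), "inter_subject")
        assert grouping.groups == {}

    def test_row_order_invariance(self, table):
        shuffled = table.sample(frac=1.0, random_state=3)
        a = group_by_effect(table, "inter_session").groups
        b = group_by_effect(shuffled, "inter_session").groups
        assert a.keys() == b.keys()
        for k in a:
            assert sorted(a[k]) == pytest.approx(sorted(b[k]))

    def test_session_groups_average_runs_first(self, table):
        grouping = group_by_effect(table, "inter_session")
        roi, subj, site = next(iter(grouping.groups))
        sub = table[(table.roi == roi) & (table.subject == subj) & (table.site == site)]
        expected = sorted(sub.groupby("session")["value"].mean())
        assert sorted(grouping.groups[(roi, subj, site)]) == pytest.approx(expected)


class TestCov:
    def test_constant_values(self):
        assert cov_percent([71.0, 71.0, 71.0]) == 0.0

    def test_hand_computed(self):
        assert cov_percent([70.0, 72.0]) == pytest.approx(np.sqrt(2) / 71 * 100, abs=1e-4)

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(4)
        v = rng.random(17) + 1.0
        expected = np.sqrt(np.sum((v - v.mean()) ** 2) / (len(v) - 1)) / v.mean() * 100
        assert cov_percent(v) == pytest.approx(expected, rel=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        v = rng.random(9) + 0.5
        assert cov_percent(3.7 * v) == pytest.approx(cov_percent(v), rel=1e-12)

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            cov_percent([1.0])


class TestICC:
    def test_identical_columns_gives_one(self):
        m = np.tile(np.array([[1.0], [2.0], [5.0], [9.0]]), (1, 3))
        assert icc_consistency_single(m).icc == pytest.approx(1.0)

    def test_constant_column_offset_gives_one(self):
        """Consistency ICC ignores fixed shifts between measurements."""
        base = np.array([3.0, 7.0, 1.0, 10.0, 5.0])
        m = np.column_stack([base, base + 2.0, base - 1.5])
        assert icc_consistency_single(m).icc == pytest.approx(1.0)

    def test_matches_anova_oracle_exactly(self):
        rng = np.random.default_rng(6)
        for _ in range(25):
            m = rng.normal(size=(6, 3)) + rng.normal(size=(6, 1)) * 2
            got = icc_consistency_single(m).icc
            assert got == pytest.approx(anova_icc_oracle(m), abs=1e-10)

    def test_matches_pingouin_cross_check(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        m = rng.normal(size=(8, 4)) + rng.normal(size=(8, 1)) * 1.5
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(8), 4),
                "rater": np.tile(np.arange(4), 8),
                "y": m.ravel(),
            }
        )
        ref = pg.intraclass_corr(long, targets="subject", raters="rater", ratings="y")
        sel = ref.Type.isin(["ICC3", "ICC(C,1)"])
        icc3 = ref.loc[sel, "ICC"].iloc[0]
        assert icc_consistency_single(m).icc == pytest.approx(icc3, abs=1e-8)

    def test_population_value_recovered_on_simulated_data(self):
        """Random-effects simulation (subject SD 2, noise SD 1): the mean
        estimate over replicates approaches 4/5."""
        rng = np.random.default_rng(8)
        estimates = [
            icc_consistency_single(
                rng.normal(0, 2, (20, 1)) + rng.normal(0, 1, (20, 8))
            ).icc
            for _ in range(200)
        ]
        assert np.mean(estimates) == pytest.approx(0.8, abs=0.05)

    def test_missing_cells_rejected(self):
        m = np.ones((3, 3))
        m[0, 0] = np.nan
        with pytest.raises(ValueError):
            icc_consistency_single(m)

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(9)
        m = rng.normal(0, 2, (12, 1)) + rng.normal(0, 1, (12, 5))
        res = icc_consistency_single(m)
        assert res.ci_lower <= res.icc <= res.ci_upper


class TestPairwise:
    def test_identical_lists_not_significant(self):
        lists = {"a": [1.0, 2.0, 3.0, 4.0], "b": [1.0, 2.0, 3.0, 4.0]}
        out = pairwise_ranksum_bonferroni(lists)
        assert out.p_adjusted.iloc[0] == 1.0
        assert not out.significant.iloc[0]

    def test_complete_separation_exact_p(self):
        """n=m=4 complete separation: two-sided exact p = 2/70."""
        lists = {"a": [1.0, 2.0, 3.0, 4.0], "b": [101.0, 102.0, 103.0, 104.0]}
        out = pairwise_ranksum_bonferroni(lists)
        assert out.p_raw.iloc[0] == pytest.approx(2 / 70, abs=1e-10)

    def test_four_effects_six_pairs(self):
        rng = np.random.default_rng(10)
        lists = {e: list(rng.random(5)) for e in "abcd"}
        out = pairwise_ranksum_bonferroni(lists)
        assert len(out) == 6
        assert np.allclose(out.p_adjusted, np.minimum(1.0, out.p_raw * 6))

    def test_short_effect_skipped(self):
        lists = {"a": [1.0, 2.0, 3.0], "b": [2.0], "c": [4.0, 5.0, 6.0]}
        with pytest.warns(UserWarning, match="skipped"):
            out = pairwise_ranksum_bonferroni(lists)
        assert set(out.effect_a) | set(out.effect_b) == {"a", "c"}


class TestReport:
    def test_end_to_end_cov_ordering_from_injected_components(self):
        """Components ordered run < session = site < subject must produce the
        matching median-CoV ordering."""
        truth = sample_scan_truth(
            make_design(), VarianceComponents(), PhantomSpec(), seed=11
        )
        report = build_report(truth_as_roi_table(truth))
        med = report.cov.groupby("effect")["cov_percent"].median()
        assert med["inter_run"] < med["inter_session"]
        assert med["inter_run"] < med["inter_scanner"]
        assert med["inter_session"] < med["inter_subject"]
        assert med["inter_scanner"] < med["inter_subject"]

    def test_report_regenerable_bit_exact(self, tmp_path):
        truth = sample_scan_truth(
            make_design(4, 2, 2, 2), VarianceComponents(), PhantomSpec(), seed=12
        )
        table = truth_as_roi_table(truth)
        build_report(table).to_csv(tmp_path / "r1")
        build_report(table).to_csv(tmp_path / "r2")
        for name in ("cov_by_effect.csv", "icc_by_roi.csv", "pairwise_tests.csv"):
            assert (tmp_path / "r1" / name).read_bytes() == (
                tmp_path / "r2" / name
            ).read_bytes()

    def test_icc_section_empty_with_single_measurement(self):
        truth = sample_scan_truth(
            make_design(5, 1, 1, 1), VarianceComponents(), PhantomSpec(), seed=13
        )
        out = icc_by_roi(truth_as_roi_table(truth))
        assert len(out) == 0
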