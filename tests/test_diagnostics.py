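"""ROC/AUC machinery against independent oracles (exhaustive pair counting,
exhaustive threshold scans, sklearn, bootstrap), confusion reconstruction,
and the summary-statistic t-test."""

import json
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from otva import (
    CriteriaConfig,
    Direction,
    Origin,
    SummaryStats,
    auc_ci,
    auc_mann_whitney,
    confusion_from_summary,
    default_spec,
    evaluate_cohort,
    generate,
    metrics_from_calls,
    roc_curve,
    two_group_test_from_summary,
    youden_cutoff,
)
from tests.conftest import pair_count_auc


def labeled_instances():
    """Random small two-class instances with ties (values on a coarse grid)."""
    return st.lists(
        st.tuples(st.integers(min_value=0, max_value=12), st.booleans()),
        min_size=4, max_size=30,
    ).filter(lambda xs: 0 < sum(b for _, b in xs) < len(xs))


def unpack(instance):
    values = [float(v) / 2.0 for v, _ in instance]
    labels = ["RVOT" if b else "LVOT" for _, b in instance]
    return values, labels


class TestAuc:
    def test_midrank_tie_example(self):
        assert auc_mann_whitney([1, 2, 2, 3], ["LVOT", "LVOT", "RVOT", "RVOT"]) == 0.875

    def test_perfect_separation(self):
        assert auc_mann_whitney([1, 2, 3, 4], ["LVOT", "LVOT", "RVOT", "RVOT"]) == 1.0

    def test_all_values_equal_gives_half(self):
        assert auc_mann_whitney([5, 5, 5, 5], ["LVOT", "RVOT", "LVOT", "RVOT"]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_mann_whitney([1, 2], ["RVOT", "RVOT"])

    @given(instance=labeled_instances())
    def test_equals_exhaustive_pair_counting_oracle(self, instance):
        values, labels = unpack(instance)
        assert auc_mann_whitney(values, labels) == pytest.approx(
            pair_count_auc(values, labels), abs=1e-12)

    @given(instance=labeled_instances())
    def test_equals_trapezoidal_roc_area(self, instance):
        values, labels = unpack(instance)
        assert roc_curve(values, labels).auc == pytest.approx(
            auc_mann_whitney(values, labels), abs=1e-12)

    @given(instance=labeled_instances())
    def test_agrees_with_sklearn(self, instance):
        values, labels = unpack(instance)
        y = [1 if l == "RVOT" else 0 for l in labels]
        assert auc_mann_whitney(values, labels) == pytest.approx(
            roc_auc_score(y, values), abs=1e-12)

    @given(instance=labeled_instances())
    def test_sign_reversal_complements(self, instance):
        values, labels = unpack(instance)
        assert auc_mann_whitney([-v for v in values], labels) == pytest.approx(
            1.0 - auc_mann_whitney(values, labels), abs=1e-12)

    def test_binormal_closed_form_at_printed_index_parameters(self, rng):
        """Simulated binormal sample at the printed V2S-angle group moments
        lands within Monte-Carlo error of Phi(dmu / sqrt(s1^2 + s2^2))."""
        n = 4000
        pos = rng.normal(68.64, 29.85, n)
        neg = rng.normal(31.80, 17.08, n)
        values = np.concatenate([pos, neg])
        labels = ["RVOT"] * n + ["LVOT"] * n
        closed = sps.norm.cdf((68.64 - 31.80) / math.sqrt(29.85**2 + 17.08**2))
        assert auc_mann_whitney(values, labels) == pytest.approx(closed, abs=0.02)


class TestRocCurve:
    def test_curve_endpoints_and_monotonicity(self):
        roc = roc_curve([1, 2, 2, 3, 5], ["LVOT", "LVOT", "RVOT", "RVOT", "RVOT"])
        assert (roc.fpr[0], roc.tpr[0]) == (0.0, 0.0)
        assert (roc.fpr[-1], roc.tpr[-1]) == (1.0, 1.0)
        assert all(a <= b for a, b in zip(roc.tpr, roc.tpr[1:]))
        assert all(a <= b for a, b in zip(roc.fpr, roc.fpr[1:]))

    def test_derived_example_cutoff_between_classes(self):
        roc = roc_curve([1, 2, 3, 4], ["LVOT", "LVOT", "RVOT", "RVOT"])
        assert roc.auc == 1.0
        assert 2 < roc.optimal_cutoff < 3
        assert roc.optimal_cutoff == 2.5  # midpoint convention

    def test_degenerate_all_equal_flags_and_returns_lowest(self):
        roc = roc_curve([3, 3, 3], ["RVOT", "LVOT", "RVOT"])
        assert roc.degenerate
        assert youden_cutoff(roc) == 3.0

    def test_lvot_direction_mirrors(self):
        values = [1, 2, 3, 4]
        labels = ["RVOT", "RVOT", "LVOT", "LVOT"]  # low value -> RVOT
        roc = roc_curve(values, labels, Direction.GE_PREDICTS_LVOT)
        assert roc.auc == 1.0
        assert 2 < roc.optimal_cutoff < 3

    def test_rvot_positive_orientation_below_half_then_flipped(self):
        """A criterion whose high side predicts LVOT shows AUC < 0.5 when
        evaluated RVOT-positive; flipping orientation complements it."""
        values = [1, 2, 3, 4, 5, 6]
        labels = ["RVOT", "RVOT", "RVOT", "LVOT", "RVOT", "LVOT"]
        a_plus = roc_curve(values, labels, Direction.GE_PREDICTS_RVOT).auc
        a_minus = roc_curve(values, labels, Direction.GE_PREDICTS_LVOT).auc
        assert a_minus == pytest.approx(1.0 - a_plus, abs=1e-12)

    @given(instance=labeled_instances())
    def test_youden_cutoff_equals_exhaustive_scan(self, instance):
        """The returned cutoff achieves the maximum J found by scanning every
        candidate threshold exhaustively, with the stated tie-breaks."""
        values, labels = unpack(instance)
        roc = roc_curve(values, labels)
        y = np.array([1 if l == "RVOT" else 0 for l in labels])
        v = np.array(values)

        def j_at(t):
            called = v >= t
            tpr = (called & (y == 1)).sum() / y.sum()
            fpr = (called & (y == 0)).sum() / (len(y) - y.sum())
            return tpr - fpr

        best_j = max(j_at(t) for t in np.unique(v))
        if not roc.degenerate:
            assert j_at(roc.optimal_cutoff) == pytest.approx(best_j, abs=1e-12)


class TestAucCi:
    def test_perfect_separation_clips_at_one(self):
        values = list(range(40))
        labels = ["LVOT"] * 20 + ["RVOT"] * 20
        low, high = auc_ci(values, labels)
        assert high == 1.0
        assert low <= 1.0

    def test_auc_inside_interval(self, rng):
        values = np.concatenate([rng.normal(1, 1, 30), rng.normal(0, 1, 30)])
        labels = ["RVOT"] * 30 + ["LVOT"] * 30
        auc = auc_mann_whitney(values, labels)
        for method in ("delong", "bootstrap"):
            low, high = auc_ci(values, labels, method=method, seed=5)
            assert low <= auc <= high

    def test_delong_and_bootstrap_agree(self, rng):
        """On a fixed 60-sample draw the DeLong normal interval matches a
        10^4-resample percentile bootstrap to within 0.02."""
        values = np.concatenate([rng.normal(1.2, 1, 30), rng.normal(0, 1, 30)])
        labels = ["RVOT"] * 30 + ["LVOT"] * 30
        d_low, d_high = auc_ci(values, labels, method="delong")
        b_low, b_high = auc_ci(values, labels, method="bootstrap", seed=99,
                               n_boot=10_000)
        assert d_low == pytest.approx(b_low, abs=0.02)
        assert d_high == pytest.approx(b_high, abs=0.02)

    def test_bootstrap_requires_seed(self):
        with pytest.raises(ValueError):
            auc_ci([1, 2, 3, 4], ["LVOT", "LVOT", "RVOT", "RVOT"], method="bootstrap")


class TestMetricsFromCalls:
    def test_all_correct(self):
        m = metrics_from_calls(["RVOT", "LVOT", "RVOT"], ["RVOT", "LVOT", "RVOT"])
        assert (m.sensitivity, m.specificity, m.ppv, m.npv, m.accuracy) == (1, 1, 1, 1, 1)

    def test_all_rvot_calls_leave_npv_missing(self):
        m = metrics_from_calls(["RVOT", "RVOT", "RVOT"], ["RVOT", "LVOT", "RVOT"])
        assert m.specificity == 0.0
        assert m.npv is None

    def test_indeterminate_excluded_and_counted(self):
        m = metrics_from_calls(["RVOT", "INDETERMINATE", "LVOT"],
                               ["RVOT", "RVOT", "LVOT"])
        assert m.n == 2 and m.n_indeterminate == 1

    def test_published_confusion_counts_give_printed_predictive_values(self):
        m = metrics_from_calls(
            ["RVOT"] * 108 + ["LVOT"] * 18 + ["RVOT"] * 1 + ["LVOT"] * 20,
            ["RVOT"] * 126 + ["LVOT"] * 21,
        )
        assert (m.tp, m.fp, m.tn, m.fn) == (108, 1, 20, 18)
        assert round(100 * m.ppv, 1) == 99.1
        assert round(100 * m.npv, 1) == 52.6

    def test_no_usable_calls_rejected(self):
        with pytest.raises(ValueError):
            metrics_from_calls(["INDETERMINATE"], ["RVOT"])


class TestConfusionFromSummary:
    @pytest.mark.parametrize(
        "sens,spec,n_pos,n_neg,tp,fp,tn,fn",
        [
            (0.857, 0.952, 126, 21, 108, 1, 20, 18),
            (1.0, 1.0, 10, 10, 10, 0, 10, 0),
            (0.972, 0.833, 36, 12, 35, 2, 10, 1),
        ],
    )
    def test_count_reconstruction(self, sens, spec, n_pos, n_neg, tp, fp, tn, fn):
        m = confusion_from_summary(sens, spec, n_pos, n_neg)
        assert (m.tp, m.fp, m.tn, m.fn) == (tp, fp, tn, fn)

    @given(
        sens=st.floats(min_value=0, max_value=1),
        spec=st.floats(min_value=0, max_value=1),
        n_pos=st.integers(min_value=1, max_value=300),
        n_neg=st.integers(min_value=1, max_value=300),
    )
    def test_roundtrip_within_half_count(self, sens, spec, n_pos, n_neg):
        """Recomputed sens/spec return the inputs to +/- 0.5/n rounding."""
        m = confusion_from_summary(sens, spec, n_pos, n_neg)
        assert abs(m.sensitivity - sens) <= 0.5 / n_pos + 1e-12
        assert abs(m.specificity - spec) <= 0.5 / n_neg + 1e-12


class TestSummaryTTest:
    def test_identical_groups(self):
        a = SummaryStats(10.0, 2.0, 20)
        t, df, p = two_group_test_from_summary(a, a)
        assert t == 0.0 and p == 1.0

    def test_procedure_time_comparison(self):
        """Pooled t-test of the two cohorts' procedure times (min)."""
        t, df, p = two_group_test_from_summary(
            SummaryStats(78.8, 31.8, 48), SummaryStats(99.5, 40.8, 147))
        assert df == 193
        assert p == pytest.approx(0.002, abs=5e-4)

    def test_student_equals_welch_for_equal_sd_and_n(self):
        a, b = SummaryStats(5.0, 2.0, 30), SummaryStats(6.0, 2.0, 30)
        ts, _, ps = two_group_test_from_summary(a, b, "student")
        tw, _, pw = two_group_test_from_summary(a, b, "welch")
        assert ts == pytest.approx(tw) and ps == pytest.approx(pw)


@pytest.fixture(scope="module")
def small_cohort():
    return generate(default_spec("retrospective", seed=3))


class TestEvaluateCohort:
    def test_report_has_every_enabled_criterion(self, small_cohort):
        cfg = CriteriaConfig.preset("published")
        report = evaluate_cohort(small_cohort, cfg)
        assert set(report["criteria"]) == set(cfg.enabled_criteria())
        v2s = report["criteria"]["v2s_angle"]
        assert v2s["auc"] is not None and 0 <= v2s["auc"] <= 1
        assert v2s["metrics_at_preset"]["tp"] >= 0
        assert report["n_rvot"] == 126 and report["n_lvot"] == 21

    def test_two_patient_perfect_ordering(self, fig_record):
        from tests.conftest import make_record
        lo = make_record("a", Origin.LVOT, v2s=0.5, v3r=1.5, v1s=0.3, v1r=0.4,
                         v2r=0.8, v3s=0.4, angle_deg=30.0)
        hi = make_record("b", Origin.RVOT, v2s=2.5, v3r=0.5, v1s=1.5, v1r=0.2,
                         v2r=0.3, v3s=1.0, angle_deg=45.0)
        report = evaluate_cohort([lo, hi])
        assert report["criteria"]["v2s_angle"]["auc"] == 1.0
        assert report["criteria"]["v12_srd"]["auc"] == 1.0

    def test_rerun_is_byte_identical(self, small_cohort, tmp_path):
        from otva.cli_reporting import write_report
        cfg = CriteriaConfig.preset("published")
        p1, p2 = tmp_path / "r1.json", tmp_path / "r2.json"
        write_report(evaluate_cohort(small_cohort, cfg), p1)
        write_report(evaluate_cohort(small_cohort, cfg), p2)
        assert p1.read_bytes() == p2.read_bytes()
        json.loads(p1.read_text())  # valid JSON

    def test_unlabeled_cohort_rejected(self, fig_record):
        rec = fig_record
        rec.origin = Origin.UNKNOWN
        with pytest.raises(ValueError):
            evaluate_cohort([rec])
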