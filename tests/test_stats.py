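"""Normality gate, paired Wilcoxon, effect size and FDR adjustment."""

import numpy as np
import pytest
import scipy.stats as sps

from cryofsl.evaluation import MetricTable
from cryofsl.stats import (bh_adjust, compare_methods, rank_biserial,
                           shapiro_gate, wilcoxon_paired)


class TestShapiroGate:
    def test_constant_sample_non_testable(self):
        with pytest.warns(UserWarning, match="constant"):
            res = shapiro_gate([2.0] * 10)
        assert not res.testable and not res.is_normal

    def test_gaussian_samples_usually_pass(self):
        rng = np.random.default_rng(1)
        hits = sum(shapiro_gate(rng.normal(size=50)).is_normal
                   for _ in range(100))
        assert hits >= 90

    def test_exponential_samples_usually_fail(self):
        rng = np.random.default_rng(2)
        hits = sum(not shapiro_gate(rng.exponential(size=50)).is_normal
                   for _ in range(100))
        assert hits >= 90

    def test_sample_size_bounds(self):
        with pytest.raises(ValueError):
            shapiro_gate([1.0, 2.0])


class TestWilcoxon:
    def test_identical_samples_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = wilcoxon_paired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.z == 0.0 and res.pvalue == 1.0

    def test_uniform_shift_is_extreme(self):
        rng = np.random.default_rng(3)
        b = rng.normal(size=20)
        a = b + 1.0
        res = wilcoxon_paired(a, b)
        assert res.statistic == 0.0  # W- = 0: every difference positive
        assert res.pvalue < 0.001
        assert res.z > 0  # a exceeds b

    def test_matches_scipy_normal_approximation(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            a = rng.normal(size=30)
            b = rng.normal(size=30) + rng.normal(0, 0.3)
            mine = wilcoxon_paired(a, b)
            ref = sps.wilcoxon(a, b, correction=False, method="approx")
            assert mine.pvalue == pytest.approx(ref.pvalue, abs=1e-12)
            assert abs(mine.z) == pytest.approx(abs(ref.zstatistic), abs=1e-12)
            assert mine.statistic == ref.statistic

    def test_too_few_nonzero_differences_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            wilcoxon_paired([1.0, 2.0, 3.0, 4.0], [0.0, 1.0, 2.0, 3.0])

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(0)
        rejections = sum(
            wilcoxon_paired(rng.normal(size=30), rng.normal(size=30)).pvalue < 0.05
            for _ in range(1000))
        assert 0.03 <= rejections / 1000 <= 0.07


class TestRankBiserial:
    @pytest.mark.parametrize("z,N,expected", [
        (2.0, 16, 0.5),
        (0.0, 7, 0.0),
        (-3.3, 121, -0.3),
    ])
    def test_formula(self, z, N, expected):
        assert rank_biserial(z, N) == pytest.approx(expected, abs=1e-12)

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            rank_biserial(1.0, 0)


class TestBhAdjust:
    def test_hand_applied_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == [0.2]

    def test_thirty_equal_ps_unchanged(self):
        assert bh_adjust([0.04] * 30) == pytest.approx([0.04] * 30)

    def test_matches_reference_step_up_on_random_vectors(self):
        def reference(p):
            p = np.asarray(p)
            m = len(p)
            order = np.argsort(p)
            q = np.empty(m)
            prev = 1.0
            for rank in range(m, 0, -1):
                idx = order[rank - 1]
                prev = min(prev, p[idx] * m / rank)
                q[idx] = prev
            return q

        rng = np.random.default_rng(5)
        for _ in range(20):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(bh_adjust(p), reference(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_adjusted_ps_dominate_raw_and_preserve_order(self):
        from hypothesis import given, settings, strategies as st

        @settings(max_examples=50, deadline=None, derandomize=True)
        @given(st.lists(st.floats(min_value=0.0, max_value=1.0, width=32),
                        min_size=1, max_size=40))
        def check(pvals):
            q = np.array(bh_adjust(pvals))
            p = np.array(pvals)
            assert np.all(q >= p - 1e-12)
            assert np.all(q <= 1.0 + 1e-12)
            # monotone in the order statistics of the input
            order = np.argsort(p)
            assert np.all(np.diff(q[order]) >= -1e-12)

        check()


def _table(methods, datasets, n_mics, metric_fn, seed=0):
    rng = np.random.default_rng(seed)
    records = []
    for method in methods:
        for dataset in datasets:
            for i in range(n_mics):
                base = rng.random()
                v = float(np.clip(metric_fn(method, base), 0.0, 1.0))
                records.append({
                    "method": method, "dataset": dataset, "micrograph": f"m{i}",
                    "precision": v, "recall": v, "f1": v, "iou": v})
    return MetricTable.from_records(records)


class TestCompareMethods:
    def test_identical_method_yields_null_result(self):
        rng = np.random.default_rng(7)
        values = {f"m{i}": rng.random() for i in range(10)}
        records = []
        for method in ("ref", "same"):
            for mic, v in values.items():
                records.append({"method": method, "dataset": "d0",
                                "micrograph": mic, "precision": v,
                                "recall": v, "f1": v, "iou": v})
        report = compare_methods(MetricTable.from_records(records), "ref")
        assert (report.frame["p_adj"] == 1.0).all()
        assert (report.frame["effect_r"] == 0.0).all()

    def test_uniform_deficit_detected_with_negative_effect(self):
        rng = np.random.default_rng(8)
        base = {f"m{i}": 0.3 + 0.5 * rng.random() for i in range(12)}
        records = []
        for method, delta in (("ref", 0.0), ("worse", -0.2)):
            for mic, v in base.items():
                w = v + delta
                records.append({"method": method, "dataset": "d0",
                                "micrograph": mic, "precision": w,
                                "recall": w, "f1": w, "iou": w})
        report = compare_methods(MetricTable.from_records(records), "ref")
        assert (report.frame["p_adj"] < 0.05).all()
        assert (report.frame["effect_r"] < 0).all()

    def test_five_methods_six_datasets_thirty_tests_per_metric(self):
        methods = ["ref"] + [f"method{k}" for k in range(5)]
        table = _table(methods, [f"ds{k}" for k in range(6)], 8,
                       lambda m, b: b, seed=9)
        report = compare_methods(table, "ref")
        for metric in ("precision", "recall", "f1", "iou"):
            assert (report.frame.metric == metric).sum() == 30

    def test_too_few_pairs_flagged_untestable(self):
        table = _table(["ref", "other"], ["d0"], 3, lambda m, b: b, seed=10)
        report = compare_methods(table, "ref")
        assert not report.frame["testable"].any()

    def test_unknown_reference_rejected(self):
        table = _table(["a", "b"], ["d0"], 6, lambda m, b: b)
        with pytest.raises(ValueError, match="reference"):
            compare_methods(table, "zzz")

    def test_pipeline_type_one_error_under_simulated_null(self):
        rng = np.random.default_rng(11)
        false_positives = 0
        n_sims = 500
        for _ in range(n_sims):
            vals_ref = rng.random(30)
            vals_cmp = rng.random(30)
            records = []
            for method, vals in (("ref", vals_ref), ("other", vals_cmp)):
                for i, v in enumerate(vals):
                    records.append({"method": method, "dataset": "d0",
                                    "micrograph": f"m{i}", "precision": v,
                                    "recall": v, "f1": v, "iou": v})
            report = compare_methods(MetricTable.from_records(records), "ref",
                                     metrics=("f1",))
            false_positives += bool((report.frame["p_adj"] < 0.05).any())
        assert false_positives / n_sims <= 0.07
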