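import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stageinv.errors import ContractError, UndefinedMetricError
from stageinv.metrics import (
    ConfusionMatrix,
    accuracy_metric,
    bootstrap_ci,
    confusion_matrix,
    c_statistic,
    f1_score,
    metric_table,
    one_vs_rest_counts,
    one_vs_rest_metrics,
    overall_accuracy,
    ovr_metric,
)
from stageinv.staging import COARSE_STAGES, coarse, fine


def pairs_from_codes(codes):
    return [(coarse(r), coarse(c)) for r, c in codes]


def random_matrix(rng):
    counts = rng.integers(0, 50, size=(4, 4))
    while counts.sum() == 0:
        counts = rng.integers(0, 50, size=(4, 4))
    return ConfusionMatrix(COARSE_STAGES, counts, int(counts.sum()))


class TestConfusionMatrix:
    def test_counting(self):
        cm = confusion_matrix(pairs_from_codes([("I", "I"), ("I", "II"), ("IV", "IV")]))
        assert cm.counts[0, 0] == 1 and cm.counts[0, 1] == 1 and cm.counts[3, 3] == 1
        assert cm.n_total == 3

    def test_empty_input_gives_zero_matrix(self):
        cm = confusion_matrix([])
        assert cm.n_total == 0 and cm.counts.sum() == 0

    def test_repeated_pairs_accumulate_one_cell(self):
        cm = confusion_matrix(pairs_from_codes([("II", "II")] * 100))
        assert cm.counts[1, 1] == 100

    def test_fine_labels_rejected(self):
        with pytest.raises(ContractError):
            confusion_matrix([(fine("IA"), coarse("I"))])


class TestOverallAccuracy:
    def test_perfect_diagonal_is_one(self):
        cm = ConfusionMatrix(COARSE_STAGES, np.diag([5, 5, 5, 5]), 20)
        assert overall_accuracy(cm) == 1.0

    def test_all_off_diagonal_is_zero(self):
        counts = np.ones((4, 4), dtype=int) - np.eye(4, dtype=int)
        cm = ConfusionMatrix(COARSE_STAGES, counts, 12)
        assert overall_accuracy(cm) == 0.0

    def test_direct_count_oracle(self):
        counts = np.diag([90, 5, 3, 2])
        counts[0, 1] = 4
        counts[1, 0] = 3
        counts[2, 3] = 3
        cm = ConfusionMatrix(COARSE_STAGES, counts, 110)
        assert overall_accuracy(cm) == pytest.approx(100 / 110)

    def test_empty_matrix_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            overall_accuracy(confusion_matrix([]))

    def test_invariant_under_simultaneous_label_permutation(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            cm = random_matrix(rng)
            perm = rng.permutation(4)
            permuted = ConfusionMatrix(
                COARSE_STAGES, cm.counts[np.ix_(perm, perm)], cm.n_total
            )
            assert overall_accuracy(permuted) == pytest.approx(overall_accuracy(cm))


class TestOneVsRest:
    def test_counts_partition_the_total(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            cm = random_matrix(rng)
            for stage in COARSE_STAGES:
                assert sum(one_vs_rest_counts(cm, stage)) == cm.n_total

    def test_f1_is_harmonic_mean_to_machine_precision(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            cm = random_matrix(rng)
            for stage in COARSE_STAGES:
                ms = one_vs_rest_metrics(cm, stage)
                if ms.sensitivity is None or ms.ppv is None or ms.f1 is None:
                    continue
                hmean = 2 / (1 / ms.sensitivity + 1 / ms.ppv) if ms.sensitivity and ms.ppv else 0.0
                assert ms.f1 == pytest.approx(hmean, abs=1e-15)

    def test_c_statistic_equals_balanced_accuracy_and_two_point_auc(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            cm = random_matrix(rng)
            for stage in COARSE_STAGES:
                ms = one_vs_rest_metrics(cm, stage)
                if ms.c_statistic is None:
                    continue
                tpr, fpr = ms.sensitivity, 1 - ms.specificity
                auc = np.trapezoid([0.0, tpr, 1.0], [0.0, fpr, 1.0])
                assert ms.c_statistic == pytest.approx((ms.sensitivity + ms.specificity) / 2)
                assert ms.c_statistic == pytest.approx(auc, abs=1e-12)

    def test_absent_reference_stage_leaves_sensitivity_undefined(self):
        cm = confusion_matrix(pairs_from_codes([("I", "I"), ("II", "I")]))
        ms = one_vs_rest_metrics(cm, "IV")
        assert ms.sensitivity is None
        assert ms.specificity == 1.0  # no false positives for IV

    def test_metric_values_stay_in_unit_interval(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            cm = random_matrix(rng)
            for stage in COARSE_STAGES:
                ms = one_vs_rest_metrics(cm, stage)
                for name in ("sensitivity", "specificity", "ppv", "npv", "f1", "c_statistic"):
                    v = ms.value(name)
                    assert v is None or 0.0 <= v <= 1.0


@given(sens=st.floats(0.01, 1.0), ppv=st.floats(0.01, 1.0), spec=st.floats(0.0, 1.0))
@settings(max_examples=100, derandomize=True)
def test_metric_formula_helpers(sens, ppv, spec):
    assert f1_score(sens, ppv) == pytest.approx(2 * sens * ppv / (sens + ppv))
    assert c_statistic(sens, spec) == pytest.approx((sens + spec) / 2)


class TestBootstrap:
    def test_degenerate_sample_gives_degenerate_interval(self):
        pairs = pairs_from_codes([("I", "I")] * 30)
        lo, hi = bootstrap_ci(pairs, accuracy_metric(), B=200, seed=0)
        assert (lo, hi) == (1.0, 1.0)

    def test_same_seed_reproduces_interval(self):
        rng = np.random.default_rng(5)
        codes = [("I", "I")] * 80 + [("I", "II")] * 10 + [("IV", "IV")] * 10
        pairs = pairs_from_codes(codes)
        a = bootstrap_ci(pairs, accuracy_metric(), B=300, seed=42)
        b = bootstrap_ci(pairs, accuracy_metric(), B=300, seed=42)
        assert a == b
        c = bootstrap_ci(pairs, accuracy_metric(), B=300, seed=43)
        assert a != c

    def test_interval_brackets_point_estimate(self):
        codes = [("I", "I")] * 70 + [("II", "I")] * 15 + [("III", "III")] * 15
        pairs = pairs_from_codes(codes)
        cm = confusion_matrix(pairs)
        acc = overall_accuracy(cm)
        lo, hi = bootstrap_ci(pairs, accuracy_metric(), B=500, seed=1)
        assert lo <= acc <= hi

    def test_ovr_metric_matches_one_vs_rest_metrics(self):
        rng = np.random.default_rng(6)
        ref = rng.integers(0, 4, 200)
        inf = rng.integers(0, 4, 200)
        codes = [(COARSE_STAGES[r], COARSE_STAGES[c]) for r, c in zip(ref, inf)]
        cm = confusion_matrix(pairs_from_codes(codes))
        for stage in COARSE_STAGES:
            ms = one_vs_rest_metrics(cm, stage)
            for name in ("sensitivity", "specificity", "ppv", "npv", "f1", "c_statistic"):
                got = ovr_metric(name, stage)(ref, inf)
                want = ms.value(name)
                if want is None:
                    assert math.isnan(got)
                else:
                    assert got == pytest.approx(want)

    def test_empty_sample_rejected(self):
        with pytest.raises(ContractError):
            bootstrap_ci([], accuracy_metric(), B=10, seed=0)


def test_metric_table_shape_and_format():
    codes = [("I", "I")] * 50 + [("II", "II")] * 20 + [("III", "IV")] * 10 + [("IV", "IV")] * 20
    table = metric_table(pairs_from_codes(codes), B=50, seed=0)
    assert list(table.columns) == ["metric", "I", "II", "III", "IV"]
    assert len(table) == 6
    cell = table.loc[0, "I"]
    assert "(" in cell and "," in cell
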