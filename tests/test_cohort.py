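"""Age normalisation, ROC AUC, GOLD classification and group tests."""

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st
from scipy import stats

from istlung import (
    AgeNormModel,
    SubjectRecord,
    classify_gold,
    generate_cohort,
    group_tests,
    percent_predicted,
    roc_auc,
)
from istlung.exceptions import ConfigurationError, UndefinedInputError

GOLD_ORDER = {"healthy": 0, "GOLD1": 1, "GOLD2": 2, "GOLD3": 3, "GOLD4": 4}


class TestPercentPredicted:
    def test_intercept_at_age_zero(self):
        model = AgeNormModel()
        assert model.predicted(0.0, "V") == pytest.approx(0.46)
        assert model.predicted(0.0, "P") == pytest.approx(0.75)

    def test_exact_hundred_percent(self):
        # 0.0043 * 50 + 0.46 = 0.675
        assert percent_predicted(0.675, 50.0, "V") == pytest.approx(100.0)

    def test_linear_in_sigma(self):
        one = percent_predicted(0.4, 60.0, "P")
        two = percent_predicted(0.8, 60.0, "P")
        assert two == pytest.approx(2 * one)

    def test_invalid_age_or_channel(self):
        with pytest.raises(ConfigurationError):
            percent_predicted(0.5, 0.0, "V")
        with pytest.raises(ConfigurationError):
            percent_predicted(0.5, 50.0, "X")

    def test_degenerate_model_rejected(self):
        with pytest.raises(ConfigurationError):
            AgeNormModel(slope_v=-0.1, intercept_v=0.5)


def _auc_brute_force(labels, scores):
    """Exhaustive pairwise oracle: P(pos > neg) + 0.5 P(tie)."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_worked_example(self):
        assert roc_auc([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.1]) == pytest.approx(0.75)

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedInputError):
            roc_auc([1, 1, 1], [0.2, 0.4, 0.6])

    @hyp_settings(max_examples=80, derandomize=True)
    @given(
        labels=st.lists(st.integers(0, 1), min_size=2, max_size=12),
        data=st.data(),
    )
    def test_matches_brute_force_on_small_inputs(self, labels, data):
        if len(set(labels)) < 2:
            labels = labels[:-1] + [1 - labels[-1]]
        scores = data.draw(
            st.lists(
                st.sampled_from([0.0, 0.25, 0.5, 0.75, 1.0]),
                min_size=len(labels), max_size=len(labels),
            )
        )
        assert roc_auc(labels, scores) == pytest.approx(
            _auc_brute_force(labels, scores)
        )


def _make_records(groups_values, ages=60.0):
    records = []
    i = 0
    for group, values in groups_values.items():
        for sv, sp in values:
            records.append(
                SubjectRecord(
                    id=f"S{i:03d}", age=ages, group=group,
                    sigma_v=sv, sigma_p=sp,
                )
            )
            i += 1
    return records


class TestClassifyGold:
    def test_separable_classes_fully_recovered(self):
        records = _make_records(
            {
                "healthy": [(0.5 + 0.01 * k, 0.8 + 0.01 * k) for k in range(6)],
                "GOLD4": [(1.8 + 0.01 * k, 2.2 + 0.01 * k) for k in range(6)],
            }
        )
        report = classify_gold(records)
        assert report.overall_accuracy == 100.0
        assert report.auc == 1.0

    def test_confusion_rows_sum_to_class_counts(self):
        records = generate_cohort(32, 72, seed=0)
        report = classify_gold(records)
        counts = {g: sum(r.group == g for r in records)
                  for g in report.class_labels}
        for i, g in enumerate(report.class_labels):
            assert report.confusion[i].sum() == counts[g]

    def test_repeatable_given_records_and_seed(self):
        records = generate_cohort(32, 72, seed=1)
        r1 = classify_gold(records, seed=0)
        r2 = classify_gold(records, seed=0)
        assert np.array_equal(r1.confusion, r2.confusion)
        assert r1.overall_accuracy == r2.overall_accuracy

    def test_predictions_within_one_gold_level(self):
        """Misclassifications on the default cohort stay within +-1 grade."""
        records = generate_cohort(32, 72, seed=0)
        report = classify_gold(records)
        n_total = report.confusion.sum()
        n_within = sum(
            report.confusion[i, j]
            for i in range(5)
            for j in range(5)
            if abs(i - j) <= 1
        )
        assert n_within / n_total >= 0.90

    def test_degenerate_class_rejected(self):
        records = _make_records(
            {"healthy": [(0.5, 0.8)] * 5, "GOLD1": [(1.0, 1.2)]}
        )
        with pytest.raises(ConfigurationError, match="GOLD1"):
            classify_gold(records)

    def test_single_class_rejected(self):
        records = _make_records({"healthy": [(0.5, 0.8)] * 5})
        with pytest.raises(ConfigurationError):
            classify_gold(records)


class TestGroupTests:
    def test_identical_groups_give_zero_t(self):
        values = [(0.5, 0.8), (0.6, 0.9), (0.7, 1.0), (0.8, 1.1)]
        records = _make_records({"healthy": values, "GOLD2": values})
        out = group_tests(records, value="sigma_v")
        assert out["t_stat"] == pytest.approx(0.0, abs=1e-12)

    def test_kruskal_two_groups_equals_ranksum_chi_square(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.7, 0.1, 15)
        b = rng.normal(0.9, 0.1, 17)
        records = _make_records(
            {
                "healthy": [(v, v) for v in a],
                "GOLD1": [(v, v) for v in b],
            }
        )
        out = group_tests(records, value="sigma_v")
        z = stats.ranksums(a, b).statistic
        assert out["kruskal_h"] == pytest.approx(z**2, rel=1e-10)

    def test_two_sd_shift_is_highly_significant(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.70, 0.15, 30)
        b = rng.normal(1.00, 0.15, 30)  # shift of 2 pooled SD
        records = _make_records(
            {
                "healthy": [(abs(v) + 0.05, 1.0) for v in a],
                "GOLD3": [(abs(v) + 0.05, 1.0) for v in b],
            }
        )
        out = group_tests(records, value="sigma_v")
        assert out["t_pvalue"] < 0.001
        assert out["kruskal_pvalue"] < 0.001

    def test_small_group_rejected(self):
        records = _make_records(
            {"healthy": [(0.5, 0.8), (0.6, 0.9)], "GOLD1": [(1.0, 1.2)]}
        )
        with pytest.raises(ConfigurationError):
            group_tests(records)
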