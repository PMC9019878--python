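"""Confusion tables, metrics with CIs, ROM, resection rates, chi-squared, AUC."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from thyrisk.errors import ContractError, DomainError, UndefinedMetricError
from thyrisk.performance import (
    ConfusionTable,
    alteration_summaries,
    auc_mann_whitney,
    binary_metrics,
    chi2_2x2,
    compare_proportions,
    confusion_table,
    resection_rates,
    rom,
    wald_cc_ci,
    wilson_ci,
)
from thyrisk.reference import DNA_RNA_PRINTED_CONFUSION


class TestConfusionTable:
    def test_rna_as_malignant(self, resected):
        ct = confusion_table(resected, "rna_call", "as_malignant")
        assert (ct.tp, ct.fp, ct.tn, ct.fn) == (40, 9, 6, 3)

    def test_rna_as_benign(self, resected):
        ct = confusion_table(resected, "rna_call", "as_benign")
        assert (ct.tp, ct.fp, ct.tn, ct.fn) == (32, 17, 8, 1)

    def test_gc_listing_vs_printed_counts(self, resected):
        # the histology listing carries one more false positive than the
        # published per-test 2x2; both are first-class in the package
        ct = confusion_table(resected, "gc_call", "as_malignant")
        assert (ct.tp, ct.fp, ct.tn, ct.fn) == (38, 8, 7, 5)
        assert DNA_RNA_PRINTED_CONFUSION == (38, 7, 8, 5)

    def test_counts_partition_records(self, resected):
        ct = confusion_table(resected, "gc_call")
        assert ct.total == len(resected)

    def test_empty_input(self):
        ct = confusion_table(pd.DataFrame(columns=["histology", "resected", "gc_call"]))
        assert (ct.tp, ct.fp, ct.tn, ct.fn) == (0, 0, 0, 0)

    def test_unresected_record_rejected(self, full_cohort):
        with pytest.raises(ContractError):
            confusion_table(full_cohort, "rna_call")


class TestBinaryMetrics:
    def test_reference_points(self, resected):
        m = binary_metrics(confusion_table(resected, "rna_call"))
        assert m["sensitivity"].point == pytest.approx(40 / 43)
        assert m["ppv"].point == pytest.approx(40 / 49)
        assert m["npv"].point == pytest.approx(6 / 9)
        assert m["specificity"].point == pytest.approx(6 / 15)

    def test_specificity_example(self):
        m = binary_metrics(ConfusionTable(tp=1, fp=7, tn=8, fn=1))
        assert m["specificity"].point == pytest.approx(8 / 15)

    def test_zero_denominator_raises_named(self):
        with pytest.raises(UndefinedMetricError, match="ppv"):
            binary_metrics(ConfusionTable(tp=0, fp=0, tn=5, fn=5))

    def test_ci_contains_point(self, resected):
        for dialect in ("wilson", "wald_cc"):
            for est in binary_metrics(confusion_table(resected, "rna_call"), dialect).values():
                assert est.ci_low <= est.point <= est.ci_high
                assert est.ci_method == dialect


class TestIntervals:
    def test_wilson_frozen_value(self):
        lo, hi = wilson_ci(6, 15, 0.95)
        assert (round(lo, 4), round(hi, 4)) == (0.1982, 0.6425)

    def test_wilson_boundaries(self):
        lo, _ = wilson_ci(0, 20, 0.95)
        assert lo == 0.0
        _, hi = wilson_ci(20, 20, 0.95)
        assert hi == 1.0

    def test_wilson_symmetry(self):
        lo, hi = wilson_ci(10, 20, 0.95)
        assert lo == pytest.approx(1 - hi)

    def test_wilson_matches_direct_formula(self):
        z = sps.norm.ppf(0.975)
        for k, n in [(3, 11), (40, 43), (6, 9), (1, 50)]:
            p = k / n
            denom = 1 + z**2 / n
            centre = (p + z**2 / (2 * n)) / denom
            half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
            lo, hi = wilson_ci(k, n)
            assert lo == pytest.approx(centre - half, abs=1e-12)
            assert hi == pytest.approx(centre + half, abs=1e-12)

    def test_wilson_contains_point_and_narrows_with_n(self):
        widths = []
        for n in (10, 40, 160, 640):
            k = int(0.3 * n)
            lo, hi = wilson_ci(k, n)
            assert lo <= k / n <= hi
            widths.append(hi - lo)
        assert widths == sorted(widths, reverse=True)

    def test_wald_cc_frozen_value(self):
        lo, hi = wald_cc_ci(6, 15, 0.95)
        assert (round(lo, 3), round(hi, 3)) == (0.119, 0.681)

    def test_wald_cc_clipping(self):
        assert wald_cc_ci(0, 12)[0] == 0.0
        assert wald_cc_ci(15, 15)[1] == 1.0

    def test_n_zero_rejected(self):
        with pytest.raises(UndefinedMetricError):
            wilson_ci(0, 0)
        with pytest.raises(UndefinedMetricError):
            wald_cc_ci(0, 0)


class TestRom:
    def test_policy_values(self, resected):
        assert rom(resected, "as_malignant").point == pytest.approx(43 / 58)
        assert rom(resected, "as_benign").point == pytest.approx(33 / 58)

    def test_all_benign_cohort(self):
        frame = pd.DataFrame(
            {"histology": ["hyperplasia"] * 4, "resected": [True] * 4}
        )
        assert rom(frame).point == 0.0

    def test_empty_raises(self):
        with pytest.raises(UndefinedMetricError):
            rom(pd.DataFrame(columns=["histology", "resected"]))


class TestResectionRates:
    def test_reference_rates(self, full_cohort):
        pos, neg, cmp = resection_rates(full_cohort, "rna_call")
        assert (pos.numerator, pos.denominator) == (49, 114)
        assert (neg.numerator, neg.denominator) == (9, 26)
        assert round(pos.point, 3) == 0.430
        assert round(neg.point, 3) == 0.346
        assert cmp.p_value > 0.05  # management was blind to the test

    def test_dna_rna_rates(self, full_cohort):
        pos, neg, _ = resection_rates(full_cohort, "gc_call")
        assert (pos.numerator, pos.denominator) == (46, 106)
        assert (neg.numerator, neg.denominator) == (12, 34)
        assert round(pos.point, 3) == 0.434
        assert round(neg.point, 3) == 0.353

    def test_equal_rates_give_zero_statistic(self):
        frame = pd.DataFrame(
            {
                "resected": [True, False] * 10,
                "gc_call": (["positive"] * 10 + ["negative"] * 10),
            }
        )
        _, _, cmp = resection_rates(frame, "gc_call")
        assert cmp.chi2_stat == pytest.approx(0.0)
        assert cmp.p_value == pytest.approx(1.0)


def _pearson_oracle(a, b, c, d):
    """Independent brute-force Σ(O−E)²/E."""
    obs = np.array([[a, b], [c, d]], float)
    n = obs.sum()
    stat = 0.0
    for i in range(2):
        for j in range(2):
            e = obs[i].sum() * obs[:, j].sum() / n
            stat += (obs[i, j] - e) ** 2 / e
    return stat


class TestChi2:
    def test_reference_comparisons(self):
        r = chi2_2x2(38, 7, 31, 18)
        assert r.chi2_stat == pytest.approx(5.390, abs=1e-3)
        assert r.p_value == pytest.approx(0.020, abs=1e-3)
        r2 = chi2_2x2(40, 9, 46, 77)
        assert r2.chi2_stat == pytest.approx(27.43, abs=0.01)

    def test_uniform_table(self):
        r = chi2_2x2(1, 1, 1, 1)
        assert r.chi2_stat == 0.0 and r.p_value == 1.0

    def test_matches_oracle_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            a, b, c, d = rng.integers(1, 200, size=4)
            r = chi2_2x2(int(a), int(b), int(c), int(d))
            assert r.chi2_stat == pytest.approx(_pearson_oracle(a, b, c, d), rel=1e-10)
            assert r.p_value == pytest.approx(sps.chi2.sf(r.chi2_stat, 1), rel=1e-10)

    def test_yates_reduces_statistic(self):
        plain = chi2_2x2(12, 5, 6, 14).chi2_stat
        yates = chi2_2x2(12, 5, 6, 14, correction="yates").chi2_stat
        assert yates < plain

    def test_empty_margin_rejected(self):
        with pytest.raises(DomainError):
            chi2_2x2(0, 0, 5, 5)

    def test_compare_proportions_wrapper(self):
        r = compare_proportions(38, 45, 31, 49)
        assert r.table == ((38, 7), (31, 18))


class TestAuc:
    def test_perfect_separation(self):
        assert auc_mann_whitney([0.9, 0.8, 0.7, 0.4], [1, 1, 0, 0]) == 1.0

    def test_pair_enumeration_example(self):
        assert auc_mann_whitney([0.8, 0.3, 0.5, 0.2], [1, 1, 0, 0]) == 0.75

    def test_all_ties(self):
        assert auc_mann_whitney([1.0] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(DomainError):
            auc_mann_whitney([0.1, 0.2], [1, 1])

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(2, 51))
            scores = np.round(rng.random(n), 1)  # coarse grid forces ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            wins = sum(
                1.0 if p > q else 0.5 if p == q else 0.0
                for p, q in itertools.product(pos, neg)
            )
            assert auc_mann_whitney(scores, labels) == pytest.approx(
                wins / (len(pos) * len(neg)), abs=1e-12
            )

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(13)
        scores = rng.random(200)
        labels = rng.integers(0, 2, size=200)
        assert auc_mann_whitney(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )


class TestAlterationSummaries:
    def test_reference_fractions(self, resected):
        s = alteration_summaries(resected)
        hr = s["high_risk_malignant_fraction"]
        assert (hr.numerator, hr.denominator) == (13, 33)
        ras = s["ras_alone_neoplasia_fraction"]
        assert (ras.numerator, ras.denominator) == (8, 10)

    def test_double_mutant_counted_once(self, resected):
        # the anaplastic nodule carries both TERT and BRAF V600E yet adds 1
        s = alteration_summaries(resected)
        assert s["high_risk_malignant_fraction"].numerator == 13

    def test_ras_like_widening_adds_k601e_carriers(self, resected):
        wide = alteration_summaries(resected, ras_genes_only=False)
        assert wide["ras_alone_neoplasia_fraction"].denominator == 12

    def test_no_high_risk_cohort(self):
        frame = pd.DataFrame(
            {
                "histology": ["PTC_classic", "PTC_classic", "hyperplasia"],
                "resected": [True] * 3,
                "alterations": ["NRAS", "", "NRAS"],
            }
        )
        s = alteration_summaries(frame)
        assert s["high_risk_malignant_fraction"].point == 0.0

    def test_empty_stratum_raises(self):
        frame = pd.DataFrame(
            {"histology": ["hyperplasia"], "resected": [True], "alterations": [""]}
        )
        with pytest.raises(UndefinedMetricError):
            alteration_summaries(frame)
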