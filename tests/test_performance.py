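"""Operating-point CIs, paired tests, DeLong machinery, agreement statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from nodulegrowth import (
    ConfusionCounts,
    bland_altman,
    cohens_kappa,
    delong_auc_ci,
    delong_paired_test,
    empirical_roc,
    icc_absolute_agreement,
    mcnemar_test,
    percent_agreement,
    proportion_ci,
    sensitivity_specificity,
)
from nodulegrowth.errors import (
    DegenerateLabelsError,
    InsufficientDataError,
    UndefinedProportionError,
)


def pairwise_auc(scores, labels):
    """Brute-force Mann-Whitney AUC over all (positive, negative) pairs."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestProportionCI:
    def test_point_estimate_and_counts(self):
        est = proportion_ci(18, 26)
        assert est.value == pytest.approx(100 * 18 / 26)
        assert (est.numerator, est.denominator) == (18, 26)
        assert est.method == "wald_clipped"

    def test_clipping_at_bounds(self):
        est = proportion_ci(1, 26)
        assert est.ci_low == 0.0
        est = proportion_ci(86, 89)
        assert est.ci_high == 100.0

    def test_degenerate_counts_use_clopper_pearson(self):
        for k, n in [(0, 26), (89, 89)]:
            assert proportion_ci(k, n).method == "clopper_pearson"

    def test_pure_methods_selectable(self):
        cp = proportion_ci(18, 26, method="clopper_pearson")
        assert cp.method == "clopper_pearson"
        # exact interval is wider than Wald here
        wald = proportion_ci(18, 26, method="wald_clipped")
        assert cp.ci_low < wald.ci_low

    @settings(deadline=None, derandomize=True)
    @given(k=st.integers(min_value=0, max_value=200), n=st.integers(min_value=1, max_value=200))
    def test_ci_ordering_invariant(self, k, n):
        k = min(k, n)
        est = proportion_ci(k, n)
        assert 0.0 <= est.ci_low <= est.value <= est.ci_high <= 100.0

    def test_zero_denominator(self):
        with pytest.raises(UndefinedProportionError):
            proportion_ci(0, 0)


class TestSensitivitySpecificity:
    @pytest.mark.parametrize(
        "counts, sens, spec",
        [
            (ConfusionCounts(tp=16, fn=10, tn=78, fp=11), 61.5, 87.6),
            (ConfusionCounts(tp=18, fn=8, tn=73, fp=16), 69.2, 82.0),
        ],
    )
    def test_published_operating_points(self, counts, sens, spec):
        s, p = sensitivity_specificity(counts)
        assert s.value == pytest.approx(sens, abs=0.1)
        assert p.value == pytest.approx(spec, abs=0.1)

    def test_all_negative_classifier(self):
        s, p = sensitivity_specificity(ConfusionCounts(tp=0, fn=5, tn=10, fp=0))
        assert s.value == 0.0 and p.value == 100.0

    def test_zero_denominators_named(self):
        with pytest.raises(UndefinedProportionError, match="sensitivity"):
            sensitivity_specificity(ConfusionCounts(tp=0, fn=0, tn=5, fp=0))
        with pytest.raises(UndefinedProportionError, match="specificity"):
            sensitivity_specificity(ConfusionCounts(tp=5, fn=0, tn=0, fp=0))


class TestMcNemar:
    def test_identical_vectors(self):
        a = [True, False, True, False]
        assert mcnemar_test(a, a).p_value == 1.0

    def test_hand_enumerated_exact_p(self):
        # discordants 2 vs 8: p = 2 * sum_{k<=2} C(10,k) / 2^10 = 0.109375
        a = [True] * 2 + [False] * 8 + [True] * 5
        b = [False] * 2 + [True] * 8 + [True] * 5
        assert mcnemar_test(a, b).p_value == pytest.approx(0.109375, abs=1e-12)

    def test_swap_invariance(self):
        rng = np.random.default_rng(7)
        a = rng.random(60) < 0.5
        b = rng.random(60) < 0.5
        assert mcnemar_test(a, b).p_value == mcnemar_test(b, a).p_value

    def test_concordant_cells_irrelevant(self):
        a = [True, False, True, True, False, False]
        b = [False, True, True, True, False, False]
        a2, b2 = a[:2] + [True] * 10, b[:2] + [True] * 10
        assert mcnemar_test(a, b).p_value == mcnemar_test(a2, b2).p_value

    def test_matches_statsmodels_exact(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        rng = np.random.default_rng(11)
        for _ in range(10):
            a = rng.random(40) < 0.4
            b = rng.random(40) < 0.6
            table = [
                [np.sum(a & b), np.sum(a & ~b)],
                [np.sum(~a & b), np.sum(~a & ~b)],
            ]
            expected = sm_mcnemar(table, exact=True).pvalue
            assert mcnemar_test(a, b).p_value == pytest.approx(expected, abs=1e-12)

    def test_continuity_corrected_variant(self):
        a = [True] * 2 + [False] * 8
        b = [False] * 2 + [True] * 8
        res = mcnemar_test(a, b, method="cc")
        assert res.method == "mcnemar_cc"
        assert res.statistic == pytest.approx((abs(2 - 8) - 1) ** 2 / 10)


class TestROC:
    def test_perfect_separation(self):
        res = empirical_roc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == pytest.approx(1.0)

    def test_small_derived_example(self):
        # cancers {3, 1}, benign {2, 0}: 3 of 4 pairs correctly ordered
        res = empirical_roc([3, 1, 2, 0], [1, 1, 0, 0])
        assert res.auc == pytest.approx(0.75)

    def test_all_ties(self):
        res = empirical_roc([5.0] * 8, [1, 0, 1, 0, 1, 0, 1, 0])
        assert res.auc == pytest.approx(0.5)

    def test_degenerate_labels(self):
        with pytest.raises(DegenerateLabelsError):
            empirical_roc([1, 2, 3], [1, 1, 1])

    @settings(deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_auc_equals_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 50))
        labels = np.zeros(n, dtype=bool)
        labels[: max(2, n // 3)] = True
        rng.shuffle(labels)
        scores = np.round(rng.normal(labels * 1.0, 1.0), 1)  # rounding forces ties
        auc, lo, hi = delong_auc_ci(scores, labels)
        assert auc == pytest.approx(pairwise_auc(scores, labels), abs=1e-12)
        assert empirical_roc(scores, labels).auc == pytest.approx(auc, abs=1e-12)
        assert 0.0 <= lo <= auc <= hi <= 1.0


class TestDeLong:
    def test_perfect_separation_zero_variance(self):
        labels = [1, 1, 0, 0]
        auc, lo, hi = delong_auc_ci([10, 9, 1, 2], labels)
        assert (auc, lo, hi) == (1.0, 1.0, 1.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        labels = rng.random(40) < 0.4
        labels[:2], labels[-2:] = True, False
        scores = rng.normal(size=40)
        a1, _, _ = delong_auc_ci(scores, labels)
        a2, _, _ = delong_auc_ci(np.exp(scores), labels)
        assert a1 == pytest.approx(a2, abs=1e-15)

    def test_insufficient_class_sizes(self):
        with pytest.raises(InsufficientDataError):
            delong_auc_ci([1, 2, 3], [1, 0, 0])

    def test_identical_scores_give_p_one(self):
        rng = np.random.default_rng(5)
        labels = rng.random(30) < 0.5
        labels[:2], labels[-2:] = True, False
        s = rng.normal(size=30)
        assert delong_paired_test(s, s, labels).p_value == 1.0

    def test_swap_negates_z_preserves_p(self):
        rng = np.random.default_rng(6)
        labels = rng.random(40) < 0.4
        labels[:2], labels[-2:] = True, False
        sa = rng.normal(labels * 1.0, 1.0)
        sb = rng.normal(labels * 0.5, 1.0)
        r1 = delong_paired_test(sa, sb, labels)
        r2 = delong_paired_test(sb, sa, labels)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)


class TestKappa:
    def test_identical_with_both_classes(self):
        a = [True, False, True, False, True]
        res = cohens_kappa(a, a)
        assert res.kappa == pytest.approx(1.0)

    def test_hand_worked_table(self):
        # table [[40, 5], [10, 45]]: p_o = 0.85, p_e = 0.50, kappa = 0.70
        a = [False] * 45 + [True] * 55
        b = [False] * 40 + [True] * 5 + [False] * 10 + [True] * 45
        res = cohens_kappa(a, b)
        assert res.kappa == pytest.approx(0.70, abs=1e-12)
        assert -1.0 <= res.ci_low <= res.kappa <= res.ci_high <= 1.0

    def test_chance_agreement(self):
        a = [False] * 50 + [True] * 50
        b = ([False] * 25 + [True] * 25) * 2
        assert cohens_kappa(a, b).kappa == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_sentinel(self):
        res = cohens_kappa([True] * 5, [True] * 5)
        assert res.degenerate and res.kappa == 1.0

    def test_matches_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(13)
        a = rng.random(200) < 0.4
        b = (a ^ (rng.random(200) < 0.2))
        assert cohens_kappa(a, b).kappa == pytest.approx(
            cohen_kappa_score(a, b), abs=1e-12
        )

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(17)
        a = rng.random(100) < 0.5
        b = rng.random(100) < 0.5
        assert cohens_kappa(a, b).kappa == pytest.approx(
            cohens_kappa(~a, ~b).kappa, abs=1e-12
        )


class TestPercentAgreement:
    def test_bounds(self):
        a = [True, False, True]
        assert percent_agreement(a, a) == 100.0
        assert percent_agreement(a, [not x for x in a]) == 0.0

    def test_published_growth_agreement(self):
        # 103 concordant growth calls of 115 -> 89.6%
        a = [True] * 103 + [True] * 12
        b = [True] * 103 + [False] * 12
        assert percent_agreement(a, b) == pytest.approx(89.6, abs=0.05)


class TestICC:
    def test_duplicated_column(self):
        x = np.array([[1.0, 1.0], [2.0, 2.0], [5.0, 5.0], [9.0, 9.0]])
        assert icc_absolute_agreement(x).icc == pytest.approx(1.0)

    def test_constant_offset_penalized(self):
        a = np.array([1.0, 2.0, 5.0, 9.0, 12.0])
        x = np.column_stack([a, a + 10.0])
        assert icc_absolute_agreement(x).icc < 1.0

    def test_matches_pingouin_icc2(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(23)
        subj = rng.normal(0, 2, size=12)
        x = np.column_stack([subj + rng.normal(0, 1, 12), subj + 0.5 + rng.normal(0, 1, 12)])
        res = icc_absolute_agreement(x)
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 2),
                "rater": np.tile(["a", "b"], 12),
                "score": x.ravel(),
            }
        )
        ping = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
        ci_col = "CI95%" if "CI95%" in ping.columns else "CI95"
        row = ping[ping["Type"].isin(["ICC2", "ICC(A,1)"])].iloc[0]
        assert res.icc == pytest.approx(row["ICC"], abs=1e-9)
        # pingouin prints CI bounds rounded to 2 decimals
        assert res.ci_low == pytest.approx(row[ci_col][0], abs=5.1e-3)
        assert res.ci_high == pytest.approx(row[ci_col][1], abs=5.1e-3)

    def test_shift_invariance(self):
        rng = np.random.default_rng(29)
        x = rng.normal(size=(10, 2))
        r1 = icc_absolute_agreement(x)
        r2 = icc_absolute_agreement(x + 100.0)
        assert r1.icc == pytest.approx(r2.icc, abs=1e-9)

    def test_degenerate_between_subject_variance(self):
        x = np.ones((5, 2))
        assert icc_absolute_agreement(x).degenerate

    def test_too_few_subjects(self):
        with pytest.raises(InsufficientDataError):
            icc_absolute_agreement(np.ones((2, 2)))


class TestBlandAltman:
    def test_identical_pairs(self):
        res = bland_altman([(1.0, 1.0), (2.0, 2.0), (3.0, 3.0)])
        assert (res.mean_diff, res.loa_low, res.loa_high) == (0.0, 0.0, 0.0)

    def test_derived_loa(self):
        # diffs {1, -1, 1, -1}: SD = sqrt(4/3), LoA = +-1.96*SD = +-2.263
        pairs = [(1.0, 0.0), (-1.0, 0.0), (1.0, 0.0), (-1.0, 0.0)]
        res = bland_altman(pairs)
        assert res.mean_diff == pytest.approx(0.0)
        assert res.loa_high == pytest.approx(1.96 * np.sqrt(4.0 / 3.0), abs=1e-12)
        assert res.loa_high == pytest.approx(2.263, abs=5e-4)

    def test_zero_spread(self):
        res = bland_altman([(3.0, 1.0)] * 4)
        assert (res.mean_diff, res.loa_low, res.loa_high) == (2.0, 2.0, 2.0)

    def test_shift_invariance(self):
        pairs = np.array([(1.0, 0.5), (2.0, 2.5), (4.0, 3.0)])
        r1 = bland_altman(pairs)
        r2 = bland_altman(pairs + 7.0)
        assert r1.mean_diff == pytest.approx(r2.mean_diff)
        assert r1.loa_low == pytest.approx(r2.loa_low)

    def test_insufficient_pairs(self):
        with pytest.raises(InsufficientDataError):
            bland_altman([(1.0, 2.0)])


class TestCIBoundsAlwaysInParameterSpace:
    def test_kappa_ci_clipped(self):
        a = [True] * 9 + [False]
        b = [True] * 9 + [False]
        res = cohens_kappa(a, b)
        assert res.ci_high <= 1.0

    def test_delong_ci_clipped(self):
        labels = [1, 1, 1, 0, 0, 0]
        _, lo, hi = delong_auc_ci([3, 2, 1.5, 1.6, 1, 0], labels)
        assert 0.0 <= lo and hi <= 1.0
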