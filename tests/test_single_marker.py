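"""Per-marker statistics: coding, exact HWE, heterogeneity, logistic fits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import snpburden as sb
from snpburden.cohort import CohortError
from snpburden.single_marker import AssocResult, InheritanceModel

DOM = InheritanceModel.DOMINANT
REC = InheritanceModel.RECESSIVE


def brute_force_hwe(hom_a, het, hom_b):
    """Exact-integer enumeration oracle for the conditional HWE test."""
    n = hom_a + het + hom_b
    na, nb = 2 * hom_a + het, 2 * hom_b + het
    weights = {}
    for h in range(na % 2, min(na, nb) + 1, 2):
        a, b = (na - h) // 2, (nb - h) // 2
        weights[h] = (
            math.factorial(n)
            * 2**h
            // (math.factorial(a) * math.factorial(h) * math.factorial(b))
        )
    total = sum(weights.values())
    w_obs = weights[het]
    return sum(w for w in weights.values() if w <= w_obs) / total


class TestRiskGenotypeCoding:
    marker = sb.MarkerDef("rsX", "A", "C", "C")

    @pytest.mark.parametrize(
        "genotype,model,expected",
        [
            ("AC", DOM, 1), ("AC", REC, 0),
            ("CC", DOM, 1), ("CC", REC, 1),
            ("AA", DOM, 0), ("AA", REC, 0),
            ("CA", DOM, 1),  # unordered
            (None, DOM, None),
        ],
    )
    def test_coding_rules(self, genotype, model, expected):
        assert sb.code_risk_genotype(genotype, self.marker, model) == expected

    def test_foreign_allele_is_an_error(self):
        with pytest.raises(CohortError):
            sb.code_risk_genotype("AG", self.marker, DOM)

    def test_fixture_lithuanian_carrier_counts(self, fixture_counts):
        # dominant carriers = het + hom-risk classes of the count table
        _, het, hom = fixture_counts.counts("Lithuania", 1, "rs3802842")
        assert het + hom == 73
        _, het, hom = fixture_counts.counts("Lithuania", 0, "rs3802842")
        assert het + hom == 53


class TestHWEExact:
    def test_lithuanian_cases_deviation(self):
        # TT/TC/CC = 58/45/20 among Lithuanian cases at rs4464148
        assert sb.hwe_exact_test((58, 45, 20)).p_exact == pytest.approx(0.045, abs=0.0005)

    def test_perfect_hwe_proportions(self):
        assert sb.hwe_exact_test((25, 50, 25)).p_exact == 1.0

    def test_monomorphic_marker_warns_p_one(self, caplog):
        r = sb.hwe_exact_test((10, 0, 0), "rsX")
        assert r.p_exact == 1.0

    def test_small_triple_matches_enumeration(self):
        assert sb.hwe_exact_test((4, 2, 4)).p_exact == pytest.approx(
            brute_force_hwe(4, 2, 4), rel=1e-9
        )

    def test_exhaustive_agreement_up_to_total_50(self):
        for n in range(1, 51):
            for hom_a in range(n + 1):
                for het in range(n - hom_a + 1):
                    hom_b = n - hom_a - het
                    expected = brute_force_hwe(hom_a, het, hom_b)
                    got = sb.hwe_exact_test((hom_a, het, hom_b)).p_exact
                    assert got == pytest.approx(expected, rel=1e-9, abs=1e-12), (
                        hom_a, het, hom_b,
                    )

    def test_large_stratum_stays_finite(self):
        # log-space arithmetic must survive study-sized strata
        r = sb.hwe_exact_test((408, 330, 57))
        assert 0.0 < r.p_exact <= 1.0


class TestHeterogeneity:
    def test_identical_populations_give_zero(self, toy_panel):
        import pandas as pd

        rows = []
        for pop in ("X", "Y"):
            for geno, cnt in (("AA", 5), ("AC", 3), ("CC", 2)):
                rows.append({"population": pop, "status": 0, "marker": "rsA",
                             "genotype": geno, "count": cnt})
        counts = sb.CountTable([toy_panel[0]], pd.DataFrame(rows))
        chi2, df, p = sb.heterogeneity_chisq(counts, 0)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_toy_table_matches_hand_computation(self, toy_panel):
        import pandas as pd

        # 3x2 table: X=(10,20,30), Y=(30,20,10)
        rows = []
        for pop, cnts in (("X", (10, 20, 30)), ("Y", (30, 20, 10))):
            for geno, cnt in zip(("AA", "AC", "CC"), cnts):
                rows.append({"population": pop, "status": 1, "marker": "rsA",
                             "genotype": geno, "count": cnt})
        counts = sb.CountTable([toy_panel[0]], pd.DataFrame(rows))
        chi2, df, p = sb.heterogeneity_chisq(counts, 1)
        # expected counts are 20 everywhere; chi2 = sum (O-E)^2/E
        expected = sum((o - 20) ** 2 / 20 for o in (10, 20, 30, 30, 20, 10))
        assert chi2 == pytest.approx(expected)
        assert df == 2

    def test_full_panel_four_countries_df(self, fixture_counts):
        for status in (0, 1):
            _, df, _ = sb.heterogeneity_chisq(fixture_counts, status)
            assert df == 51

    def test_p_monotone_in_chi2(self, fixture_counts):
        chi2_all, df, p_all = sb.heterogeneity_chisq(fixture_counts, 0)
        assert p_all == pytest.approx(stats.chi2.sf(chi2_all, df))


class TestUnconditionalFit:
    def test_or_equals_cross_product(self):
        # Lithuanian rs3802842 dominant carrier table from the study counts
        status = np.r_[np.ones(123), np.zeros(123)]
        g = np.r_[np.ones(73), np.zeros(50), np.ones(53), np.zeros(70)]
        res = sb.fit_unconditional(status, g)
        assert res.or_hat == pytest.approx((73 * 70) / (50 * 53), rel=1e-6)
        assert res.p_nominal == pytest.approx(0.011, abs=0.0005)

    def test_balanced_table_is_null(self):
        status = np.r_[np.ones(20), np.zeros(20)]
        g = np.r_[np.ones(10), np.zeros(10), np.ones(10), np.zeros(10)]
        res = sb.fit_unconditional(status, g)
        assert res.or_hat == pytest.approx(1.0, rel=1e-9)
        assert res.p_nominal == pytest.approx(1.0, rel=1e-9)

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(0)
        status = rng.integers(0, 2, 200)
        g = rng.integers(0, 2, 200)
        res = sb.fit_unconditional(status, g)
        assert res.ci_low <= res.or_hat <= res.ci_high

    def test_zero_cell_uses_continuity_and_flags(self):
        status = np.r_[np.ones(10), np.zeros(10)]
        g = np.r_[np.ones(10), np.zeros(10)]  # perfect separation
        res = sb.fit_unconditional(status, g)
        assert "separation" in res.flags
        assert math.isfinite(res.or_hat)
        # Haldane-Anscombe on (10,0,0,10) -> (10.5*10.5)/(0.5*0.5)
        assert res.or_hat == pytest.approx(441.0, rel=1e-9)

    def test_integer_covariate_supported(self):
        rng = np.random.default_rng(1)
        k = rng.integers(0, 5, 400)
        eta = 0.4 * k - 0.8
        status = (rng.random(400) < 1 / (1 + np.exp(-eta))).astype(float)
        res = sb.fit_unconditional(status, k)
        assert 1.0 < res.or_hat < 2.5


class TestConditionalPairs:
    def test_binary_reduces_to_discordant_ratio(self):
        g_case = np.r_[np.ones(20), np.zeros(10), np.ones(7), np.zeros(5)]
        g_control = np.r_[np.zeros(20), np.ones(10), np.ones(7), np.zeros(5)]
        res = sb.fit_conditional_pairs(g_case, g_control)
        assert res.or_hat == pytest.approx(2.0, rel=1e-6)
        assert res.n_effective == 30  # concordant pairs are uninformative

    def test_symmetric_discordance_is_null(self):
        g_case = np.r_[np.ones(15), np.zeros(15)]
        g_control = np.r_[np.zeros(15), np.ones(15)]
        res = sb.fit_conditional_pairs(g_case, g_control)
        assert res.or_hat == pytest.approx(1.0, rel=1e-9)

    def test_no_discordant_pairs_is_undefined(self):
        res = sb.fit_conditional_pairs(np.ones(5), np.ones(5))
        assert not res.defined
        assert "no_discordant_pairs" in res.flags

    def test_zero_discordant_cell_continuity(self):
        res = sb.fit_conditional_pairs(np.ones(8), np.zeros(8))
        assert "separation" in res.flags
        assert res.or_hat == pytest.approx(8.5 / 0.5, rel=1e-9)

    def test_integer_covariate_is_local_maximum(self):
        # 3 hand-built pairs with integer burden differences
        g_case, g_control = np.array([3.0, 1.0, 2.0]), np.array([1.0, 2.0, 2.0])
        res = sb.fit_conditional_pairs(g_case, g_control)
        d = (g_case - g_control)[g_case != g_control]

        def loglik(beta):
            return float(-np.logaddexp(0, -beta * d).sum())

        bhat = math.log(res.or_hat)
        assert loglik(bhat) >= loglik(bhat + 0.1)
        assert loglik(bhat) >= loglik(bhat - 0.1)

    def test_matches_statsmodels_conditional_logit(self):
        from statsmodels.discrete.conditional_models import ConditionalLogit

        rng = np.random.default_rng(4)
        g_case = rng.integers(0, 4, 120).astype(float)
        g_control = rng.integers(0, 4, 120).astype(float)
        res = sb.fit_conditional_pairs(g_case, g_control)
        y = np.tile([1, 0], 120)
        x = np.column_stack([np.ravel(np.column_stack([g_case, g_control]))]).astype(float)
        groups = np.repeat(np.arange(120), 2)
        ref = ConditionalLogit(y, x, groups=groups).fit(disp=0)
        assert math.log(res.or_hat) == pytest.approx(float(ref.params[0]), abs=1e-4)


class TestBonferroniAndSelection:
    @pytest.mark.parametrize("p,m,expected", [(0.011, 2, 0.022), (0.9, 2, 1.0),
                                              (0.0017, 2, 0.0034), (0.5, 1, 0.5)])
    def test_bonferroni_values(self, p, m, expected):
        assert sb.bonferroni(p, m) == pytest.approx(expected)

    @given(p=st.floats(0, 1), m=st.integers(1, 100))
    @settings(derandomize=True, max_examples=200)
    def test_bonferroni_monotone_and_capped(self, p, m):
        corrected = sb.bonferroni(p, m)
        assert 0 <= corrected <= 1
        assert corrected >= sb.bonferroni(p, max(1, m - 1)) - 1e-15
        if p < 1:
            assert corrected >= p

    def _result(self, p, or_hat, model):
        return AssocResult("rsX", "Pop", model, "unconditional",
                           or_hat, or_hat / 2, or_hat * 2, p, p, 100)

    def test_lowest_p_wins(self):
        dom = self._result(0.2, 1.5, DOM)
        rec = self._result(0.05, 1.2, REC)
        assert sb.select_model(dom, rec).model is REC

    def test_tie_broken_by_larger_or(self):
        dom = self._result(0.1, 1.5, DOM)
        rec = self._result(0.1, 1.2, REC)
        assert sb.select_model(dom, rec).model is DOM

    def test_max_or_criterion(self):
        dom = self._result(0.05, 1.2, DOM)
        rec = self._result(0.2, 1.8, REC)
        assert sb.select_model(dom, rec, criterion="max_or").model is REC

    def test_both_degenerate_is_an_error(self):
        bad = AssocResult("rsX", "Pop", DOM, "unconditional",
                          math.nan, math.nan, math.nan, math.nan, math.nan, 0)
        with pytest.raises(CohortError):
            sb.select_model(bad, bad)

    def test_fixture_rs4779584_dominant_under_max_risk(self, fixture_cohort):
        # the published study chose dominant for rs4779584 in every country;
        # reproducible from the count margins under the max-risk criterion
        # for the unmatched populations (matched ones depend on pairing)
        for pop in ("Latvia", "Lithuania"):
            sel = sb.analyze_population(fixture_cohort, pop, criterion="max_or")
            assert sel["rs4779584"].model is DOM
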