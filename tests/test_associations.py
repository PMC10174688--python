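"""Clinical-association statistics against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fcbrainage.associations import (
    ClinicalTable,
    chi_square_gof,
    delta,
    fdr_bh,
    hippocampal_occupancy,
    independent_ttest,
    kendall_test,
    pearson_test,
    percent_change,
    residualize,
    run_association_suite,
)

from oracles import (
    bh_qvalues_bruteforce,
    bh_stepup_bruteforce,
    kendall_tau_b_bruteforce,
    pooled_ttest_bruteforce,
)


class TestDeltaAndPercentChange:
    def test_delta_sign_convention(self):
        assert delta(30.1, 29.3) == pytest.approx(0.8)
        assert delta(5.0, 5.0) == 0.0

    def test_percent_change_sign_convention(self):
        assert percent_change(100.0, 95.0) == pytest.approx(-5.0)
        assert percent_change(88.0, 88.0) == 0.0
        with pytest.raises(ValueError):
            percent_change(0.0, 5.0)

    def test_loss_gives_positive_delta_and_negative_percent(self, rng):
        t0 = rng.uniform(80, 120, 50)
        t18 = t0 * (1 - rng.uniform(0.01, 0.1, 50))  # everyone loses
        assert np.all(delta(t0, t18) > 0)
        assert np.all(percent_change(t0, t18) < 0)


class TestPearson:
    def test_exact_linear(self):
        out = pearson_test([1, 2, 3], [3, 5, 7])
        assert out["r"] == pytest.approx(1.0)

    def test_hand_computed_r(self):
        out = pearson_test([1, 2, 3, 4], [2, 1, 4, 3])
        assert out["r"] == pytest.approx(0.6)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            pearson_test([1, 2], [3, 4])


class TestKendall:
    def test_identical_and_reversed(self):
        assert kendall_test([1, 2, 3, 4], [1, 2, 3, 4])["tau"] == 1.0
        assert kendall_test([1, 2, 3, 4], [4, 3, 2, 1])["tau"] == -1.0

    def test_tied_example_matches_pair_counting(self):
        x, y = [1, 1, 2, 3], [1, 2, 2, 3]
        out = kendall_test(x, y)
        assert out["tau"] == pytest.approx(kendall_tau_b_bruteforce(x, y))

    @settings(deadline=None, derandomize=True, max_examples=150)
    @given(
        xy=st.lists(
            st.tuples(st.integers(0, 4), st.integers(0, 4)),
            min_size=3, max_size=8,
        )
    )
    def test_tau_b_equals_exhaustive_counting(self, xy):
        x = [a for a, _ in xy]
        y = [b for _, b in xy]
        if len(set(x)) < 2 or len(set(y)) < 2:
            return
        out = kendall_test(x, y)
        assert out["tau"] == pytest.approx(
            kendall_tau_b_bruteforce(x, y), abs=1e-12
        )

    def test_all_tied_rejected(self):
        with pytest.raises(ValueError):
            kendall_test([1, 1, 1], [1, 2, 3])


class TestTTest:
    def test_identical_groups(self):
        out = independent_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out["t"] == pytest.approx(0.0)
        assert out["p"] == pytest.approx(1.0)

    def test_closed_form_oracle(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        out = independent_ttest(a, b)
        assert out["t"] == pytest.approx(pooled_ttest_bruteforce(a, b))

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError):
            independent_ttest([1.0], [2.0, 3.0])


class TestResidualize:
    def test_exact_linear_combination_vanishes(self, rng):
        C = rng.normal(size=(30, 2))
        y = 2.0 + C @ np.array([1.5, -0.7])
        np.testing.assert_allclose(residualize(y, C), 0.0, atol=1e-10)

    def test_orthogonality_to_every_covariate(self, rng):
        C = rng.normal(size=(40, 3))
        y = rng.normal(size=40)
        res = residualize(y, C)
        for j in range(3):
            assert abs(np.corrcoef(res, C[:, j])[0, 1]) < 1e-10

    def test_rank_deficient_design_rejected(self, rng):
        c = rng.normal(size=30)
        with pytest.raises(ValueError):
            residualize(rng.normal(size=30), np.column_stack([c, 2 * c]))


class TestFdrBH:
    def test_worked_example(self):
        out = fdr_bh([0.01, 0.02, 0.04, 0.5])
        np.testing.assert_allclose(out["q"], [0.04, 0.04, 0.4 / 7.5, 0.5])
        # q for the third test is 0.0533 > alpha, so only two rejections
        np.testing.assert_array_equal(out["reject"],
                                      [True, True, False, False])

    def test_degenerate_families(self):
        out = fdr_bh([1.0, 1.0, 1.0])
        assert not out["reject"].any()
        np.testing.assert_allclose(out["q"], 1.0)
        single = fdr_bh([0.03])
        assert single["q"][0] == pytest.approx(0.03)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        p=st.lists(st.floats(1e-6, 1.0, allow_nan=False), min_size=1,
                   max_size=10),
        alpha=st.sampled_from([0.01, 0.05, 0.1, 0.25]),
    )
    def test_matches_bruteforce_stepup(self, p, alpha):
        out = fdr_bh(p, alpha=alpha)
        np.testing.assert_array_equal(
            out["reject"], bh_stepup_bruteforce(p, alpha)
        )
        np.testing.assert_allclose(out["q"], bh_qvalues_bruteforce(p),
                                   atol=1e-12)

    def test_q_monotone_in_p(self, rng):
        p = rng.uniform(1e-4, 1, 10)
        q = fdr_bh(p)["q"]
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.0, 0.5])
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.2])


class TestChiSquare:
    def test_expected_vs_observed_split(self):
        out = chi_square_gof([58, 44])
        assert out["x2"] == pytest.approx(98 / 51)
        assert out["x2"] == pytest.approx(1.922, abs=5e-4)
        assert out["p"] == pytest.approx(0.166, abs=5e-4)

    def test_equal_counts_and_extreme_split(self):
        out = chi_square_gof([25, 25])
        assert out["x2"] == 0.0 and out["p"] == pytest.approx(1.0)
        assert chi_square_gof([10, 0])["x2"] == pytest.approx(10.0)

    def test_zero_expected_rejected(self):
        with pytest.raises(ValueError):
            chi_square_gof([5, 5], [0.0, 10.0])


class TestHippocampalOccupancy:
    def test_worked_values(self):
        assert hippocampal_occupancy(4000, 1000, 4000, 1000) == \
            pytest.approx(0.8)
        assert hippocampal_occupancy(4000, 1000, 3000, 2000) == \
            pytest.approx(0.7)

    def test_boundaries(self):
        assert hippocampal_occupancy(4000, 0, 4000, 0) == 1.0
        with pytest.raises(ValueError):
            hippocampal_occupancy(0, 1000, 4000, 1000)


class TestAssociationSuite:
    def _table(self, rng, n, coupled=True):
        att = rng.normal(0, 1, n)
        noise = rng.normal(0, 1, n)
        cont = (2.0 * att + 0.5 * noise) if coupled else noise
        ordinal = np.digitize(
            (att if coupled else noise) + rng.normal(0, 0.8, n),
            [-0.5, 0.5],
        ) - 1
        binary = ((att if coupled else noise)
                  + rng.normal(0, 1.0, n) > 0).astype(float)
        data = pd.DataFrame({
            "delta_bmi": cont,
            "ffq_processed": ordinal.astype(float),
            "processed_t18_level": binary,
        })
        table = ClinicalTable(
            data=data,
            categories={"delta_bmi": "anthropometry",
                        "ffq_processed": "ffq",
                        "processed_t18_level": "ffq"},
            ordinal=frozenset({"ffq_processed"}),
            binary=frozenset({"processed_t18_level"}),
        )
        return att, table

    def test_coupled_delta_detected_and_ffq_uncorrected(self, rng):
        att, table = self._table(rng, 150, coupled=True)
        results = {r.variable: r for r in run_association_suite(att, table)}
        bmi = results["delta_bmi"]
        assert bmi.stat_type == "pearson_r"
        assert bmi.statistic > 0
        assert bmi.q is not None and bmi.q <= 0.05
        assert results["ffq_processed"].stat_type == "kendall_tau"
        assert results["ffq_processed"].q is None
        assert results["processed_t18_level"].stat_type == "t"

    def test_null_family_false_rejections_controlled(self):
        """With no coupling, FDR-significant families appear in about
        alpha of replicates (binomial tolerance)."""
        hits = 0
        n_rep = 100
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            att, table = self._table(rng, 60, coupled=False)
            res = run_association_suite(att, table)
            hits += any(r.q is not None and r.q <= 0.05 for r in res)
        # one continuous test per replicate -> Bernoulli(0.05);
        # 3 sigma binomial band around 5 of 100
        assert hits <= 5 + 3 * np.sqrt(100 * 0.05 * 0.95)

    def test_orthogonal_covariate_leaves_association_unchanged(self, rng):
        n = 500
        att = rng.normal(0, 1, n)
        cont = 1.0 * att + rng.normal(0, 1, n)
        cov = rng.normal(size=(n, 2))  # independent of both sides
        data = pd.DataFrame({"delta_bmi": cont})
        table = ClinicalTable(data=data,
                              categories={"delta_bmi": "anthropometry"})
        plain = run_association_suite(att, table)[0].statistic
        adjusted = run_association_suite(att, table,
                                         covariates=cov)[0].statistic
        assert abs(plain - adjusted) < 0.05

    def test_missing_values_pairwise_complete(self, rng):
        att, table = self._table(rng, 80, coupled=True)
        table.data.loc[3, "delta_bmi"] = np.nan
        res = {r.variable: r for r in run_association_suite(att, table)}
        assert res["delta_bmi"].n == 79
        assert res["ffq_processed"].n == 80

    def test_unknown_category_rejected(self, rng):
        data = pd.DataFrame({"x": rng.normal(size=10)})
        with pytest.raises(ValueError):
            ClinicalTable(data=data, categories={"x": "bogus"})
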