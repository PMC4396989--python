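"""Independence tests, linear trend test, dispatch, FDR and grouping."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import fisher_exact as scipy_fisher

from apaswitch import (
    ContingencyTable,
    FisherWorkloadError,
    SwitchTestResult,
    TandemGene,
    UntestableError,
    attach_fdr,
    bh_fdr,
    chi_squared_test,
    fisher_exact_test,
    group_genes,
    linear_trend_test,
    run_gene_tests,
    select_and_run,
    simulate_cohort,
)
from apaswitch.stats import pearson_chi2_stat


def table(c1, c2, scores=None):
    scores = scores if scores is not None else tuple(range(1, len(c1) + 1))
    return ContingencyTable((tuple(c1), tuple(c2)), scores)


def fisher_oracle(c1, c2):
    """Exhaustive Freeman-Halton reference: enumerate every margin-preserving
    2xN table with itertools and sum exact rational hypergeometric
    probabilities of tables no more probable than the observed one."""
    col = [a + b for a, b in zip(c1, c2)]
    r1, n = sum(c1), sum(c1) + sum(c2)
    denom = math.comb(n, r1)

    def prob(row):
        num = 1
        for c, a in zip(col, row):
            num *= math.comb(c, a)
        return Fraction(num, denom)

    p_obs = prob(c1)
    total = Fraction(0)
    for row in itertools.product(*(range(c + 1) for c in col)):
        if sum(row) == r1 and prob(row) <= p_obs:
            total += prob(row)
    return float(total)


class TestChiSquared:
    def test_identical_rows_give_p_one(self):
        assert chi_squared_test(table((100, 100, 100), (100, 100, 100))) == 1.0

    @pytest.mark.parametrize("c2,expected", [
        ((100, 500, 100), 2.67e-28),
        ((10, 100, 10), 2.21e-19),
    ])
    def test_extreme_tails_are_representable(self, c2, expected):
        p = chi_squared_test(table((100, 100, 100), c2))
        assert p == pytest.approx(expected, rel=0.01)

    def test_column_permutation_invariance(self):
        p_ref = chi_squared_test(table((5, 10, 20), (20, 1, 3)))
        for perm in itertools.permutations(range(3)):
            c1 = tuple((5, 10, 20)[i] for i in perm)
            c2 = tuple((20, 1, 3)[i] for i in perm)
            assert chi_squared_test(table(c1, c2)) == pytest.approx(p_ref, rel=1e-12)

    def test_zero_columns_dropped_with_df_reduction(self):
        full = table((5, 10, 20), (20, 1, 3))
        padded = table((5, 0, 10, 20), (20, 0, 1, 3), scores=(1, 2, 3, 4))
        assert pearson_chi2_stat(padded)[1] == 2
        assert chi_squared_test(padded) == pytest.approx(chi_squared_test(full), rel=1e-12)

    def test_fewer_than_two_nonzero_columns_untestable(self):
        with pytest.raises(UntestableError):
            chi_squared_test(table((5, 0), (3, 0)))

    def test_empty_sample_untestable(self):
        with pytest.raises(UntestableError):
            chi_squared_test(table((0, 0, 0), (3, 1, 3)))


class TestFisherExact:
    def test_2x2_hand_enumeration(self):
        # margins (4,4)/(4,4): 34 of the 70 equally-weighted tables are as extreme
        assert fisher_exact_test(table((3, 1), (1, 3))) == pytest.approx(34 / 70, rel=1e-9)

    def test_identical_rows_give_p_one(self):
        assert fisher_exact_test(table((2, 2), (2, 2))) == pytest.approx(1.0)

    def test_matches_scipy_on_2x2(self):
        for c1, c2 in [((3, 1), (1, 3)), ((8, 2), (1, 5)), ((0, 5), (5, 0))]:
            assert fisher_exact_test(table(c1, c2)) == pytest.approx(
                scipy_fisher([list(c1), list(c2)]).pvalue, rel=1e-9)

    @pytest.mark.parametrize("c1,c2", [
        ((2, 0, 1), (0, 2, 1)),
        ((1, 2, 3), (3, 2, 1)),
        ((4, 0, 0, 1), (0, 3, 2, 1)),
    ])
    def test_matches_enumeration_oracle(self, c1, c2):
        assert fisher_exact_test(table(c1, c2)) == pytest.approx(
            fisher_oracle(c1, c2), rel=1e-9)

    @given(st.data())
    def test_oracle_agreement_random_small_tables(self, data):
        k = data.draw(st.integers(2, 4))
        cells = data.draw(st.lists(st.integers(0, 4), min_size=2 * k, max_size=2 * k))
        c1, c2 = tuple(cells[:k]), tuple(cells[k:])
        if sum(c1) + sum(c2) == 0 or sum(c1) + sum(c2) > 12:
            return
        if sum(a + b for a, b in zip(c1, c2) if a + b > 0) == 0:
            return
        nz = [j for j in range(k) if c1[j] + c2[j] > 0]
        if len(nz) < 2:
            return
        assert fisher_exact_test(table(c1, c2)) == pytest.approx(
            fisher_oracle([c1[j] for j in nz], [c2[j] for j in nz]), rel=1e-9)

    def test_workload_cap(self):
        big = table((500, 500, 500, 500, 500), (500, 500, 500, 500, 500))
        with pytest.raises(FisherWorkloadError):
            fisher_exact_test(big, max_tables=1000)


class TestLinearTrend:
    COUNTS = ((100, 100, 100), (100, 500, 100))

    @pytest.mark.parametrize("scores,expected", [
        ((1000, 2000, 4000), 0.004866),
        ((1000, 2300, 4000), 0.247235),
        ((1000, 2700, 4000), 0.247235),
        ((1000, 3000, 4000), 0.004866),
    ])
    def test_middle_site_distance_controls_power(self, scores, expected):
        res = linear_trend_test(table(*self.COUNTS, scores=scores))
        assert res.p == pytest.approx(expected, rel=1e-3)

    def test_symmetric_geometry_blinds_the_test(self):
        # middle score at the flank mean with equal flank counts: r is exactly 0
        res = linear_trend_test(table(*self.COUNTS, scores=(1000, 2500, 4000)))
        assert res.r == 0.0 and res.m2 == 0.0 and res.p == 1.0

    def test_m2_identity(self):
        t = table((5, 10, 20), (20, 1, 3), scores=(100, 250, 900))
        res = linear_trend_test(t)
        n = t.grand_total
        assert res.m2 == pytest.approx((n - 1) * res.r**2, rel=1e-12)

    def test_2x2_m2_equals_scaled_x2(self):
        # for 2x2 tables the trend and Pearson statistics coincide up to (n-1)/n
        for c1, c2 in [((7, 3), (2, 9)), ((10, 10), (5, 30)), ((1, 5), (4, 2))]:
            t = table(c1, c2, scores=(500, 1500))
            n = t.grand_total
            x2, _ = pearson_chi2_stat(t)
            assert linear_trend_test(t).m2 == pytest.approx((n - 1) / n * x2, rel=1e-9)

    @given(a=st.floats(0.1, 50), b=st.floats(-1000, 1000))
    def test_affine_score_invariance(self, a, b):
        t0 = table((5, 10, 20), (20, 1, 3), scores=(100, 250, 900))
        scaled = table((5, 10, 20), (20, 1, 3),
                       scores=tuple(a * s + b for s in (100, 250, 900)))
        r0, r1 = linear_trend_test(t0), linear_trend_test(scaled)
        assert r1.r == pytest.approx(r0.r, rel=1e-9, abs=1e-12)
        assert r1.p == pytest.approx(r0.p, rel=1e-9)

    def test_score_reversal_flips_r_keeps_p(self):
        t = table((5, 10, 20), (20, 1, 3), scores=(100, 250, 900))
        rev = table((20, 10, 5), (3, 1, 20), scores=(-900, -250, -100))
        res, res_rev = linear_trend_test(t), linear_trend_test(rev)
        assert res_rev.r == pytest.approx(-res.r, rel=1e-9)
        assert res_rev.p == pytest.approx(res.p, rel=1e-9)

    def test_trend_not_permutation_invariant_but_chi_is(self):
        c1, c2 = (100, 100, 100), (100, 500, 100)
        p_sorted = linear_trend_test(table(c1, c2, scores=(1000, 2000, 4000))).p
        # moving the middle site's score changes the trend p but not chi-squared
        p_moved = linear_trend_test(table(c1, c2, scores=(1000, 2300, 4000))).p
        assert p_sorted != pytest.approx(p_moved, rel=1e-3)
        assert chi_squared_test(table(c1, c2)) == pytest.approx(
            chi_squared_test(table(c2, c1)), rel=1e-12)

    def test_empty_row_gives_r_zero_p_one(self):
        res = linear_trend_test(table((0, 0, 0), (3, 1, 3)))
        assert res.r == 0.0 and res.p == 1.0


class TestDispatch:
    def test_small_total_uses_fisher_without_trend(self):
        t = table((5, 5, 5), (5, 5, 4))  # grand total 29
        res = select_and_run(t, "g", small_threshold=30)
        assert res.independence_method == "fisher_exact"
        assert res.p_trend is None and res.r is None and res.m2 is None

    def test_threshold_total_uses_chi_and_trend(self):
        t = table((5, 5, 5), (5, 5, 5))  # grand total 30
        res = select_and_run(t, "g", small_threshold=30)
        assert res.independence_method == "chi_squared"
        assert res.p_trend is not None

    def test_example_genes_all_dispatch_to_chi(self):
        from apaswitch import all_example_genes

        for g in all_example_genes():
            res = select_and_run(ContingencyTable.from_gene(g), g.gene_id)
            assert res.independence_method == "chi_squared"


class TestBhFdr:
    @pytest.mark.parametrize("p,expected", [
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.005, 0.5], [0.01, 0.5]),
        ([0.25], [0.25]),
    ])
    def test_hand_computed_adjustments(self, p, expected):
        assert bh_fdr(p) == pytest.approx(expected)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, float("nan")])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    def test_matches_statsmodels_and_dominates_p(self, pvals):
        from statsmodels.stats.multitest import multipletests

        q = bh_fdr(pvals)
        _, q_ref, _, _ = multipletests(pvals, method="fdr_bh")
        assert q == pytest.approx(q_ref, rel=1e-12, abs=1e-12)
        assert (q >= np.asarray(pvals) - 1e-15).all()
        assert (q <= 1.0).all()
        order = np.argsort(pvals)
        assert (np.diff(q[order]) >= -1e-15).all()  # monotone over sorted p


class TestGrouping:
    @staticmethod
    def result(gene_id, q_ind, q_trend):
        return SwitchTestResult(
            gene_id=gene_id, n_sites=3, grand_total=300,
            independence_method="chi_squared", p_independence=q_ind,
            p_trend=q_trend, q_independence=q_ind, q_trend=q_trend,
        )

    def test_partition_definitions(self):
        results = [
            self.result("both", 0.001, 0.001),
            self.result("chi_only", 0.001, 0.5),
            self.result("trend_only", 0.5, 0.001),
            self.result("neither", 0.5, 0.5),
        ]
        groups = group_genes(results, fdr_cutoff=0.01)
        assert groups == {"CL": ["both"], "CO": ["chi_only"],
                          "LO": ["trend_only"], "NS": ["neither"]}

    def test_no_trend_result_restricted_to_co_or_ns(self):
        small_sig = SwitchTestResult("a", 2, 20, "fisher_exact", 1e-6,
                                     q_independence=1e-5)
        small_ns = SwitchTestResult("b", 2, 20, "fisher_exact", 0.9,
                                    q_independence=0.9)
        groups = group_genes([small_sig, small_ns], fdr_cutoff=0.01)
        assert groups["CO"] == ["a"] and groups["NS"] == ["b"]
        assert not groups["CL"] and not groups["LO"]

    def test_planted_complex_genes_land_in_co_or_cl(self):
        genes = simulate_cohort(60, effect="up_down_up", effect_size=0.3,
                                depth=800, seed=11)
        results, skipped = run_gene_tests(genes)
        assert not skipped
        groups = group_genes(results, fdr_cutoff=0.01)
        assert len(groups["CL"]) + len(groups["CO"]) == 60

    def test_q_values_required(self):
        bare = SwitchTestResult("a", 3, 300, "chi_squared", 0.5)
        with pytest.raises(ValueError, match="attach_fdr"):
            group_genes([bare])


class TestAttachFdr:
    def test_trend_fdr_runs_only_over_trend_tested_genes(self):
        results = [
            SwitchTestResult("a", 3, 300, "chi_squared", 0.02, p_trend=0.04),
            SwitchTestResult("b", 3, 300, "chi_squared", 0.01, p_trend=0.02),
            SwitchTestResult("c", 2, 10, "fisher_exact", 0.03),
        ]
        attach_fdr(results)
        assert results[2].q_trend is None
        # independence BH over m=3, trend BH over m=2
        assert results[0].q_independence == pytest.approx(0.03)
        assert results[0].q_trend == pytest.approx(0.04)
        assert results[1].q_trend == pytest.approx(0.04)


def test_null_type_i_error_within_tolerance_small():
    """Quick null calibration: neither test rejects far from its level."""
    genes = simulate_cohort(400, effect="null", depth=300, seed=7)
    results, _ = run_gene_tests(genes)
    chi_rate = np.mean([r.p_independence < 0.05 for r in results])
    trend_rate = np.mean([r.p_trend < 0.05 for r in results])
    # 400 genes: ~3 sd of a binomial(400, 0.05) proportion is ~0.033
    assert abs(chi_rate - 0.05) < 0.035
    assert abs(trend_rate - 0.05) < 0.035
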