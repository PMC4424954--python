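"""Contingency statistics: OR/CI, chi-squared, Fisher exact, CMH, logistic."""

import numpy as np
import pytest
import scipy.special
import scipy.stats
from hypothesis import given
from hypothesis import strategies as st

import finelocus as fl
from finelocus.association import (
    ContingencyTable2x2,
    auto_test,
    fisher_pvalues_for_margins,
)
from finelocus.exceptions import (
    DegenerateTableError,
    SeparationError,
    SingularDesignError,
)
from finelocus.genotypes import GenotypeMatrix
from finelocus.variants import AlleleCount

tables = st.tuples(
    st.integers(0, 40), st.integers(0, 40), st.integers(0, 40), st.integers(0, 40)
).filter(lambda t: t[0] + t[1] > 0 and t[2] + t[3] > 0)


def T(a, b, c, d):
    return ContingencyTable2x2(a, b, c, d)


class TestTableFromCounts:
    def test_published_examples(self):
        t = fl.table_from_counts(AlleleCount(54, 492), AlleleCount(129, 758))
        assert t.cells() == (54, 438, 129, 629)
        t = fl.table_from_counts(AlleleCount(54, 492), AlleleCount(1687, 8600))
        assert t.cells() == (54, 438, 1687, 6913)

    def test_zero_alt(self):
        t = fl.table_from_counts(AlleleCount(0, 10), AlleleCount(0, 10))
        assert t.cells() == (0, 10, 0, 10)


class TestOddsRatioCI:
    def test_lead_variant_vs_reference_panels(self):
        res = fl.odds_ratio_ci(T(54, 438, 129, 629))
        assert res.odds_ratio == pytest.approx(0.6012, abs=5e-4)
        assert round(res.ci_low, 2) == 0.43
        assert round(res.ci_high, 2) == 0.84
        res = fl.odds_ratio_ci(T(54, 438, 1687, 6913))
        assert res.odds_ratio == pytest.approx(0.5052, abs=5e-4)

    def test_symmetric_table(self):
        res = fl.odds_ratio_ci(T(5, 5, 5, 5))
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.ci_low * res.ci_high == pytest.approx(1.0)  # log-symmetric

    def test_zero_cell_haldane_flagged(self):
        res = fl.odds_ratio_ci(T(0, 10, 5, 5))
        assert res.haldane
        assert 0 < res.odds_ratio < 1

    def test_degenerate_margin(self):
        with pytest.raises(DegenerateTableError):
            fl.odds_ratio_ci(T(0, 10, 0, 10))

    @given(tables)
    def test_antisymmetry_under_row_swap(self, cells):
        t = T(*cells)
        try:
            a = fl.odds_ratio_ci(t)
            b = fl.odds_ratio_ci(t.transpose_rows())
        except DegenerateTableError:
            return
        assert a.odds_ratio * b.odds_ratio == pytest.approx(1.0, rel=1e-9)


class TestChisqAllelic:
    def test_identical_proportions(self):
        res = fl.chisq_allelic(T(10, 90, 10, 90))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_published_p_value(self):
        res = fl.chisq_allelic(T(54, 438, 129, 629))
        assert res.p_value == pytest.approx(3.1e-3, abs=1e-4)

    def test_matches_hand_computed_pearson(self):
        # brute force from the definition sum (O-E)^2 / E
        a, b, c, d = 20, 80, 10, 90
        n = a + b + c + d
        obs = np.array([[a, b], [c, d]], dtype=float)
        exp = np.outer(obs.sum(1), obs.sum(0)) / n
        stat = ((obs - exp) ** 2 / exp).sum()
        res = fl.chisq_allelic(T(a, b, c, d))
        assert res.statistic == pytest.approx(stat, rel=1e-12)

    def test_monotone_in_proportion_gap_at_fixed_margins(self):
        # row margins fixed; growing |p_case - p_control| shrinks both p's
        chi_p = [fl.chisq_allelic(T(a, 100 - a, 30, 70)).p_value
                 for a in range(30, 56, 5)]
        fis_p = [fl.fisher_exact(T(a, 100 - a, 30, 70)).p_value
                 for a in range(30, 56, 5)]
        assert chi_p == sorted(chi_p, reverse=True)
        assert fis_p == sorted(fis_p, reverse=True)


class TestFisherExact:
    def test_null_table(self):
        assert fl.fisher_exact(T(0, 10, 0, 10)).p_value == pytest.approx(1.0)

    def test_single_case_singleton(self):
        res = fl.fisher_exact(T(1, 491, 0, 758))
        oracle = scipy.stats.fisher_exact([[1, 491], [0, 758]])[1]
        assert res.p_value == pytest.approx(oracle, rel=1e-9)

    def test_rare_vs_large_panel_significant(self):
        res = fl.fisher_exact(T(2, 490, 2, 9356))
        assert res.p_value < 0.05

    def test_sidedness(self):
        t = T(8, 2, 2, 8)
        g = fl.fisher_exact(t, sided="greater").p_value
        l = fl.fisher_exact(t, sided="less").p_value
        sg = scipy.stats.fisher_exact([[8, 2], [2, 8]], alternative="greater")[1]
        sl = scipy.stats.fisher_exact([[8, 2], [2, 8]], alternative="less")[1]
        assert g == pytest.approx(sg, rel=1e-9)
        assert l == pytest.approx(sl, rel=1e-9)

    def test_exhaustive_small_margins_vs_scipy(self):
        for r1 in range(1, 13):
            for r2 in range(1, 13):
                for a in range(r1 + 1):
                    for c in range(r2 + 1):
                        mine = fl.fisher_exact(T(a, r1 - a, c, r2 - c)).p_value
                        ref = scipy.stats.fisher_exact(
                            [[a, r1 - a], [c, r2 - c]]
                        )[1]
                        assert mine == pytest.approx(ref, rel=1e-9, abs=1e-12)

    @given(tables)
    def test_random_tables_vs_scipy(self, cells):
        mine = fl.fisher_exact(T(*cells)).p_value
        ref = scipy.stats.fisher_exact([cells[:2], cells[2:]])[1]
        assert mine == pytest.approx(ref, rel=1e-9, abs=1e-12)

    def test_vectorized_margins_match_per_table_calls(self):
        avals, pvals = fisher_pvalues_for_margins(12, 9, 7)
        for a, p in zip(avals, pvals):
            t = T(int(a), 12 - int(a), 7 - int(a), 9 - 7 + int(a))
            assert fl.fisher_exact(t).p_value == pytest.approx(float(p), rel=1e-12)


class TestCombineTables:
    def test_pooling_identical_tables_preserves_or(self):
        t = T(20, 80, 10, 90)
        single = auto_test(t)
        double = fl.combine_tables([t, t], method="pool")
        assert double.odds_ratio == pytest.approx(single.odds_ratio, rel=1e-12)

    def test_single_table_pool_is_identity(self):
        t = T(20, 80, 10, 90)
        assert fl.combine_tables([t], method="pool").p_value == pytest.approx(
            auto_test(t).p_value
        )

    def test_pool_commutes_with_permutation(self):
        ts = [T(5, 15, 3, 17), T(20, 80, 10, 90), T(1, 9, 2, 8)]
        a = fl.combine_tables(ts, method="pool")
        b = fl.combine_tables(ts[::-1], method="pool")
        assert a.odds_ratio == b.odds_ratio and a.p_value == b.p_value

    def test_cmh_common_or_closed_form(self):
        # both strata have OR exactly 2 => MH common OR 2
        ts = [T(20, 10, 10, 10), T(40, 10, 20, 10)]
        res = fl.combine_tables(ts, method="cmh")
        assert res.odds_ratio == pytest.approx(2.0, rel=1e-9)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            fl.combine_tables([])


def _hard_cohort(rng, n, maf, beta1, beta0=-1.0, extra=None):
    g = rng.binomial(2, maf, n).astype(float)
    eta = beta0 + beta1 * g
    if extra is not None:
        eta = eta + extra[1] * extra[0]
    y = rng.random(n) < scipy.special.expit(eta)
    cols = [g] if extra is None else [g, extra[0]]
    return GenotypeMatrix(
        [f"s{i}" for i in range(n)],
        [f"v{j+1}" for j in range(len(cols))],
        np.column_stack(cols),
        phenotype=np.where(y, "case", "control").astype(object),
    )


class TestLogisticDosage:
    def test_constant_dosage_singular(self):
        gm = GenotypeMatrix(
            ["a", "b", "c", "d"],
            ["v"],
            np.ones((4, 1)),
            phenotype=np.array(["control", "case", "control", "case"], dtype=object),
        )
        with pytest.raises(SingularDesignError):
            fl.logistic_dosage(gm, "v")

    def test_complete_separation_reported(self):
        gm = GenotypeMatrix(
            ["a", "b", "c", "d"],
            ["v"],
            np.array([[0.0], [0.0], [2.0], [2.0]]),
            phenotype=np.array(
                ["control", "control", "case", "case"], dtype=object
            ),
        )
        with pytest.raises(SeparationError):
            fl.logistic_dosage(gm, "v")

    def test_matches_statsmodels_oracle(self, rng):
        import statsmodels.api as sm

        gm = _hard_cohort(rng, 3000, 0.3, np.log(1.5))
        res = fl.logistic_dosage(gm, "v1")
        X = sm.add_constant(gm.dosages)
        fit = sm.Logit(gm.is_case().astype(float), X).fit(disp=0)
        assert res.beta == pytest.approx(fit.params[1], abs=1e-6)
        assert res.p_value == pytest.approx(fit.pvalues[1], rel=1e-4)

    def test_agrees_with_allelic_or_on_hard_genotypes(self, rng):
        gm = _hard_cohort(rng, 30000, 0.3, np.log(1.5))
        res = fl.logistic_dosage(gm, "v1")
        y = gm.is_case()
        g = gm.dosages[:, 0]
        a = g[y].sum()
        b = 2 * y.sum() - a
        c = g[~y].sum()
        d = 2 * (~y).sum() - c
        allelic = fl.odds_ratio_ci(ContingencyTable2x2(a, b, c, d)).odds_ratio
        assert res.odds_ratio == pytest.approx(allelic, rel=0.05)

    def test_perfect_proxy_conditioning_is_singular(self, rng):
        g = rng.binomial(2, 0.3, 500).astype(float)
        y = rng.random(500) < 0.5
        gm = GenotypeMatrix(
            [f"s{i}" for i in range(500)],
            ["target", "proxy"],
            np.column_stack([g, g]),  # r^2 = 1 in the sample
            phenotype=np.where(y, "case", "control").astype(object),
        )
        with pytest.raises(SingularDesignError):
            fl.logistic_dosage(gm, "target", condition_on="proxy")

    def test_conditioning_absorbs_true_signal(self, rng):
        # target's effect flows entirely through the conditioned variant:
        # conditional p should be non-significant
        g = rng.binomial(2, 0.3, 8000).astype(float)
        noisy = np.clip(g + rng.normal(0, 0.1, 8000), 0, 2)
        y = rng.random(8000) < scipy.special.expit(-1 + np.log(2.0) * g)
        gm = GenotypeMatrix(
            [f"s{i}" for i in range(8000)],
            ["target", "driver"],
            np.column_stack([noisy, g]),
            phenotype=np.where(y, "case", "control").astype(object),
        )
        alone = fl.logistic_dosage(gm, "target")
        conditional = fl.logistic_dosage(gm, "target", condition_on="driver")
        assert alone.p_value < 1e-10
        assert conditional.p_value > 0.01

    def test_missing_dosages_dropped_pairwise(self, rng):
        gm = _hard_cohort(rng, 1000, 0.3, np.log(1.5))
        gm.dosages[:50, 0] = np.nan
        res = fl.logistic_dosage(gm, "v1")
        assert res.n_effective == 950
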