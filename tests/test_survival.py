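"""Kaplan-Meier, log-rank, Cox (Efron), and the minimal-p cutoff scan."""
import dataclasses
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test as lifelines_logrank

from immunoscreen import (
    InsufficientGroupError,
    NoCutoffError,
    SingularDesignError,
    SurvivalData,
    ValidationError,
    fit_cox,
    km_estimate,
    logrank_test,
    outcome_screen,
    scan_cutoffs,
    simulate_cohort,
)
from immunoscreen.simulate import SimulationConfig
from immunoscreen.survival import candidate_cutoffs

from conftest import make_survival


class TestKaplanMeier:
    def test_all_events_product_limit(self):
        km = km_estimate(make_survival([1, 2, 3], [1, 1, 1]))
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0])
        np.testing.assert_array_equal(km.at_risk, [3, 2, 1])

    def test_no_events_flat_curve(self):
        km = km_estimate(make_survival([5, 6, 7], [0, 0, 0]))
        assert km.times.size == 0  # S(t) stays at 1: no steps

    def test_censoring_decrements_risk_without_step(self):
        # 4 samples: event at t=2, rest censored at t=5 -> S(2) = 3/4
        km = km_estimate(make_survival([2, 5, 5, 5], [1, 0, 0, 0]))
        np.testing.assert_allclose(km.survival, [0.75])
        np.testing.assert_array_equal(km.at_risk, [4])

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            km_estimate(make_survival([], []))

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.lists(st.integers(1, 20), min_size=1, max_size=15))
    def test_no_censoring_equals_empirical_survival(self, times):
        """With every sample an event, KM is the empirical survival function."""
        t = np.array(times, float)
        km = km_estimate(make_survival(t, np.ones_like(t)))
        for et, s in zip(km.times, km.survival):
            assert s == pytest.approx((t > et).mean())


def logrank_oracle(ta, ea, tb, eb):
    """Independent per-event-time loop (textbook O-E and variance)."""
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    g = np.concatenate([np.ones(len(ta)), np.zeros(len(tb))])
    o_minus_e = var = 0.0
    for et in np.unique(t[e == 1]):
        at = t >= et
        n, n1 = at.sum(), (at & (g == 1)).sum()
        dmask = (t == et) & (e == 1)
        d, d1 = dmask.sum(), (dmask & (g == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestLogrank:
    def test_identical_groups_give_null_result(self):
        a = make_survival([3, 6, 9, 12], [1, 0, 1, 0])
        chi2, p = logrank_test(a, a)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_six_sample_hand_instance(self):
        ta, ea = np.array([2.0, 4.0, 6.0]), np.array([1.0, 1.0, 0.0])
        tb, eb = np.array([3.0, 5.0, 7.0]), np.array([1.0, 0.0, 1.0])
        chi2, _ = logrank_test(SurvivalData(ta, ea), SurvivalData(tb, eb))
        assert chi2 == pytest.approx(logrank_oracle(ta, ea, tb, eb), abs=1e-10)

    def test_matches_lifelines_with_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            ta = np.round(rng.exponential(10, 15), 0) + 1
            tb = np.round(rng.exponential(14, 12), 0) + 1
            ea = rng.integers(0, 2, 15).astype(float)
            eb = rng.integers(0, 2, 12).astype(float)
            if ea.sum() + eb.sum() == 0:
                ea[0] = 1
            chi2, p = logrank_test(SurvivalData(ta, ea), SurvivalData(tb, eb))
            ref = lifelines_logrank(ta, tb, ea, eb)
            assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
            assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_symmetric_under_group_exchange(self):
        a = make_survival([2, 8, 14, 20], [1, 1, 0, 1])
        b = make_survival([5, 9, 30], [1, 0, 0])
        assert logrank_test(a, b) == pytest.approx(logrank_test(b, a))

    def test_zero_events_rejected(self):
        with pytest.raises(ValidationError):
            logrank_test(make_survival([1, 2], [0, 0]), make_survival([3], [0]))


def efron_loglik_oracle(beta, x, t, e):
    """Straightforward (slow) Efron partial log-likelihood for 1 covariate."""
    ll = 0.0
    for et in np.unique(t[e == 1]):
        deaths = np.flatnonzero((t == et) & (e == 1))
        risk = np.flatnonzero(t >= et)
        d = len(deaths)
        s0 = np.exp(beta * x[risk]).sum()
        s0d = np.exp(beta * x[deaths]).sum()
        ll += beta * x[deaths].sum()
        for l in range(d):
            ll -= math.log(s0 - (l / d) * s0d)
    return ll


COX_T = np.array([3.0, 3.0, 5.0, 7.0, 7.0, 7.0, 9.0, 11.0, 13.0, 15.0])
COX_E = np.array([1.0, 1.0, 0.0, 1.0, 1.0, 0.0, 1.0, 0.0, 1.0, 1.0])
COX_X = np.array([2.1, 0.5, 1.7, -0.3, 0.9, -1.2, 0.4, 1.1, -0.8, -1.5])


class TestCox:
    def test_identical_groups_give_null_coefficient(self):
        t = np.tile([2.0, 5.0, 8.0, 11.0], 2)
        e = np.tile([1.0, 0.0, 1.0, 1.0], 2)
        x = np.r_[np.zeros(4), np.ones(4)]
        fit = fit_cox(x, SurvivalData(t, e))
        assert abs(fit.coef[0]) < 1e-6
        assert fit.hr[0] == pytest.approx(1.0, abs=1e-5)

    def test_ten_sample_instance_matches_likelihood_grid(self):
        """Newton solution maximizes the Efron partial likelihood (grid oracle)."""
        fit = fit_cox(COX_X, SurvivalData(COX_T, COX_E))
        grid = np.arange(-3.0, 3.0, 1e-4)
        lls = [efron_loglik_oracle(b, COX_X, COX_T, COX_E) for b in grid]
        assert fit.coef[0] == pytest.approx(grid[int(np.argmax(lls))], abs=1e-4)

    def test_matches_lifelines_efron(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(40, 3))
        t = np.round(rng.exponential(12, 40), 1) + 0.1
        e = (rng.random(40) < 0.7).astype(float)
        fit = fit_cox(x, SurvivalData(t, e), names=("a", "b", "c"))
        df = pd.DataFrame({"t": t, "e": e, "a": x[:, 0], "b": x[:, 1], "c": x[:, 2]})
        ref = CoxPHFitter().fit(df, "t", "e")
        np.testing.assert_allclose(fit.coef, ref.params_.values, atol=1e-5)
        np.testing.assert_allclose(fit.se, ref.standard_errors_.values, atol=1e-5)

    def test_score_test_equals_logrank_without_ties(self):
        rng = np.random.default_rng(2)
        t = rng.permutation(np.arange(1.0, 31.0))  # distinct times: no ties
        e = (rng.random(30) < 0.8).astype(float)
        x = (rng.random(30) < 0.5).astype(float)
        fit = fit_cox(x, SurvivalData(t, e))
        chi2, p = logrank_test(
            SurvivalData(t[x == 1], e[x == 1]), SurvivalData(t[x == 0], e[x == 0])
        )
        assert fit.score_chi2 == pytest.approx(chi2, abs=1e-8)
        assert fit.score_p == pytest.approx(p, abs=1e-8)

    def test_covariate_shift_invariance(self):
        fit1 = fit_cox(COX_X, SurvivalData(COX_T, COX_E))
        fit2 = fit_cox(COX_X + 100.0, SurvivalData(COX_T, COX_E))
        assert fit1.coef[0] == pytest.approx(fit2.coef[0], abs=1e-8)

    def test_binary_relabel_inverts_hr(self):
        x = (COX_X > 0).astype(float)
        fit1 = fit_cox(x, SurvivalData(COX_T, COX_E))
        fit2 = fit_cox(1.0 - x, SurvivalData(COX_T, COX_E))
        assert fit1.hr[0] == pytest.approx(1.0 / fit2.hr[0], rel=1e-6)

    def test_constant_covariate_rejected(self):
        with pytest.raises(SingularDesignError):
            fit_cox(np.ones(10), SurvivalData(COX_T, COX_E))

    def test_collinear_design_rejected(self):
        design = np.column_stack([COX_X, 2.0 * COX_X])
        with pytest.raises(SingularDesignError):
            fit_cox(design, SurvivalData(COX_T, COX_E))

    def test_perfect_separation_flagged_not_silent(self):
        # covariate orders survival perfectly -> monotone likelihood
        t = np.arange(1.0, 13.0)
        e = np.ones(12)
        x = -t  # highest x dies first
        fit = fit_cox(x, SurvivalData(t, e))
        assert not fit.converged
        assert fit.flags

    def test_too_few_events_rejected(self):
        with pytest.raises(ValidationError):
            fit_cox(COX_X, SurvivalData(COX_T, np.r_[1.0, np.zeros(9)]))


def scan_oracle(values, surv):
    """Brute force: lifelines log-rank at every eligible split."""
    best_p, best_c = np.inf, None
    for c in candidate_cutoffs(values):
        hi = values > c
        r = lifelines_logrank(surv.time[hi], surv.time[~hi],
                              surv.event[hi], surv.event[~hi])
        if r.p_value < best_p - 1e-15:
            best_p, best_c = r.p_value, c
    return best_c, best_p


class TestScanCutoffs:
    def test_constant_expression_is_error(self):
        surv = make_survival(np.arange(1.0, 25.0), np.ones(24))
        with pytest.raises(NoCutoffError):
            scan_cutoffs(np.full(24, 3.3), surv)

    def test_small_cohort_rejected(self):
        surv = make_survival(np.arange(1.0, 11.0), np.ones(10))
        with pytest.raises(InsufficientGroupError):
            scan_cutoffs(np.arange(10.0), surv)

    def test_fixed_instance_matches_brute_force(self):
        rng = np.random.default_rng(12)
        n = 20
        v = rng.normal(5, 1, n)
        surv = make_survival(np.round(rng.exponential(30, n), 1) + 0.1,
                             (rng.random(n) < 0.7).astype(float))
        res = scan_cutoffs(v, surv)
        c, p = scan_oracle(v, surv)
        assert res.best_cutoff == pytest.approx(c)
        assert res.min_p == pytest.approx(p, rel=1e-8)

    def test_group_sizes_respect_quartile_bound(self):
        rng = np.random.default_rng(13)
        n = 40
        v = rng.normal(size=n)
        surv = make_survival(np.round(rng.exponential(30, n), 1) + 0.1,
                             np.ones(n))
        res = scan_cutoffs(v, surv)
        for c in res.cutoffs:
            n_high = int((v > c).sum())
            assert n_high >= n // 4 and (n - n_high) >= n // 4

    def test_min_p_not_worse_than_median_split(self):
        rng = np.random.default_rng(14)
        n = 31  # odd: the median is an observed value, hence eligible
        v = rng.normal(size=n)
        surv = make_survival(np.round(rng.exponential(20, n), 1) + 0.1,
                             (rng.random(n) < 0.8).astype(float))
        res = scan_cutoffs(v, surv)
        med = np.median(v)
        assert np.any(np.isclose(res.cutoffs, med))
        hi = v > med
        r = lifelines_logrank(surv.time[hi], surv.time[~hi],
                              surv.event[hi], surv.event[~hi])
        assert res.min_p <= r.p_value + 1e-12

    def test_min_p_is_minimum_of_trace(self):
        rng = np.random.default_rng(15)
        n = 35
        v = rng.normal(size=n)
        surv = make_survival(np.round(rng.exponential(25, n), 1) + 0.1, np.ones(n))
        res = scan_cutoffs(v, surv)
        assert res.min_p == res.p_values.min()
        assert res.best_q == res.fdr_q[int(np.argmin(res.p_values))]


class TestOutcomeScreen:
    def test_single_gene_matches_direct_scan(self, recovery_cohort):
        expr, clin = recovery_cohort
        surv = clin.survival()
        direct = scan_cutoffs(expr.gene_values("STAT1"), surv, name="STAT1")
        screened = outcome_screen(expr, surv, gene_list=["STAT1"])
        assert len(screened) == 1
        assert screened[0].best_cutoff == direct.best_cutoff
        assert screened[0].min_p == direct.min_p
        assert screened[0].hr == direct.hr

    def test_planted_protective_gene_recovered(self):
        """A strongly protective gene achieves the smallest minimal p
        among noise genes in most seeded replicates."""
        hits = 0
        cfg = SimulationConfig(n_samples=150, n_genes=12,
                               planted_signature=("HIT",), log_hr=-0.9)
        for seed in range(10):
            expr, clin = simulate_cohort(dataclasses.replace(cfg, seed=seed))
            res = outcome_screen(expr, clin.survival(), fit_hr=False)
            best = min(res, key=lambda r: r.min_p)
            hits += best.name == "HIT"
        assert hits >= 9

    def test_pooled_fdr_scope(self, recovery_cohort):
        expr, clin = recovery_cohort
        within = outcome_screen(expr, clin.survival(), fit_hr=False)
        pooled = outcome_screen(expr, clin.survival(), fit_hr=False,
                                fdr_scope="pooled")
        assert [r.name for r in within] == [r.name for r in pooled]
        for w, p in zip(within, pooled):
            assert w.min_p == p.min_p  # only the q changes
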