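import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rxagsp.core import GeneSetPair, IndexVector, compute_index, enumerate_gsps
from rxagsp.io import CandidateSets
from rxagsp.simulate import SimulationConfig, simulate_cohorts
from rxagsp.survival import (
    cox_multivariate,
    cox_univariate,
    dichotomize,
    logrank_test,
    screen_cohort,
)
from conftest import random_survival


def iv_from(index_values):
    index = np.asarray(index_values, dtype=float)
    return IndexVector(
        sample_ids=[f"s{i}" for i in range(index.size)],
        index=index,
        poor_mask=index > 0,
        evaluable=~np.isnan(index),
    )


class TestDichotomize:
    def test_even_split_balanced(self):
        d = dichotomize(iv_from([+1, -1, +2, -2]))
        assert (d.n_poor, d.n_good, d.balanced) == (2, 2, True)

    def test_boundary_20_percent_inclusive(self):
        d = dichotomize(iv_from([+1, +1, +1, +1, -1]))
        assert (d.n_poor, d.n_good) == (4, 1)
        assert d.balanced  # 1/5 == 20% passes "at least 20%"

    def test_all_positive_unbalanced(self):
        d = dichotomize(iv_from([+1, +2, +3]))
        assert d.n_good == 0 and not d.balanced

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dichotomize(iv_from([np.nan, np.nan]))


class TestLogrank:
    def test_identical_groups_null(self):
        # two copies of the same survival experience
        time = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        event = np.array([1, 0, 1, 1, 0, 1])
        group = np.array([True, True, True, False, False, False])
        res = logrank_test(group, time, event)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_four_samples(self):
        # group A events at t=1,2; group B censored at t=3,4
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.array([1, 1, 0, 0])
        group = np.array([True, True, False, False])
        # by hand: t=1: n=4, n_A=2, d=1 in A -> O-E = 1 - 1/2, V = (1/2)(1/2)(3/3)
        #          t=2: n=3, n_A=1, d=1 in A -> O-E = 1 - 1/3, V = (1/3)(2/3)(2/2)
        o_minus_e = (1 - 2 / 4) + (1 - 1 / 3)
        var = (2 / 4) * (2 / 4) * (4 - 1) / (4 - 1) + (1 / 3) * (2 / 3) * (3 - 1) / (3 - 1)
        expected_stat = o_minus_e ** 2 / var
        res = logrank_test(group, time, event)
        assert res.statistic == pytest.approx(expected_stat)
        assert res.p_value == pytest.approx(stats.chi2.sf(expected_stat, 1))

    def test_zero_events_degenerate(self):
        res = logrank_test(np.array([True, False]), np.array([1.0, 2.0]), np.array([0, 0]))
        assert res.degenerate and res.p_value == 1.0

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test(np.array([True, True]), np.array([1.0, 2.0]), np.array([1, 1]))

    def test_null_p_uniform(self, rng):
        # permuted labels on null data -> approximately uniform p-values
        n = 40
        pvals = []
        for _ in range(400):
            time, event = random_survival(rng, n, hazard=0.3, censor=0.1)
            group = rng.permutation(np.arange(n) < n // 2)
            pvals.append(logrank_test(group, time, event).p_value)
        stat, p = stats.kstest(pvals, "uniform")
        assert p > 0.001

    def test_time_unit_invariance(self, rng):
        time, event = random_survival(rng, 60)
        group = rng.random(60) < 0.5
        if not group.any() or group.all():
            group[0] = ~group[0]
        a = logrank_test(group, time, event)
        b = logrank_test(group, time * 365.25, event)
        assert a.statistic == pytest.approx(b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank

        for _ in range(5):
            time, event = random_survival(rng, 80, hazard=0.25)
            group = rng.random(80) < 0.4
            res = logrank_test(group, time, event)
            ref = ll_logrank(time[group], time[~group], event[group], event[~group])
            assert res.statistic == pytest.approx(ref.test_statistic, rel=1e-9)
            assert res.p_value == pytest.approx(ref.p_value, rel=1e-9)


class TestCoxUnivariate:
    def test_identical_groups(self):
        time = np.array([1.0, 2.0, 3.0, 4.0, 1.0, 2.0, 3.0, 4.0])
        event = np.array([1, 1, 0, 1, 1, 1, 0, 1])
        group = np.array([1.0] * 4 + [0.0] * 4)
        res = cox_univariate(group, time, event)
        assert res.hazard_ratio == pytest.approx(1.0, abs=1e-6)
        assert res.p_wald == pytest.approx(1.0, abs=1e-6)

    def test_planted_hr_recovery(self, rng):
        n = 500
        group = rng.random(n) < 0.5
        hazard = 0.1 * np.exp(np.log(2.0) * group)
        t_event = rng.exponential(1.0 / hazard)
        t_cens = rng.exponential(20.0, size=n)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
        res = cox_univariate(group, time, event)
        assert 1.6 <= res.hazard_ratio <= 2.5
        assert res.ci_low < 2.0 < res.ci_high

    def test_sign_flip_inverts_hr(self, rng):
        time, event = random_survival(rng, 100)
        x = rng.normal(size=100)
        a = cox_univariate(x, time, event)
        b = cox_univariate(-x, time, event)
        assert a.hazard_ratio == pytest.approx(1.0 / b.hazard_ratio, rel=1e-6)
        assert a.p_wald == pytest.approx(b.p_wald, rel=1e-6)

    def test_matches_lifelines_binary_and_continuous(self, rng):
        from lifelines import CoxPHFitter

        time, event = random_survival(rng, 120, hazard=0.2)
        for x in (rng.random(120) < 0.4, rng.normal(size=120)):
            res = cox_univariate(x, time, event)
            df = pd.DataFrame({"x": np.asarray(x, float), "t": time, "e": event})
            cph = CoxPHFitter().fit(df, "t", "e")
            assert res.beta == pytest.approx(float(cph.params_.iloc[0]), abs=1e-4)
            assert res.se == pytest.approx(float(cph.standard_errors_.iloc[0]), rel=1e-3)

    def test_separation_flagged(self):
        # all events in group 1 while group 0 stays at risk: monotone likelihood
        time = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        event = np.array([1, 1, 1, 0, 0, 0])
        group = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        res = cox_univariate(group, time, event)
        assert res.separation
        assert res.hazard_ratio == np.inf
        assert 0.0 < res.p_wald < 1.0  # score test still informative

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError):
            cox_univariate(np.array([1.0, 0.0]), np.array([1.0, 2.0]), np.array([1, 0]))

    def test_efron_ties_reference_value(self):
        # frozen oracle: R survival::coxph(Surv(t,e)~x, ties="efron") on this data
        time = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 3.0, 4.0, 5.0])
        event = np.array([1, 1, 0, 1, 1, 1, 0, 1])
        x = np.array([1.0, 0.0, 1.0, 1.0, 0.0, 0.0, 1.0, 0.0])
        res = cox_univariate(x, time, event)
        assert res.beta == pytest.approx(-0.0912173231717, abs=1e-9)


class TestCoxMultivariate:
    def test_single_covariate_matches_univariate(self, rng):
        time, event = random_survival(rng, 150, hazard=0.2)
        x = rng.normal(size=150)
        table, model_p = cox_multivariate(pd.DataFrame({"x": x}), time, event)
        uni = cox_univariate(x, time, event)
        assert np.log(table.loc["x", "hazard_ratio"]) == pytest.approx(uni.beta, abs=1e-4)

    def test_two_planted_effects(self, rng):
        n = 1000
        x1 = (rng.random(n) < 0.5).astype(float)
        x2 = (rng.random(n) < 0.5).astype(float)
        hazard = 0.1 * np.exp(np.log(1.5) * x1 + np.log(2.0) * x2)
        t_event = rng.exponential(1.0 / hazard)
        t_cens = rng.exponential(25.0, size=n)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
        table, model_p = cox_multivariate(pd.DataFrame({"x1": x1, "x2": x2}), time, event)
        assert abs(table.loc["x1", "hazard_ratio"] - 1.5) / 1.5 < 0.25
        assert abs(table.loc["x2", "hazard_ratio"] - 2.0) / 2.0 < 0.25
        assert model_p < 1e-6

    def test_duplicated_column_rejected(self, rng):
        time, event = random_survival(rng, 50)
        x = rng.normal(size=50)
        with pytest.raises(ValueError, match="collinear.*x2"):
            cox_multivariate(pd.DataFrame({"x1": x, "x2": x}), time, event)


@pytest.fixture(scope="module")
def planted():
    cfg = SimulationConfig(n_samples=250, n_genes=30, seed=7)
    cohort = simulate_cohorts(cfg)[0]
    return cfg, cohort


class TestScreenCohort:
    def test_record_count(self, planted):
        cfg, cohort = planted
        gsps = enumerate_gsps(cfg.candidate_sets())
        records = screen_cohort(cohort, gsps)
        assert len(records) == 2717
        assert [r.gsp for r in records] == gsps

    def test_planted_pair_wins(self, planted):
        cfg, cohort = planted
        gsps = enumerate_gsps(cfg.candidate_sets())
        records = screen_cohort(cohort, gsps)
        planted_rec = records[gsps.index(cfg.planted_gsp())]
        assert planted_rec.hazard_ratio > 1
        # pairs overlapping the planted genes are correlated with it, so in a
        # single cohort the planted pair need only sit near the very top
        rank = sum(r.p_logrank < planted_rec.p_logrank for r in records)
        assert rank < 10
        assert planted_rec.p_logrank < 1e-4

    def test_one_sided_group_flagged(self, cohort_factory, rng):
        time, event = random_survival(rng, 10)
        values = np.vstack([np.full((2, 10), 5.0), np.zeros((2, 10))])
        cohort = cohort_factory(values, genes=list("abxy"), time=time, event=event)
        recs = screen_cohort(cohort, [GeneSetPair(("a", "b"), ("x", "y"))])
        assert recs[0].degenerate and not recs[0].balanced
        assert recs[0].n_good_group == 0

    def test_group_vs_index_covariate(self, planted):
        cfg, cohort = planted
        gsp = cfg.planted_gsp()
        a = screen_cohort(cohort, [gsp], cox_covariate="group")[0]
        b = screen_cohort(cohort, [gsp], cox_covariate="index")[0]
        assert a.p_logrank == b.p_logrank  # log-rank unaffected
        assert a.hazard_ratio != b.hazard_ratio

    def test_missing_member_gene_degenerate(self, cohort_factory, rng):
        time, event = random_survival(rng, 8)
        cohort = cohort_factory(rng.normal(size=(3, 8)), genes=list("abx"),
                                time=time, event=event)
        recs = screen_cohort(cohort, [GeneSetPair(("a", "b"), ("x", "q"))])
        assert recs[0].degenerate

    def test_screen_matches_single_pair_tools(self, planted):
        # the optimized screen must agree with the plain per-pair path
        cfg, cohort = planted
        gsp = cfg.planted_gsp()
        rec = screen_cohort(cohort, [gsp])[0]
        iv = compute_index(cohort, gsp)
        lr = logrank_test(iv.poor_mask, cohort.time, cohort.event)
        cox = cox_univariate(iv.poor_mask.astype(float), cohort.time, cohort.event)
        assert rec.p_logrank == pytest.approx(lr.p_value, rel=1e-12)
        assert rec.hazard_ratio == pytest.approx(cox.hazard_ratio, rel=1e-9)
        assert rec.p_cox_onesided == pytest.approx(cox.p_onesided, rel=1e-9)

    def test_logrank_and_cox_agree_on_strong_effects(self, planted):
        cfg, cohort = planted
        gsps = enumerate_gsps(cfg.candidate_sets())[:200]
        records = screen_cohort(cohort, gsps)
        usable = [r for r in records if not r.degenerate]
        by_lr = sorted(usable, key=lambda r: r.p_logrank)[:5]
        by_cox = sorted(usable, key=lambda r: r.p_cox_onesided)[:5]
        assert {r.gsp for r in by_lr} & {r.gsp for r in by_cox}
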