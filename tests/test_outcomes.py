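"""Aalen-Johansen CIF, Cox partial likelihood, and log-rank tests."""

import numpy as np
import pytest

from gdrecon import (SurvivalDataset, cox_fit, cumulative_incidence,
                     logrank_test)
from gdrecon.outcomes import (CENSORED, COMPETING, EVENT, build_survival,
                              outcome_by_stratum)
from gdrecon.stratify import stratify_cohort


class TestCumulativeIncidence:
    def test_no_events_flat_zero(self):
        ds = SurvivalDataset([10, 20, 30], [CENSORED] * 3)
        curve = cumulative_incidence(ds)
        assert len(curve.times) == 0 and curve.at(100) == 0.0

    def test_hand_aalen_johansen_four_subjects(self):
        # event@10, competing@20, censored@30, event@40
        ds = SurvivalDataset([10, 20, 30, 40],
                             [EVENT, COMPETING, CENSORED, EVENT])
        curve = cumulative_incidence(ds)
        assert curve.at(10) == pytest.approx(0.25)
        assert curve.at(39) == pytest.approx(0.25)
        assert curve.at(40) == pytest.approx(0.75)

    def test_all_events_reach_one(self):
        ds = SurvivalDataset([5, 8, 13, 21], [EVENT] * 4)
        curve = cumulative_incidence(ds)
        assert curve.cif[-1] == pytest.approx(1.0)

    def test_equals_one_minus_km_without_competing_events(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(50, size=40).round() + 1
        s = np.where(rng.uniform(size=40) < 0.7, EVENT, CENSORED)
        ds = SurvivalDataset(t, s)
        aj = cumulative_incidence(ds)
        km = cumulative_incidence(ds, method="one-minus-km")
        np.testing.assert_allclose(aj.cif, km.cif, atol=1e-12)

    def test_matches_lifelines_aalen_johansen(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(1)
        t = rng.exponential(60, size=60) + 0.5  # continuous: no ties
        s = rng.choice([CENSORED, EVENT, COMPETING], size=60,
                       p=[0.3, 0.45, 0.25])
        curve = cumulative_incidence(SurvivalDataset(t, s))
        ajf = lifelines.AalenJohansenFitter(calculate_variance=False)
        ajf.fit(t, s, event_of_interest=EVENT)
        ours = {float(u): c for u, c in zip(curve.times, curve.cif)}
        ref = ajf.cumulative_density_
        for u, c in ours.items():
            np.testing.assert_allclose(
                ref.loc[:u].iloc[-1, 0], c, atol=1e-10)

    def test_never_exceeds_event_probability_bound(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(40, size=50).round() + 1
        s = rng.choice([CENSORED, EVENT, COMPETING], size=50)
        curve = cumulative_incidence(SurvivalDataset(t, s))
        assert (np.diff(curve.cif) >= -1e-12).all()
        assert curve.cif[-1] <= 1.0 + 1e-12

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            SurvivalDataset([0.0, 5.0], [EVENT, EVENT])


def _partial_loglik(beta, t, d, x):
    """Explicit Breslow log partial likelihood for one covariate."""
    ll = 0.0
    for u in np.unique(t[d]):
        died = (t == u) & d
        risk = t >= u
        ll += beta * x[died].sum() - died.sum() * np.log(
            np.exp(beta * x[risk]).sum())
    return ll


def _golden_section_max(f, lo=-10.0, hi=10.0, tol=1e-10):
    phi = (np.sqrt(5) - 1) / 2
    a, b = lo, hi
    c, d = b - phi * (b - a), a + phi * (b - a)
    while abs(b - a) > tol:
        if f(c) > f(d):
            b, d = d, c
            c = b - phi * (b - a)
        else:
            a, c = c, d
            d = a + phi * (b - a)
    return (a + b) / 2


class TestCox:
    def test_symmetric_groups_beta_near_zero(self):
        t = np.array([1, 2, 3, 4, 1, 2, 3, 4], dtype=float)
        s = np.array([EVENT] * 8)
        x = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=float)
        res = cox_fit(SurvivalDataset(t, s), covariates=x)
        assert res.hr == pytest.approx(1.0, abs=1e-6)

    def test_beta_matches_golden_section_oracle(self):
        # tiny all-event dataset with alternating groups (an interior
        # maximum exists; a block design would separate)
        t = np.array([1.0, 2.0, 3.0, 4.0])
        d = np.array([True] * 4)
        x = np.array([1.0, 0.0, 1.0, 0.0])
        res = cox_fit(SurvivalDataset(t, d.astype(int)), covariates=x)
        oracle = _golden_section_max(lambda b: _partial_loglik(b, t, d, x))
        assert res.beta == pytest.approx(oracle, abs=1e-4)

    def test_beta_matches_oracle_on_random_censored_data(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = 30
            x = rng.normal(size=n)
            t = rng.exponential(np.exp(-0.7 * x)) + 0.01
            d = rng.uniform(size=n) < 0.8
            res = cox_fit(SurvivalDataset(t, d.astype(int)), covariates=x)
            oracle = _golden_section_max(
                lambda b: _partial_loglik(b, t, d, x))
            assert res.beta == pytest.approx(oracle, abs=1e-4)

    def test_matches_lifelines_cox(self):
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd
        rng = np.random.default_rng(4)
        n = 80
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.5 * x)) + 0.01
        d = (rng.uniform(size=n) < 0.8).astype(int)
        res = cox_fit(SurvivalDataset(t, d), covariates=x)
        cph = lifelines.CoxPHFitter()
        cph.fit(pd.DataFrame({"T": t, "E": d, "x": x}),
                duration_col="T", event_col="E")
        assert res.beta == pytest.approx(cph.params_["x"], abs=1e-5)
        assert res.se == pytest.approx(cph.standard_errors_["x"], abs=1e-4)

    def test_newton_iterates_monotone_in_loglik(self):
        # step-halving guarantees the log partial likelihood never drops;
        # check the final loglik beats beta=0
        rng = np.random.default_rng(5)
        x = rng.normal(size=40)
        t = rng.exponential(np.exp(-x)) + 0.01
        d = np.ones(40, dtype=int)
        res = cox_fit(SurvivalDataset(t, d), covariates=x)
        assert _partial_loglik(res.beta, t, d.astype(bool), x) >= \
            _partial_loglik(0.0, t, d.astype(bool), x)

    def test_separation_flagged_not_estimated(self):
        # group 1 events all strictly before group 0: monotone likelihood
        t = np.array([1, 2, 3, 4, 10, 11, 12, 13], dtype=float)
        d = np.ones(8, dtype=int)
        x = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=float)
        res = cox_fit(SurvivalDataset(t, d), covariates=x)
        assert res.monotone_likelihood and np.isnan(res.beta)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            cox_fit(SurvivalDataset([1.0, 2.0], [CENSORED, CENSORED]),
                    covariates=np.array([0.0, 1.0]))

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError):
            cox_fit(SurvivalDataset([1.0, 2.0], [EVENT, EVENT]),
                    covariates=np.array([1.0, 1.0]))


class TestLogRank:
    def test_identical_arms_give_zero(self):
        t = np.array([3, 5, 8, 3, 5, 8], dtype=float)
        s = np.array([EVENT] * 6)
        g = np.array(["a", "a", "a", "b", "b", "b"])
        chi2, p = logrank_test(SurvivalDataset(t, s, group=g))
        assert chi2 == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_hand_hypergeometric_accumulation(self):
        t = np.array([1, 2, 3, 4, 5, 6], dtype=float)
        s = np.array([EVENT, EVENT, CENSORED, EVENT, EVENT, CENSORED])
        g = np.array([1, 0, 1, 0, 1, 0])
        o_minus_e = var = 0.0
        for u in np.unique(t[s == EVENT]):
            risk = t >= u
            n, n1 = risk.sum(), (risk & (g == 1)).sum()
            dt = ((t == u) & (s == EVENT)).sum()
            d1 = ((t == u) & (s == EVENT) & (g == 1)).sum()
            o_minus_e += d1 - dt * n1 / n
            var += dt * (n1 / n) * (1 - n1 / n) * (n - dt) / (n - 1)
        chi2, _ = logrank_test(SurvivalDataset(t, s, group=g))
        assert chi2 == pytest.approx(o_minus_e ** 2 / var, abs=1e-10)

    def test_equals_cox_score_test_at_zero_on_tie_free_data(self):
        from gdrecon.outcomes import _cox_loglik
        rng = np.random.default_rng(6)
        t = rng.exponential(10, size=30) + 0.01
        s = (rng.uniform(size=30) < 0.8).astype(int)
        g = rng.integers(0, 2, size=30)
        chi2, _ = logrank_test(SurvivalDataset(t, s, group=g))
        _, grad, info = _cox_loglik(np.zeros(1), t, s == EVENT,
                                    g.astype(float).reshape(-1, 1))
        assert chi2 == pytest.approx(grad[0] ** 2 / info[0, 0], abs=1e-8)

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(7)
        t = rng.exponential(10, size=40) + 0.01
        s = (rng.uniform(size=40) < 0.7).astype(int)
        g = rng.integers(0, 2, size=40)
        chi2, p = logrank_test(SurvivalDataset(t, s, group=g))
        ref = lifelines.statistics.logrank_test(t[g == 0], t[g == 1],
                                                s[g == 0], s[g == 1])
        assert chi2 == pytest.approx(ref.test_statistic, abs=1e-8)
        assert p == pytest.approx(ref.p_value, abs=1e-10)


class TestOutcomeByStratum:
    def test_bundle_structure_and_label_symmetry(self, default_cohort):
        splits = stratify_cohort(default_cohort, subsets=("vd2",))
        res = outcome_by_stratum(default_cohort, splits["vd2"], "ebv")
        assert set(res.curves) == {"low", "high"}
        flipped = splits["vd2"]
        flipped.labels = {pid: ("high" if lab == "low" else "low")
                          for pid, lab in flipped.labels.items()}
        res2 = outcome_by_stratum(default_cohort, flipped, "ebv")
        assert res.logrank_chi2 == pytest.approx(res2.logrank_chi2, abs=1e-10)

    def test_subject_order_invariance(self, default_cohort):
        splits = stratify_cohort(default_cohort, subsets=("gd_t",))
        res1 = outcome_by_stratum(default_cohort, splits["gd_t"], "cmv")
        c = default_cohort.copy()
        c.outcomes = c.outcomes.sample(frac=1, random_state=3)
        res2 = outcome_by_stratum(c, splits["gd_t"], "cmv")
        assert res1.logrank_p == pytest.approx(res2.logrank_p, abs=1e-12)
        assert res1.cox.beta == pytest.approx(res2.cox.beta, nan_ok=True)

    def test_unknown_outcome_rejected(self, default_cohort):
        splits = stratify_cohort(default_cohort, subsets=("vd2",))
        with pytest.raises(KeyError):
            outcome_by_stratum(default_cohort, splits["vd2"], "nonsense")

    def test_death_enters_as_competing_risk(self, default_cohort):
        ds, pids = build_survival(default_cohort, "ebv")
        o = default_cohort.outcomes.set_index("patient_id")
        died_no_ebv = o.index[(o["death"]) & (~o["ebv"])]
        for pid in died_no_ebv:
            i = list(pids).index(pid)
            assert ds.status[i] == COMPETING
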