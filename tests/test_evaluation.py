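"""Survival statistics against hand values and independent oracles."""

import numpy as np
import pandas as pd
import pytest

import wsisurv as w


def cindex_bruteforce(risks, times, events):
    """Double-loop Harrell oracle: comparable iff earlier time is an event."""
    num, den = 0.0, 0
    n = len(risks)
    for m in range(n):
        for j in range(n):
            if times[m] < times[j] and events[m] == 1:
                den += 1
                if risks[m] > risks[j]:
                    num += 1
                elif risks[m] == risks[j]:
                    num += 0.5
    if den == 0:
        raise ValueError("no comparable pairs")
    return num / den


class TestConcordanceIndex:
    def test_perfectly_concordant(self):
        assert w.concordance_index([3, 2, 1], [1, 2, 3], [1, 1, 1]) == 1.0

    def test_perfectly_anticoncordant(self):
        assert w.concordance_index([1, 2, 3], [1, 2, 3], [1, 1, 1]) == 0.0

    def test_tied_risks_count_half(self):
        assert w.concordance_index([5, 5], [1, 3], [1, 0]) == 0.5

    def test_all_censored_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            w.concordance_index([1, 2], [1, 2], [0, 0])

    def test_monotone_transform_invariance(self, rng):
        risks = rng.normal(size=50)
        times = rng.exponential(10, size=50)
        events = (rng.random(50) < 0.7).astype(int)
        a = w.concordance_index(risks, times, events)
        b = w.concordance_index(np.exp(2 * risks) + 3, times, events)
        assert a == b

    def test_agrees_with_lifelines(self, rng):
        from lifelines.utils import concordance_index as ll_cindex

        risks = rng.normal(size=80)
        times = rng.exponential(10, size=80)
        events = (rng.random(80) < 0.6).astype(int)
        ours = w.concordance_index(risks, times, events)
        # lifelines scores concordance of predicted *survival* times
        theirs = ll_cindex(times, -risks, events)
        assert ours == pytest.approx(theirs, abs=1e-12)


class TestStratifyMedian:
    def test_even_cohort(self):
        assert list(w.stratify_median([1, 2, 3, 4])) == ["low", "low", "high", "high"]

    def test_odd_cohort_median_goes_low(self):
        assert list(w.stratify_median([1, 2, 3])) == ["low", "low", "high"]

    def test_all_equal_warns_all_low(self):
        with pytest.warns(UserWarning, match="all risks equal"):
            labels = w.stratify_median([2.0, 2.0, 2.0])
        assert list(labels) == ["low", "low", "low"]


class TestKaplanMeier:
    def test_all_censored_survival_stays_one(self):
        km = w.km_estimate([1, 2, 3], [0, 0, 0])
        assert len(km.event_times) == 0
        assert np.allclose(km.survival_at([0.5, 5.0]), 1.0)

    def test_three_observed_steps(self):
        km = w.km_estimate([1, 2, 3], [1, 1, 1])
        assert np.allclose(km.event_times, [1, 2, 3])
        assert np.allclose(km.survival, [2 / 3, 1 / 3, 0.0])

    def test_censoring_between_events(self):
        km = w.km_estimate([1, 2, 3], [1, 0, 1])
        assert np.allclose(km.event_times, [1, 3])
        assert np.allclose(km.survival, [2 / 3, 0.0])

    def test_no_censoring_matches_one_minus_ecdf(self, rng):
        times = rng.exponential(5, size=60)
        km = w.km_estimate(times, np.ones(60, dtype=int))
        grid = np.quantile(times, [0.1, 0.33, 0.5, 0.9])
        ecdf = np.array([(times <= t).mean() for t in grid])
        assert np.allclose(km.survival_at(grid), 1 - ecdf)

    def test_survival_monotone_nonincreasing(self, rng):
        times = rng.exponential(5, size=40)
        events = (rng.random(40) < 0.6).astype(int)
        km = w.km_estimate(times, events)
        assert (np.diff(km.survival) <= 1e-12).all()
        assert km.survival_at(0.0) <= 1.0


def _logrank_oracle_statistic(times, events, groups):
    """Direct O-E / V computation of the two-group log-rank chi-square."""
    labels = np.unique(groups)
    o1 = e1 = v = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == labels[1])).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == labels[1])).sum()
        o1 += d1
        e1 += d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (o1 - e1) ** 2 / v


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        times = np.array([1, 2, 3, 4, 1, 2, 3, 4], float)
        events = np.array([1, 1, 0, 1] * 2)
        groups = np.array(["a"] * 4 + ["b"] * 4)
        chi2, p = w.logrank_test(times, events, groups)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_separated_groups_significant(self):
        times = np.array([1, 2, 3, 10, 11, 12], float)
        events = np.ones(6, int)
        groups = np.array(["a"] * 3 + ["b"] * 3)
        chi2, p = w.logrank_test(times, events, groups)
        assert p < 0.05
        assert chi2 == pytest.approx(_logrank_oracle_statistic(times, events, groups), rel=1e-9)

    def test_matches_permutation_null(self, rng):
        n = 30
        times = rng.exponential(10, size=n)
        events = (rng.random(n) < 0.8).astype(int)
        groups = np.array(["a", "b"])[rng.integers(0, 2, size=n)]
        if len(np.unique(groups)) < 2:
            groups[:2] = ["a", "b"]
        chi2, p = w.logrank_test(times, events, groups)
        stats = []
        for _ in range(2000):
            perm = rng.permutation(groups)
            if len(np.unique(perm)) == 2:
                stats.append(_logrank_oracle_statistic(times, events, perm))
        p_perm = np.mean(np.array(stats) >= chi2 - 1e-12)
        mc_err = 3 * np.sqrt(max(p_perm * (1 - p_perm), 1e-4) / len(stats))
        assert abs(p_perm - p) <= mc_err + 0.02

    def test_single_group_errors(self):
        with pytest.raises(ValueError, match="2 groups"):
            w.logrank_test([1, 2], [1, 1], ["a", "a"])


class TestCoxRegression:
    def _fixture(self):
        # 10 subjects, one covariate, mixed censoring, no ties
        x = np.array([0.2, -1.0, 0.5, 1.5, -0.3, 0.9, -1.2, 0.1, 0.7, -0.5])
        t = np.array([5.0, 12.0, 3.0, 6.0, 2.0, 9.0, 15.0, 1.0, 4.0, 11.0])
        e = np.array([1, 0, 1, 1, 1, 1, 0, 1, 1, 0])
        return x, t, e

    def test_matches_grid_search_maximizer(self):
        x, t, e = self._fixture()
        fit = w.cox_regression(x, t, e)
        betas = np.linspace(-3, 3, 60001)
        # vectorized brute-force partial likelihood over the grid
        nll = np.zeros_like(betas)
        for m in np.flatnonzero(e):
            riskset = t >= t[m]
            nll += -betas * x[m] + np.log(np.exp(betas[:, None] * x[riskset]).sum(axis=1))
        best = betas[np.argmin(nll)]
        assert fit.coef[0] == pytest.approx(best, abs=1e-4)
        assert fit.converged

    def test_score_vanishes_at_optimum(self):
        from wsisurv._coxph import nll_grad_hess_beta

        x, t, e = self._fixture()
        fit = w.cox_regression(x, t, e)
        _, grad, _ = nll_grad_hess_beta(fit.coef, x[:, None], t, e)
        assert np.linalg.norm(grad) < 1e-6

    def test_agrees_with_lifelines_when_untied(self):
        from lifelines import CoxPHFitter

        x, t, e = self._fixture()
        fit = w.cox_regression(x, t, e)
        df = pd.DataFrame({"x": x, "t": t, "e": e})
        ll = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        assert fit.coef[0] == pytest.approx(ll.params_["x"], abs=1e-4)
        assert fit.se[0] == pytest.approx(ll.standard_errors_["x"], abs=1e-4)

    def test_null_covariate_ci_coverage(self, rng):
        hits = 0
        reps = 200
        for _ in range(reps):
            n = 100
            x = rng.normal(size=n)
            t = rng.exponential(10, size=n)
            e = (rng.random(n) < 0.8).astype(int)
            fit = w.cox_regression(x, t, e)
            lo, hi = fit.ci95[0]
            hits += lo <= 1.0 <= hi
        assert 0.90 <= hits / reps <= 0.99

    def test_binary_covariate_hr_consistency(self, rng):
        n = 2000
        x = (rng.random(n) < 0.5).astype(float)
        lam = 0.05 * np.exp(np.log(2) * x)
        t = rng.exponential(1 / lam)
        e = np.ones(n, int)
        fit = w.cox_regression(x, t, e)
        assert fit.hazard_ratio[0] == pytest.approx(2.0, abs=0.3)

    def test_univariable_mode_fits_each_alone(self, rng):
        n = 150
        X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        t = rng.exponential(10, size=n) * np.exp(-0.5 * X["a"])
        e = np.ones(n, int)
        fits = w.cox_regression(X, t, e, mode="univariable")
        assert [f.variables for f in fits] == [["a"], ["b"]]
        solo = w.cox_regression(X[["a"]], t, e)
        assert fits[0].coef[0] == pytest.approx(solo.coef[0], abs=1e-10)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            w.cox_regression(np.ones(5), [1, 2, 3, 4, 5], [1, 1, 1, 1, 1])

    def test_separation_flags_nonconvergence(self):
        # 2 subjects, perfect separation: monotone likelihood
        fit = w.cox_regression(np.array([1.0, 0.0]), [1.0, 2.0], [1, 1])
        assert not fit.converged
        assert np.isnan(fit.hazard_ratio).all()

    def test_cindex_invariant_to_univariable_fit_direction(self):
        x, t, e = self._fixture()
        fit = w.cox_regression(x, t, e, mode="univariable")[0]
        direct = w.concordance_index(np.sign(fit.coef[0]) * x, t, e)
        assert fit.c_index == pytest.approx(direct)


def test_logrank_hazard_ratio_orders_groups():
    times = np.array([1, 2, 3, 10, 11, 12], float)
    events = np.ones(6, int)
    groups = np.array(["a"] * 3 + ["b"] * 3)
    hr = w.logrank_hazard_ratio(times, events, groups)
    assert hr < 1.0  # group "b" lives longer -> lower hazard vs "a"
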