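"""Survival statistics: c-index, risk stratification, KM, log-rank, Cox fits.

Harrell's concordance index uses the standard comparable-pair rule: a
pair is comparable iff the shorter time is an observed event and the
times are untied; tied risks count 1/2.  Hazard-ratio regression is
Newton-Raphson on the Breslow partial likelihood with Wald intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import _coxph

__all__ = [
    "concordance_index",
    "stratify_median",
    "KMEstimate",
    "km_estimate",
    "logrank_test",
    "logrank_hazard_ratio",
    "CoxFit",
    "cox_regression",
]


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

def concordance_index(risks, times, events) -> float:
    """Harrell's c-index: P(higher risk | shorter observed survival).

    Over comparable pairs (t_m < t_n with event observed at t_m), counts
    pairs where the shorter-lived patient has the strictly higher
    predicted risk; risk ties contribute 1/2.  Raises when no comparable
    pair exists (e.g. everything censored).
    """
    risks = np.asarray(risks, dtype=float).ravel()
    times = np.asarray(times, dtype=float).ravel()
    events = np.asarray(events).ravel().astype(int)
    if not (len(risks) == len(times) == len(events)):
        raise ValueError("equal lengths required")
    comparable = (times[:, None] < times[None, :]) & (events[:, None] == 1)
    n_pairs = int(comparable.sum())
    if n_pairs == 0:
        raise ValueError("c-index undefined: no comparable pairs")
    higher = risks[:, None] > risks[None, :]
    tied = risks[:, None] == risks[None, :]
    score = (comparable & higher).sum() + 0.5 * (comparable & tied).sum()
    return float(score / n_pairs)


def stratify_median(patient_risks) -> np.ndarray:
    """Label each patient ``high``/``low`` by the cohort median risk.

    Risks strictly above the median are ``high``; risks at or below it
    are ``low`` (deterministic handling of median-equal scores).
    """
    risks = np.asarray(patient_risks, dtype=float).ravel()
    if len(risks) < 2:
        raise ValueError("need at least 2 patients to stratify")
    med = np.median(risks)
    if np.all(risks == risks[0]):
        warnings.warn("all risks equal; every patient assigned to the low group")
    return np.where(risks > med, "high", "low")


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------

@dataclass
class KMEstimate:
    """Product-limit survival curve S(t) with its risk/event tables."""

    event_times: np.ndarray  # distinct times with >= 1 observed event, sorted
    survival: np.ndarray     # S(t) just after each event time
    at_risk: np.ndarray      # n_i at each event time
    events: np.ndarray       # d_i at each event time

    def survival_at(self, t) -> np.ndarray:
        """Step-function evaluation, S(0) = 1."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.event_times, t, side="right")
        s = np.concatenate([[1.0], self.survival])
        return s[idx]


def km_estimate(times, events) -> KMEstimate:
    """Kaplan-Meier product-limit estimate S(t) = prod (1 - d_i/n_i)."""
    from lifelines import KaplanMeierFitter

    times = np.asarray(times, dtype=float).ravel()
    events = np.asarray(events).ravel().astype(int)
    if len(times) == 0:
        raise ValueError("need at least one subject")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    rows = table[table["observed"] > 0]
    event_times = rows.index.to_numpy(dtype=float)
    at_risk = rows["at_risk"].to_numpy(dtype=float)
    d = rows["observed"].to_numpy(dtype=float)
    survival = kmf.survival_function_at_times(event_times).to_numpy(dtype=float)
    return KMEstimate(event_times=event_times, survival=survival, at_risk=at_risk, events=d)


def _two_groups(times, events, groups):
    times = np.asarray(times, dtype=float).ravel()
    events = np.asarray(events).ravel().astype(int)
    groups = np.asarray(groups).ravel()
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"exactly 2 groups required, got {len(labels)}")
    masks = [groups == g for g in labels]
    if any(m.sum() == 0 for m in masks):
        raise ValueError("each group must be nonempty")
    return times, events, masks, labels


def logrank_test(times, events, group_labels) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and its two-sided p value."""
    from lifelines.statistics import logrank_test as _lr

    times, events, (m0, m1), _ = _two_groups(times, events, group_labels)
    res = _lr(times[m0], times[m1], event_observed_A=events[m0], event_observed_B=events[m1])
    return float(res.test_statistic), float(res.p_value)


def logrank_hazard_ratio(times, events, group_labels):
    """Mantel-Haenszel style O/E hazard ratio between two KM groups.

    HR = (O1/E1) / (O0/E0) with observed and expected event counts from
    the log-rank table; used to annotate two-group KM comparisons (the
    regression hazard ratios come from :func:`cox_regression`).
    """
    times, events, (m0, m1), labels = _two_groups(times, events, group_labels)
    event_times = np.unique(times[events == 1])
    O = np.array([events[m0].sum(), events[m1].sum()], dtype=float)
    E = np.zeros(2)
    for t in event_times:
        n0 = (times[m0] >= t).sum()
        n1 = (times[m1] >= t).sum()
        d = ((times == t) & (events == 1)).sum()
        n = n0 + n1
        E[0] += d * n0 / n
        E[1] += d * n1 / n
    if E[0] == 0 or E[1] == 0 or O[0] == 0:
        raise ValueError("hazard ratio undefined: a group has no expected/observed events")
    return float((O[1] / E[1]) / (O[0] / E[0]))


# ---------------------------------------------------------------------------
# proportional-hazards regression
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    """A fitted proportional-hazards model (one or several covariates)."""

    variables: list[str]
    coef: np.ndarray
    se: np.ndarray
    hazard_ratio: np.ndarray
    ci95: np.ndarray      # (p, 2) on the HR scale
    p_value: np.ndarray
    converged: bool
    c_index: float        # c-index of the linear predictor
    mode: str = "multivariable"

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable": self.variables,
                "coef": self.coef,
                "HR": self.hazard_ratio,
                "ci_low": self.ci95[:, 0],
                "ci_high": self.ci95[:, 1],
                "p": self.p_value,
                "c_index": self.c_index,
            }
        )


def _newton_cox(X, times, events, max_iter=100, tol=1e-10):
    p = X.shape[1]
    beta = np.zeros(p)
    loss, grad, hess = _coxph.nll_grad_hess_beta(beta, X, times, events)
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            return beta, hess, False
        new_beta = beta - step
        new_loss, new_grad, new_hess = _coxph.nll_grad_hess_beta(new_beta, X, times, events)
        # step-halving keeps Newton monotone
        halvings = 0
        while not np.isfinite(new_loss) or new_loss > loss + 1e-12:
            halvings += 1
            if halvings > 30:
                break
            step = step / 2
            new_beta = beta - step
            new_loss, new_grad, new_hess = _coxph.nll_grad_hess_beta(new_beta, X, times, events)
        beta, loss, grad, hess = new_beta, new_loss, new_grad, new_hess
        if np.abs(beta).max() > 15:
            # monotone likelihood / separation: the gradient decays to zero
            # while the coefficient runs away, so flag on magnitude
            return beta, hess, False
        if np.abs(grad).max() < tol * max(1.0, abs(loss)):
            return beta, hess, True
    return beta, hess, np.abs(grad).max() < 1e-6


def _fit_one(X, times, events, variables, mode):
    events_arr = np.asarray(events).ravel().astype(int)
    beta, hess, converged = _newton_cox(X, times, events_arr)
    if not converged:
        nan = np.full(X.shape[1], np.nan)
        return CoxFit(
            variables=variables, coef=nan, se=nan, hazard_ratio=nan,
            ci95=np.full((X.shape[1], 2), np.nan), p_value=nan,
            converged=False, c_index=np.nan, mode=mode,
        )
    cov = np.linalg.inv(hess)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    hr = np.exp(beta)
    ci = np.column_stack([np.exp(beta - 1.96 * se), np.exp(beta + 1.96 * se)])
    c = concordance_index(X @ beta, times, events_arr)
    return CoxFit(
        variables=variables, coef=beta, se=se, hazard_ratio=hr, ci95=ci,
        p_value=np.clip(pvals, np.finfo(float).tiny, 1.0),
        converged=True, c_index=c, mode=mode,
    )


def cox_regression(covariates, times, events, mode: str = "multivariable"):
    """Fit proportional-hazards regression(s) and report hazard ratios.

    ``covariates`` is a DataFrame or 2-D array.  ``multivariable`` fits
    all covariates jointly and returns one :class:`CoxFit`;
    ``univariable`` fits each covariate alone and returns a list of fits.
    Wald 95% intervals exp(coef +/- 1.96 se); Breslow tie handling; the
    linear predictor's c-index is reported per fit.
    """
    if isinstance(covariates, pd.DataFrame):
        names = [str(c) for c in covariates.columns]
        X = covariates.to_numpy(dtype=float)
    else:
        X = np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{i}" for i in range(X.shape[1])]
    times = np.asarray(times, dtype=float).ravel()
    events_arr = np.asarray(events).ravel().astype(int)
    if X.shape[0] != len(times):
        raise ValueError("covariate rows must match number of subjects")
    for j, name in enumerate(names):
        if np.ptp(X[:, j]) == 0:
            raise ValueError(f"constant covariate {name!r}")
    n_events = int(events_arr.sum())
    if mode == "multivariable":
        if n_events < X.shape[1] + 1:
            raise ValueError("too few events for the number of covariates")
        return _fit_one(X, times, events_arr, names, mode)
    if mode == "univariable":
        if n_events < 2:
            raise ValueError("too few events")
        return [
            _fit_one(X[:, [j]], times, events_arr, [names[j]], mode)
            for j in range(X.shape[1])
        ]
    raise ValueError(f"mode must be 'univariable' or 'multivariable', got {mode!r}")
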