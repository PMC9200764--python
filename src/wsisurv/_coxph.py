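"""Cox partial-likelihood internals shared by training and evaluation.

Everything works on risks sorted by descending time, so each risk set is
a prefix.  Tied event times use the Breslow approximation (shared risk
set) by default; Efron's correction is available where noted.  All
log-sum-exp computations subtract the global maximum, which also makes
the loss exactly invariant to adding a constant to all risks.
"""

from __future__ import annotations

import numpy as np


def _prepare(risks, times, events):
    risks = np.asarray(risks, dtype=float).ravel()
    times = np.asarray(times, dtype=float).ravel()
    events = np.asarray(events).ravel().astype(int)
    if not (len(risks) == len(times) == len(events)):
        raise ValueError("risks, times, events must have equal lengths")
    if len(risks) == 0:
        raise ValueError("empty input")
    if not np.all((events == 0) | (events == 1)):
        raise ValueError("events must be 0 or 1")
    order = np.argsort(-times, kind="stable")
    return risks[order], times[order], events[order], order


def _tie_groups(t_sorted):
    """Start indices of tied-time groups in a descending-sorted time array."""
    starts = np.flatnonzero(np.concatenate([[True], t_sorted[1:] != t_sorted[:-1]]))
    ends = np.concatenate([starts[1:], [len(t_sorted)]])
    return starts, ends


def nll(risks, times, events, ties: str = "breslow") -> float:
    """Negative log partial likelihood (sum over events)."""
    r, t, d, _ = _prepare(risks, times, events)
    if d.sum() == 0:
        return 0.0
    m = r.max()
    w = np.exp(r - m)
    cw = np.cumsum(w)
    starts, ends = _tie_groups(t)
    total = 0.0
    for s, e in zip(starts, ends):
        ev = np.flatnonzero(d[s:e]) + s
        D = len(ev)
        if D == 0:
            continue
        S = cw[e - 1]  # Breslow risk set: everyone with time >= this group's time
        if ties == "breslow":
            total -= r[ev].sum() - D * (m + np.log(S))
        elif ties == "efron":
            Wev = w[ev].sum()
            ls = np.log(S - (np.arange(D) / D) * Wev).sum()
            total -= r[ev].sum() - (D * m + ls)
        else:
            raise ValueError(f"unknown ties rule {ties!r}")
    return float(total)


def grad_risks(risks, times, events, ties: str = "breslow") -> np.ndarray:
    """Gradient of the negative log partial likelihood w.r.t. each risk."""
    r, t, d, order = _prepare(risks, times, events)
    n = len(r)
    g_sorted = np.zeros(n)
    if d.sum() > 0:
        m = r.max()
        w = np.exp(r - m)
        cw = np.cumsum(w)
        starts, ends = _tie_groups(t)
        if ties == "breslow":
            # suffix sum over event groups of D_g / S_g, assigned per group
            ratios = np.zeros(len(starts))
            for gi, (s, e) in enumerate(zip(starts, ends)):
                D = int(d[s:e].sum())
                if D:
                    ratios[gi] = D / cw[e - 1]
            suffix = np.cumsum(ratios[::-1])[::-1]
            factor = np.empty(n)
            for gi, (s, e) in enumerate(zip(starts, ends)):
                factor[s:e] = suffix[gi]
            g_sorted = -d + w * factor
        elif ties == "efron":
            inv_sum = np.zeros(len(starts))  # sum_l 1/denom for each event group
            own = np.zeros(n)                # extra term for the group's own events
            for gi, (s, e) in enumerate(zip(starts, ends)):
                ev = np.flatnonzero(d[s:e]) + s
                D = len(ev)
                if D == 0:
                    continue
                Wev = w[ev].sum()
                denom = cw[e - 1] - (np.arange(D) / D) * Wev
                inv_sum[gi] = (1.0 / denom).sum()
                own[ev] = -w[ev] * ((np.arange(D) / D) / denom).sum()
            suffix = np.cumsum(inv_sum[::-1])[::-1]
            factor = np.empty(n)
            for gi, (s, e) in enumerate(zip(starts, ends)):
                factor[s:e] = suffix[gi]
            g_sorted = -d + w * factor + own
        else:
            raise ValueError(f"unknown ties rule {ties!r}")
    g = np.empty(n)
    g[order] = g_sorted
    return g


def nll_grad_hess_beta(beta, X, times, events):
    """Breslow NLL, gradient and Hessian w.r.t. regression coefficients."""
    beta = np.asarray(beta, dtype=float)
    X = np.asarray(X, dtype=float)
    risks = X @ beta
    r, t, d, order = _prepare(risks, times, events)
    Xs = X[order]
    n, p = Xs.shape
    m = r.max()
    w = np.exp(r - m)
    cw = np.cumsum(w)
    cwx = np.cumsum(w[:, None] * Xs, axis=0)
    cwxx = np.cumsum(w[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]), axis=0)
    starts, ends = _tie_groups(t)

    loss = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    for s, e in zip(starts, ends):
        ev = np.flatnonzero(d[s:e]) + s
        D = len(ev)
        if D == 0:
            continue
        S = cw[e - 1]
        Sx = cwx[e - 1]
        Sxx = cwxx[e - 1]
        mu = Sx / S
        loss -= r[ev].sum() - D * (m + np.log(S))
        grad += D * mu - Xs[ev].sum(axis=0)
        hess += D * (Sxx / S - np.outer(mu, mu))
    return float(loss), grad, hess
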