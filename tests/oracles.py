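"""Brute-force oracles, independent of the package's survival engine.

Everything here is written as a direct transcription of textbook
definitions — explicit risk-set enumeration, tabulated O-E/V computation,
naive partial-likelihood evaluation maximized by scalar search — with no
shared code with ``saspsurv.survival``.
"""

import numpy as np
from scipy.optimize import minimize_scalar


def km_oracle(times, events):
    """Product-limit estimate by explicit enumeration of risk sets.

    Returns (event_times, survival) with events preceding censorings at
    tied times.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    ts = sorted(set(times[events == 1]))
    surv = []
    s = 1.0
    for t in ts:
        n_at_risk = sum(1 for x in times if x >= t)
        d = sum(1 for x, e in zip(times, events) if x == t and e == 1)
        s *= 1.0 - d / n_at_risk
        surv.append(s)
    return np.array(ts), np.array(surv)


def logrank_oracle(t_a, e_a, t_b, e_b):
    """Two-group log-rank chi-square from the hand risk-set table."""
    t_a, e_a = np.asarray(t_a, float), np.asarray(e_a, int)
    t_b, e_b = np.asarray(t_b, float), np.asarray(e_b, int)
    all_t = np.concatenate([t_a, t_b])
    all_e = np.concatenate([e_a, e_b])
    o_minus_e, v = 0.0, 0.0
    for t in sorted(set(all_t[all_e == 1])):
        na = sum(1 for x in t_a if x >= t)
        nb = sum(1 for x in t_b if x >= t)
        n = na + nb
        d = sum(1 for x, e in zip(all_t, all_e) if x == t and e == 1)
        da = sum(1 for x, e in zip(t_a, e_a) if x == t and e == 1)
        o_minus_e += da - d * na / n
        if n > 1:
            v += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    if v <= 0:
        return 0.0
    return o_minus_e ** 2 / v


def cox_loglik_oracle(beta, times, events, x, ties="efron"):
    """Naive partial log-likelihood for one scalar covariate."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    x = np.asarray(x, float)
    ll = 0.0
    for t in sorted(set(times[events == 1])):
        deaths = [i for i in range(len(times))
                  if times[i] == t and events[i] == 1]
        risk = [i for i in range(len(times)) if times[i] >= t]
        d = len(deaths)
        sum_death_eta = sum(beta * x[i] for i in deaths)
        s0 = sum(np.exp(beta * x[i]) for i in risk)
        s0d = sum(np.exp(beta * x[i]) for i in deaths)
        ll += sum_death_eta
        for el in range(d):
            frac = el / d if ties == "efron" else 0.0
            ll -= np.log(s0 - frac * s0d)
    return ll


def cox_argmax_oracle(times, events, x, ties="efron", bound=5.0):
    """Grid search + bounded refinement of the naive partial likelihood.

    Returns (beta_hat, at_boundary): ``at_boundary`` signals a monotone
    likelihood (no interior maximum on [-bound, bound]).
    """
    grid = np.linspace(-bound, bound, 501)
    vals = [cox_loglik_oracle(b, times, events, x, ties) for b in grid]
    if np.ptp(vals) < 1e-9:  # flat likelihood: no information about beta
        return 0.0, True
    i = int(np.argmax(vals))
    if i == 0 or i == len(grid) - 1:
        return grid[i], True
    res = minimize_scalar(
        lambda b: -cox_loglik_oracle(b, times, events, x, ties),
        bounds=(grid[i - 1], grid[i + 1]), method="bounded",
        options={"xatol": 1e-10})
    return float(res.x), False
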